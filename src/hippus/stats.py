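"""Group statistics: t-tests, chi-square, age-adjusted ANCOVA, correlations.

The group contrasts follow the study design the features feed into: feature
values are compared between two groups by ANCOVA with age as a covariate
(age affects pupil size), with post hoc two-tailed t-tests on the raw
values; demographic tables use pooled-variance Student t and the 2x2
Pearson chi-square without continuity correction; feature-feature and
feature-ASRS associations use Pearson's R.  A pair of features with
|R| > 0.8 is treated as collinear and their joint use in the classifier is
disallowed.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

ALPHA = 0.05


def two_sample_t(a, b, pooled: bool = True) -> tuple[float, float]:
    """Two-tailed two-sample t-test (Student pooled variance by default).

    Zero pooled variance: equal means give (0, 1); unequal means give a
    sign-carrying infinite t with p = 0.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        log.warning("zero pooled variance with unequal means: t unbounded")
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = sps.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table (df = 1), no continuity
    correction by default."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


@dataclass
class AncovaResult:
    """Group main effect from `value ~ group + age` with partial eta^2."""

    F: float
    p: float
    eta_sq: float
    df: tuple[int, int]
    adjusted_means: dict
    covariate_dropped: bool = False
    posthoc_t: float = float("nan")
    posthoc_p: float = float("nan")


def ancova_group_age(values, group, age) -> AncovaResult:
    """ANCOVA of a feature with a two-level group factor and age covariate.

    The group F comes from the extra sum of squares of dropping the group
    indicator; partial eta^2 = SS_group / (SS_group + SS_residual).  A
    constant age drops the covariate (with a warning), reducing to one-way
    ANOVA.  The post hoc t is the pooled two-sample t on the raw values,
    signed so that positive t means the second group level (sorted order)
    is larger.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "group": np.asarray(group),
        "age": np.asarray(age, dtype=float),
    })
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels}")
    if df.groupby("group").size().min() < 3:
        raise ValueError("need at least 3 subjects per group")
    covariate_dropped = bool(np.all(df["age"] == df["age"].iloc[0]))
    if covariate_dropped:
        log.warning("age is constant: covariate dropped, reduces to one-way ANOVA")
        formula = "value ~ C(group)"
    else:
        formula = "value ~ C(group) + age"
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    ss_group = float(anova.loc["C(group)", "sum_sq"])
    ss_resid = float(anova.loc["Residual", "sum_sq"])
    F = float(anova.loc["C(group)", "F"])
    p = float(anova.loc["C(group)", "PR(>F)"])
    eta_sq = ss_group / (ss_group + ss_resid)
    dfn = int(anova.loc["C(group)", "df"])
    dfd = int(anova.loc["Residual", "df"])
    # covariate-adjusted group means: prediction at the grand mean age
    adj = {}
    for lev in levels:
        pred = pd.DataFrame({"group": [lev], "age": [df["age"].mean()]})
        adj[lev] = float(fit.predict(pred).iloc[0])
    a = df.loc[df["group"] == levels[1], "value"]
    b = df.loc[df["group"] == levels[0], "value"]
    t_post, p_post = two_sample_t(a, b)
    return AncovaResult(
        F=F, p=p, eta_sq=eta_sq, df=(dfn, dfd), adjusted_means=adj,
        covariate_dropped=covariate_dropped, posthoc_t=t_post, posthoc_p=p_post,
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson R with two-tailed p from the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CorrelationMatrix:
    features: list
    R: pd.DataFrame
    p: pd.DataFrame
    collinear_pairs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "R": self.R.round(10).to_dict(),
            "p": self.p.round(10).to_dict(),
            "collinear_pairs": [list(pr) for pr in self.collinear_pairs],
        }


def correlation_matrix(
    table: pd.DataFrame, columns: list[str], threshold: float = 0.8
) -> CorrelationMatrix:
    """Pairwise Pearson R (and p) over feature columns, flagging pairs with
    |R| strictly above the collinearity threshold.  Rows with any missing
    value among the columns are dropped pairwise."""
    R = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    P = pd.DataFrame(np.zeros((len(columns), len(columns))), index=columns, columns=columns)
    collinear = []
    for ca, cb in combinations(columns, 2):
        sub = table[[ca, cb]].dropna()
        r, p = pearson_r(sub[ca], sub[cb])
        R.loc[ca, cb] = R.loc[cb, ca] = r
        P.loc[ca, cb] = P.loc[cb, ca] = p
        if abs(r) > threshold:
            collinear.append((ca, cb))
    return CorrelationMatrix(features=list(columns), R=R, p=P, collinear_pairs=collinear)


def multicollinearity_gate(
    table: pd.DataFrame,
    features: tuple[str, ...] = ("size_mm", "sampen", "tranen"),
    threshold: float = 0.8,
) -> list[tuple[str, ...]]:
    """Enumerate the candidate feature combinations (all non-empty subsets)
    and drop any combination containing a pair with |R| strictly above the
    threshold.  A pair at exactly the threshold is retained."""
    cm = correlation_matrix(table, list(features), threshold)
    banned = {frozenset(pr) for pr in cm.collinear_pairs}
    allowed = []
    for k in range(1, len(features) + 1):
        for combo in combinations(features, k):
            if any(frozenset(pr) <= set(combo) for pr in banned):
                continue
            allowed.append(combo)
    return allowed
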