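"""Logistic-regression classification with ROC/AUC and decision regions.

A binomial GLM with logit link is fitted by iteratively reweighted least
squares on the selected feature columns (positive class = ADHD).  The ROC
curve is traced by sweeping the decision threshold on the fitted
probability P(ADHD) from 0 to 1: at each threshold the true- and
false-positive rates are recorded, and the AUC is the trapezoidal area
under the sorted curve.  Evaluation is in-sample (fit and ROC on the same
cohort); k-fold cross-validated AUC is available as a clearly separated
extension.  For two-feature models the fitted probability surface is
evaluated on a rectangular grid to expose the (linear) decision boundary
P = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

POSITIVE_CLASS = "ADHD"


@dataclass
class LogisticFit:
    feature_names: list
    intercept: float
    weights: np.ndarray
    probabilities: np.ndarray
    converged: bool
    separation_flag: bool
    n_iter: int
    log_likelihood: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.weights])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.weights
        return _sigmoid(eta)


@dataclass
class RocResult:
    feature_set: list
    coefficients: list
    roc_points: list          # (fpr, tpr) sorted along the curve
    auc: float
    probabilities: list
    thresholds: list

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "coefficients": self.coefficients,
            "roc_points": self.roc_points,
            "thresholds": self.thresholds,
            "auc": self.auc,
            "probabilities": self.probabilities,
        }


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-300
    return float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def encode_labels(labels, positive: str = POSITIVE_CLASS) -> np.ndarray:
    """Map group labels to {0, 1} with the ADHD-like class positive.

    Any label containing the positive-class string (e.g. drug-naive-ADHD)
    counts as positive.
    """
    return np.array([1 if positive in str(l) else 0 for l in labels], dtype=float)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Binomial GLM (logit link) by IRLS.

    Convergence: max |coefficient change| < ``tol`` or ``max_iter``
    iterations.  Quasi-separation (fitted probabilities pinned to 0/1 with
    still-growing coefficients) stops at the iteration cap with
    ``separation_flag`` set; the probability ordering remains usable for
    ROC.  Zero-variance feature columns receive weight 0 and are excluded
    from the design (a model with no informative feature reduces to the
    intercept at the logit of class prevalence).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(y) > 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(d)]
    if not np.all(np.isfinite(X)):
        keep = np.all(np.isfinite(X), axis=1)
        log.warning("dropping %d subjects with missing feature values", int((~keep).sum()))
        X, y = X[keep], y[keep]
        n = len(y)
    classes = np.unique(y)
    if len(classes) < 2 or min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 subjects in each class")

    active = np.std(X, axis=0) > 0
    Xa = X[:, active]
    design = np.column_stack([np.ones(n), Xa])
    beta = np.zeros(design.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        p = _sigmoid(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        wd = design * w[:, None]
        try:
            beta_new = np.linalg.solve(design.T @ wd, design.T @ (w * z))
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(wd, w * z, rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    p = _sigmoid(design @ beta)
    separation = not converged and bool(
        np.all((p > 1 - 1e-6) == (y == 1)) or np.max(np.abs(beta)) > 1e3
    )
    if separation:
        log.warning("quasi-separation detected: stopped at iteration cap %d", it)
    weights = np.zeros(d)
    weights[active] = beta[1:]
    return LogisticFit(
        feature_names=list(feature_names),
        intercept=float(beta[0]),
        weights=weights,
        probabilities=p,
        converged=converged,
        separation_flag=separation,
        n_iter=it,
        log_likelihood=_log_likelihood(y, p),
    )


def roc_auc(probabilities, labels, feature_set=None, coefficients=None) -> RocResult:
    """ROC curve and trapezoidal AUC from fitted probabilities.

    Thresholds are {0} + sorted unique probabilities + {1}; a subject is
    called positive when its probability is >= the threshold.  Tied
    probabilities move the operating point simultaneously, so the trapezoid
    over a tie block contributes the standard half-credit, and the AUC
    equals the Mann-Whitney pair-counting statistic.
    """
    prob = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # descending thresholds trace the curve from (0,0) to (1,1); the +inf
    # sentinel guarantees the (0,0) endpoint even when a score equals 1
    thresholds = np.concatenate([[0.0], np.unique(prob), [1.0], [np.inf]])
    thresholds = np.unique(thresholds)[::-1]
    points = []
    for th in thresholds:
        call = prob >= th
        tpr = np.sum(call & (y == 1)) / n_pos
        fpr = np.sum(call & (y == 0)) / n_neg
        points.append((float(fpr), float(tpr)))
    pts = np.array(points)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocResult(
        feature_set=list(feature_set or []),
        coefficients=list(map(float, coefficients)) if coefficients is not None else [],
        roc_points=[(float(a), float(b)) for a, b in pts],
        auc=auc,
        probabilities=[float(v) for v in prob],
        thresholds=[float(t) for t in thresholds],
    )


@dataclass
class DecisionGrid:
    feature_names: list
    x: np.ndarray
    y: np.ndarray
    P: np.ndarray             # (len(y), len(x)) probability surface
    region: np.ndarray        # boolean, P >= 0.5

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "P": np.round(self.P, 10).tolist(),
            "region": self.region.astype(int).tolist(),
        }


def decision_grid(fit: LogisticFit, bounds, resolution: int = 50) -> DecisionGrid:
    """Probability surface of a two-feature model on a uniform grid.

    ``bounds`` is ((x_min, x_max), (y_min, y_max)) covering the observed
    feature ranges.  The P >= 0.5 region is bounded by the straight line
    where the linear predictor is zero.
    """
    if len(fit.weights) != 2:
        raise ValueError("decision grid requires a model with exactly 2 features")
    (x0, x1), (y0, y1) = bounds
    gx = np.linspace(x0, x1, resolution)
    gy = np.linspace(y0, y1, resolution)
    XX, YY = np.meshgrid(gx, gy)
    P = fit.predict_proba(np.column_stack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    return DecisionGrid(
        feature_names=list(fit.feature_names), x=gx, y=gy, P=P, region=P >= 0.5
    )


def evaluate_combinations(
    table: pd.DataFrame,
    labels,
    allowed: list[tuple[str, ...]],
    cv_folds: int = 0,
    cv_seed: int = 0,
) -> dict:
    """Fit and ROC-score each allowed feature combination on the full cohort.

    Returns combo -> {auc, roc, fit, (cv_auc)}.  Evaluation is in-sample by
    design; pass ``cv_folds > 1`` for an additional stratified
    cross-validated AUC, reported separately and labelled as such.
    """
    y = encode_labels(labels)
    results = {}
    for combo in allowed:
        X = table[list(combo)].to_numpy(dtype=float)
        fit = fit_logistic(X, y, feature_names=list(combo))
        keep = np.all(np.isfinite(X), axis=1)
        roc = roc_auc(fit.probabilities, y[keep], feature_set=list(combo),
                      coefficients=fit.coefficients)
        entry = {"auc": roc.auc, "roc": roc, "fit": fit}
        if cv_folds > 1:
            entry["cv_auc"] = _cv_auc(X[keep], y[keep], cv_folds, cv_seed)
        results[combo] = entry
    return results


def _cv_auc(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """Stratified k-fold out-of-sample AUC (non-replicative extension)."""
    rng = np.random.default_rng(seed)
    idx_pos = rng.permutation(np.flatnonzero(y == 1))
    idx_neg = rng.permutation(np.flatnonzero(y == 0))
    prob = np.full(len(y), np.nan)
    for k in range(folds):
        test = np.concatenate([idx_pos[k::folds], idx_neg[k::folds]])
        train = np.setdiff1d(np.arange(len(y)), test)
        if len(np.unique(y[train])) < 2:
            continue
        fit = fit_logistic(X[train], y[train])
        prob[test] = fit.predict_proba(X[test])
    ok = np.isfinite(prob)
    return roc_auc(prob[ok], y[ok]).auc
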