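"""End-to-end orchestration: simulate/load -> features -> surrogate test ->
group statistics -> correlations -> classification.

`run_pipeline` is a pure function of its configuration: all randomness is
seeded from ``config.seed`` and two runs with the same config produce
byte-identical report files.  Outputs: the per-subject feature table (CSV)
plus JSON reports for the surrogate determinism test, group statistics
(demographics + ANCOVA + post hoc), feature/ASRS correlations, and the
classifier (ROC points, AUCs, coefficients, decision grids).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from hippus import io
from hippus.classify import decision_grid, encode_labels, evaluate_combinations
from hippus.features import build_feature_table
from hippus.iaaft import SurrogateParams, surrogate_test
from hippus.sampen import SampEnParams
from hippus.stats import (
    ancova_group_age,
    chi_square_2x2,
    correlation_matrix,
    multicollinearity_gate,
    pearson_r,
    two_sample_t,
)
from hippus.synthetic import CohortSpec, adhd_preset, td_preset
from hippus.tranen import TranEnParams

log = logging.getLogger(__name__)

FEATURES = ("size_mm", "sampen", "tranen")


@dataclass
class PipelineConfig:
    """All pipeline parameters with their standard defaults."""

    epoch_len_s: float = 5.0
    cutoff_hz: float = 50.0
    max_missing_frac: float = 0.5
    sampen_m: int = 2
    sampen_r: float = 0.2
    tranen_tau: int = 10
    tranen_dim: int = 5
    tranen_bins: int = 3
    iaaft_n_iter: int = 50
    iaaft_n_surr: int = 10
    collinearity_threshold: float = 0.8
    alpha: float = 0.05
    seed: int = 0
    # simulation settings (used when no input directory is given)
    n_td: int = 20
    n_adhd: int = 16
    duration_s: float = 120.0
    fs: float = 300.0
    input_dir: str | None = None
    out_dir: str = "results"
    run_surrogates: bool = True
    cv_folds: int = 0

    def validate(self) -> None:
        if not self.sampen_r > 0:
            raise ValueError("sampen_r must be positive")
        if self.sampen_m < 1 or self.tranen_tau < 1 or self.tranen_dim < 1:
            raise ValueError("embedding parameters must be >= 1")
        if self.tranen_bins < 2:
            raise ValueError("tranen_bins must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.cutoff_hz <= 0 or self.epoch_len_s <= 0:
            raise ValueError("cutoff_hz and epoch_len_s must be positive")

    def sampen_params(self) -> SampEnParams:
        return SampEnParams(m=self.sampen_m, r=self.sampen_r)

    def tranen_params(self) -> TranEnParams:
        return TranEnParams(tau=self.tranen_tau, dx=self.tranen_dim,
                            dy=self.tranen_dim, n_bins=self.tranen_bins)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True) + "\n")


def _group_stats(table: pd.DataFrame, alpha: float) -> dict:
    """Demographics (t / chi-square) and per-feature ANCOVA for each pair of
    groups present in the cohort."""
    out: dict = {"alpha": alpha, "contrasts": {}}
    groups = sorted(table["group"].unique())
    for ga, gb in combinations(groups, 2):
        sub = table[table["group"].isin([ga, gb])]
        key = f"{ga}_vs_{gb}"
        entry: dict = {}
        a_age = sub.loc[sub["group"] == ga, "age"]
        b_age = sub.loc[sub["group"] == gb, "age"]
        t_age, p_age = two_sample_t(a_age, b_age)
        entry["age_t"] = {"t": t_age, "p": p_age}
        if "sex" in sub.columns:
            counts = pd.crosstab(sub["group"], sub["sex"])
            if counts.shape == (2, 2) and (counts.to_numpy().sum(axis=0) > 0).all():
                chi2, p_sex = chi_square_2x2(counts.to_numpy())
                entry["sex_chi2"] = {"chi2": chi2, "p": p_sex}
        for feat in FEATURES:
            ok = sub.dropna(subset=[feat])
            if ok.groupby("group").size().min() < 3:
                continue
            res = ancova_group_age(ok[feat], ok["group"], ok["age"])
            entry[feat] = {
                "F": res.F, "p": res.p, "eta_sq": res.eta_sq, "df": list(res.df),
                "adjusted_means": res.adjusted_means,
                "posthoc_t": res.posthoc_t, "posthoc_p": res.posthoc_p,
                "group_means": ok.groupby("group")[feat].mean().to_dict(),
                "group_sds": ok.groupby("group")[feat].std(ddof=1).to_dict(),
            }
        out["contrasts"][key] = entry
    return out


def _correlations(table: pd.DataFrame, threshold: float) -> dict:
    """Feature-feature correlation matrix (with the collinearity flag) and
    feature-ASRS correlations, per group pairing used downstream."""
    out: dict = {"threshold": threshold}
    cm = correlation_matrix(table.dropna(subset=list(FEATURES)), list(FEATURES), threshold)
    out["features"] = cm.to_dict()
    asrs_cols = [c for c in ("asrs_total", "asrs_in", "asrs_hyp_i") if c in table.columns]
    out["asrs"] = {}
    for feat in FEATURES:
        for score in asrs_cols:
            sub = table.dropna(subset=[feat, score])
            if len(sub) >= 3 and sub[feat].std() > 0 and sub[score].std() > 0:
                r, p = pearson_r(sub[feat], sub[score])
                out["asrs"][f"{feat}__{score}"] = {"R": r, "p": p}
    return out


def _classifier_report(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Gate-driven logistic-regression evaluation with decision grids for
    the two-feature models."""
    sub = table.dropna(subset=list(FEATURES))
    labels = sub["group"]
    if len(set(encode_labels(labels))) < 2:
        return {"skipped": "need both a TD-like and an ADHD-like group"}
    allowed = multicollinearity_gate(sub, FEATURES, config.collinearity_threshold)
    results = evaluate_combinations(sub, labels, allowed,
                                    cv_folds=config.cv_folds, cv_seed=config.seed)
    report: dict = {"allowed_combinations": ["+".join(c) for c in allowed],
                    "models": {}, "decision_grids": {}}
    for combo, entry in results.items():
        key = "+".join(combo)
        report["models"][key] = {
            "auc": entry["auc"],
            "coefficients": list(map(float, entry["fit"].coefficients)),
            "converged": entry["fit"].converged,
            "separation_flag": entry["fit"].separation_flag,
            "roc_points": entry["roc"].roc_points,
        }
        if "cv_auc" in entry:
            report["models"][key]["cv_auc"] = entry["cv_auc"]
        if len(combo) == 2:
            cols = sub[list(combo)].to_numpy(dtype=float)
            pad = 0.05 * (cols.max(axis=0) - cols.min(axis=0) + 1e-12)
            bounds = ((cols[:, 0].min() - pad[0], cols[:, 0].max() + pad[0]),
                      (cols[:, 1].min() - pad[1], cols[:, 1].max() + pad[1]))
            report["decision_grids"][key] = decision_grid(entry["fit"], bounds).to_dict()
    return report


def _load_cohort(config: PipelineConfig):
    d = Path(config.input_dir)
    meta = io.read_metadata(d / "metadata.csv")
    recs = []
    for sid in meta["subject_id"].astype(str):
        recs.append(io.read_recording(d / f"{sid}.csv", subject_id=sid))
    return recs, meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory results (feature table, reports).
    """
    config.validate()
    log.info("resolved config: %s", asdict(config))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        recordings, meta = _load_cohort(config)
    else:
        spec = CohortSpec(
            groups=[
                td_preset(config.n_td, duration_s=config.duration_s, fs=config.fs),
                adhd_preset(config.n_adhd, duration_s=config.duration_s, fs=config.fs),
            ],
            seed=config.seed,
        )
        recordings, meta = simulate_cohort_cached(spec)

    table, epochsets = build_feature_table(
        recordings, meta,
        epoch_len_s=config.epoch_len_s, cutoff_hz=config.cutoff_hz,
        max_missing_frac=config.max_missing_frac,
        sampen_params=config.sampen_params(),
        tranen_params=config.tranen_params(),
        return_epochsets=True,
    )
    io.write_feature_table(table, out / "features.csv")

    results: dict = {"feature_table": table}

    if config.run_surrogates:
        groups = dict(zip(table["subject_id"], table["group"]))
        surr: dict = {}
        for feat in ("sampen", "tranen"):
            original = dict(zip(table["subject_id"], table[feat]))
            rep = surrogate_test(
                epochsets, original, groups, feat,
                SurrogateParams(config.iaaft_n_iter, config.iaaft_n_surr, config.seed),
                config.sampen_params(), config.tranen_params(),
            )
            surr[feat] = rep.to_dict()
        _json_dump(surr, out / "surrogate_report.json")
        results["surrogates"] = surr

    stats_rep = _group_stats(table, config.alpha)
    _json_dump(stats_rep, out / "group_stats.json")
    results["group_stats"] = stats_rep

    corr_rep = _correlations(table, config.collinearity_threshold)
    _json_dump(corr_rep, out / "correlations.json")
    results["correlations"] = corr_rep

    cls_rep = _classifier_report(table, config)
    _json_dump(cls_rep, out / "classifier.json")
    results["classifier"] = cls_rep
    return results


def simulate_cohort_cached(spec: CohortSpec):
    # thin indirection kept so callers can monkeypatch cohort creation
    from hippus.synthetic import simulate_cohort

    return simulate_cohort(spec)
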