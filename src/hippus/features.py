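"""Per-subject feature assembly: baseline size, SampEn, TranEn.

Baseline size is the temporal mean diameter in raw millimetres (after gap
interpolation and filtering, whose DC gain is 1), averaged between the two
eyes and then across kept epochs.  The entropy features are computed on the
z-scored epochs by their own modules.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hippus.io import DataError, PupilRecording, FEATURE_COLUMNS
from hippus.preprocess import EpochSet, preprocess
from hippus.sampen import SampEnParams, epoch_average_sampen
from hippus.tranen import TranEnParams, epoch_average_tranen

log = logging.getLogger(__name__)

ALL_FEATURES = ("size", "sampen", "tranen")


def baseline_size(es: EpochSet) -> float:
    """Mean diameter (mm): per kept epoch the mean of the two eyes' temporal
    means, then the mean over kept epochs.  NaN when no epoch is kept."""
    if es.n_kept == 0:
        log.warning("%s: no kept epochs; size feature missing", es.subject_id)
        return float("nan")
    left_means = es.epochs_left[es.kept].mean(axis=1)
    right_means = es.epochs_right[es.kept].mean(axis=1)
    return float(np.mean(0.5 * (left_means + right_means)))


def compute_subject_features(
    rec: PupilRecording,
    epoch_len_s: float = 5.0,
    cutoff_hz: float = 50.0,
    max_missing_frac: float = 0.5,
    sampen_params: SampEnParams | None = None,
    tranen_params: TranEnParams | None = None,
    features: tuple[str, ...] = ALL_FEATURES,
) -> tuple[dict, EpochSet]:
    """Preprocess one recording and compute the requested features."""
    es = preprocess(rec, epoch_len_s, cutoff_hz, max_missing_frac)
    row: dict = {"subject_id": rec.subject_id, "n_epochs_kept": es.n_kept}
    if es.n_kept == 0:
        for f in features:
            row["size_mm" if f == "size" else f] = float("nan")
        return row, es
    if "size" in features:
        row["size_mm"] = baseline_size(es)
    if "sampen" in features:
        row["sampen"] = epoch_average_sampen(es, sampen_params or SampEnParams())
    if "tranen" in features:
        row["tranen"] = epoch_average_tranen(es, tranen_params or TranEnParams())
    return row, es


def build_feature_table(
    recordings: list[PupilRecording],
    meta: pd.DataFrame,
    epoch_len_s: float = 5.0,
    cutoff_hz: float = 50.0,
    max_missing_frac: float = 0.5,
    sampen_params: SampEnParams | None = None,
    tranen_params: TranEnParams | None = None,
    features: tuple[str, ...] = ALL_FEATURES,
    return_epochsets: bool = False,
):
    """Assemble the per-subject feature table for a cohort.

    ``meta`` must contain one row per recording subject (columns
    subject_id, group, age, sex, asrs_*).  Rows are ordered by subject_id
    so the output is invariant to the order recordings are supplied in.
    """
    meta_ids = set(meta["subject_id"].astype(str))
    rec_ids = [r.subject_id for r in recordings]
    missing = sorted(set(rec_ids) - meta_ids)
    if missing:
        raise DataError(f"recordings without metadata: {missing}")
    if len(set(rec_ids)) != len(rec_ids):
        raise DataError("duplicate subject_id among recordings")

    meta_idx = meta.astype({"subject_id": str}).set_index("subject_id")
    rows = []
    epochsets: dict[str, EpochSet] = {}
    for rec in sorted(recordings, key=lambda r: r.subject_id):
        row, es = compute_subject_features(
            rec, epoch_len_s, cutoff_hz, max_missing_frac,
            sampen_params, tranen_params, features,
        )
        m = meta_idx.loc[rec.subject_id]
        for col in ("group", "age", "sex", "asrs_total", "asrs_in", "asrs_hyp_i"):
            if col in meta_idx.columns:
                row[col] = m[col]
        log.info("%s: %d epochs kept", rec.subject_id, row["n_epochs_kept"])
        rows.append(row)
        epochsets[rec.subject_id] = es
    table = pd.DataFrame(rows)
    table = table[[c for c in FEATURE_COLUMNS if c in table.columns]]
    if return_epochsets:
        return table, epochsets
    return table
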