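"""Reading and writing recordings, metadata and feature tables.

All file formats are delimited text (CSV/TSV) with a header row.  Units are
fixed: diameters in millimetres, time in seconds.  Missing diameter samples
are represented internally as NaN with the matching validity flag set to
False; on disk an empty cell, the string ``NaN`` or any non-positive
diameter is treated as missing (a pupil diameter is strictly positive, so a
non-positive value can only be a sentinel).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROUPS = ("TD", "ADHD", "drug-naive-ADHD")

#: default column names for recording files
DEFAULT_DIALECT = {
    "time": "time_s",
    "left": "left_mm",
    "right": "right_mm",
    "valid_left": "valid_left",
    "valid_right": "valid_right",
}

FEATURE_COLUMNS = [
    "subject_id", "group", "age", "sex",
    "asrs_total", "asrs_in", "asrs_hyp_i",
    "size_mm", "sampen", "tranen", "n_epochs_kept",
]


class FormatError(ValueError):
    """File structure cannot be mapped onto the expected schema."""


class DataError(ValueError):
    """File parsed but its content violates an invariant."""


@dataclass
class PupilRecording:
    """Two-channel pupil-diameter time series.

    Attributes
    ----------
    subject_id : str
    fs : float
        Sampling rate in Hz (nominally 300).
    t : ndarray
        Timestamps in seconds, uniformly spaced at 1/fs, strictly increasing.
    left, right : ndarray
        Diameters in mm; missing samples are NaN.
    valid_left, valid_right : ndarray of bool
        False exactly where the corresponding diameter is missing.
    """

    subject_id: str
    fs: float
    t: np.ndarray
    left: np.ndarray
    right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.valid_left = np.asarray(self.valid_left, dtype=bool)
        self.valid_right = np.asarray(self.valid_right, dtype=bool)
        n = len(self.t)
        if n < 1:
            raise DataError("recording must contain at least one sample")
        for name in ("left", "right", "valid_left", "valid_right"):
            if len(getattr(self, name)) != n:
                raise DataError(f"length of {name} does not match timestamps")
        if not self.fs > 0:
            raise DataError("sampling rate must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError("timestamps must be strictly increasing")
        # enforce the missing<->invalid correspondence in both directions
        self.left[~self.valid_left] = np.nan
        self.right[~self.valid_right] = np.nan
        self.valid_left &= np.isfinite(self.left)
        self.valid_right &= np.isfinite(self.right)
        self.left[~self.valid_left] = np.nan
        self.right[~self.valid_right] = np.nan

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SubjectMeta:
    """Per-subject metadata: group label, demographics and ASRS scores."""

    subject_id: str
    group: str
    age: float
    sex: str
    asrs_total: int = 0
    asrs_in: int = 0
    asrs_hyp_i: int = 0

    def __post_init__(self) -> None:
        if min(self.asrs_total, self.asrs_in, self.asrs_hyp_i) < 0:
            raise DataError("ASRS scores must be non-negative")


def _to_missing(values: pd.Series) -> np.ndarray:
    """Map the on-disk missing markers (empty, NaN, diameter <= 0) to NaN."""
    x = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    x[x <= 0] = np.nan
    return x


def read_recording(
    path: str | Path,
    dialect: dict | None = None,
    subject_id: str | None = None,
    fs: float | None = None,
) -> PupilRecording:
    """Read a delimited-text recording.

    Parameters
    ----------
    path : path to a CSV/TSV file with a header row.
    dialect : optional mapping with keys ``time``, ``left``, ``right`` and
        optionally ``valid_left``/``valid_right``, giving the column names
        used in the file.  Defaults to :data:`DEFAULT_DIALECT`.
    subject_id : defaults to the file stem.
    fs : declared sampling rate in Hz.  If omitted it is inferred from the
        median timestamp spacing; if supplied and deviating by more than 1%
        from the inferred rate, a warning is logged and the declared rate
        is kept.
    """
    path = Path(path)
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep=None, engine="python")
    for key in ("time", "left", "right"):
        if d[key] not in df.columns:
            raise FormatError(
                f"column {d[key]!r} (for {key}) not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
    t = pd.to_numeric(df[d["time"]], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise DataError("non-numeric timestamps")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise DataError("timestamps are not strictly increasing")

    left = _to_missing(df[d["left"]])
    right = _to_missing(df[d["right"]])
    valid_left = np.isfinite(left)
    valid_right = np.isfinite(right)
    for key, valid in (("valid_left", valid_left), ("valid_right", valid_right)):
        col = d.get(key)
        if col is not None and col in df.columns:
            flags = pd.to_numeric(df[col], errors="coerce").fillna(0).to_numpy()
            valid &= flags.astype(bool)
    left[~valid_left] = np.nan
    right[~valid_right] = np.nan

    inferred = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else (fs or 1.0)
    if fs is None:
        fs = inferred
    elif abs(fs - inferred) / fs > 0.01:
        log.warning(
            "%s: declared fs=%.6g Hz deviates >1%% from inferred %.6g Hz",
            path.name, fs, inferred,
        )
        warnings.warn(
            f"declared fs {fs:g} Hz deviates >1% from inferred {inferred:g} Hz",
            stacklevel=2,
        )
    return PupilRecording(
        subject_id=subject_id or path.stem,
        fs=float(fs),
        t=t,
        left=left,
        right=right,
        valid_left=valid_left,
        valid_right=valid_right,
    )


def write_recording(rec: PupilRecording, path: str | Path) -> None:
    """Write a recording using the default dialect; missing samples as empty cells."""
    df = pd.DataFrame(
        {
            "time_s": rec.t,
            "left_mm": rec.left,
            "right_mm": rec.right,
            "valid_left": rec.valid_left.astype(int),
            "valid_right": rec.valid_right.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the subject metadata table (one row per subject)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise DataError(f"duplicate subject_id in metadata: {dupes}")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def write_feature_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the per-subject feature table; missing features become empty cells."""
    if len(rows) == 0:
        raise DataError("feature table is empty")
    if rows["subject_id"].duplicated().any():
        dupes = rows.loc[rows["subject_id"].duplicated(), "subject_id"].tolist()
        raise DataError(f"duplicate subject_id: {dupes}")
    cols = [c for c in FEATURE_COLUMNS if c in rows.columns]
    cols += [c for c in rows.columns if c not in cols]
    rows[cols].to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    if "subject_id" not in df.columns:
        raise FormatError("feature table missing subject_id column")
    if df["subject_id"].duplicated().any():
        raise DataError("duplicate subject_id in feature table")
    return df
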