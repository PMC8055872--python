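"""Epoching, gap interpolation, low-pass filtering and z-scoring.

A recording is split into consecutive non-overlapping epochs (default 5 s),
missing samples inside an epoch are linearly interpolated, each epoch is
zero-phase low-pass filtered (0–50 Hz) and, for the entropy features,
normalized to zero mean and unit variance per epoch.  Epochs whose missing
fraction exceeds ``max_missing_frac`` in either eye (or that are entirely
missing) are flagged ``kept=False`` and excluded downstream: entropy
estimated from mostly-interpolated data would reflect the interpolant, not
the pupil.

Filtering is applied forward and backward (``scipy.signal.filtfilt``) so the
two eyes acquire no relative phase lag — phase distortion would create
artifactual left->right directionality in the transfer-entropy stage.  The
Butterworth design frequency is pre-warped so that the combined two-pass
response is -3 dB at the nominal cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from hippus.io import PupilRecording

_BUTTER_ORDER = 4
# single-pass gain g at the nominal cutoff such that g^2 = 1/sqrt(2):
# (f_c/f_design)^(2n) = sqrt(2) - 1  =>  f_design = f_c / (sqrt(2)-1)^(1/(2n))
_WARP = (np.sqrt(2.0) - 1.0) ** (-1.0 / (2 * _BUTTER_ORDER))


@dataclass
class EpochSet:
    """Preprocessed fixed-length segments for both eyes of one subject.

    ``epochs_*`` hold raw millimetres after interpolation and filtering
    (the input for baseline size); ``zscored_*`` hold the per-epoch
    normalized versions (the input for the entropy features).
    """

    subject_id: str
    fs: float
    epoch_len_s: float
    epochs_left: np.ndarray      # (n_epochs, n_samples)
    epochs_right: np.ndarray
    zscored_left: np.ndarray
    zscored_right: np.ndarray
    missing_frac_left: np.ndarray
    missing_frac_right: np.ndarray
    kept: np.ndarray             # bool per epoch
    degenerate_left: np.ndarray = field(default=None)  # constant raw epoch
    degenerate_right: np.ndarray = field(default=None)

    @property
    def n_epochs(self) -> int:
        return self.epochs_left.shape[0]

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.kept))


def segment(rec: PupilRecording, epoch_len_s: float = 5.0) -> dict:
    """Cut a recording into non-overlapping epochs anchored at its start.

    Returns a dict with raw (possibly NaN-containing) per-eye epoch arrays
    and the per-epoch missing fraction recorded *before* interpolation.
    A trailing partial window is discarded.
    """
    n_per = int(round(rec.fs * epoch_len_s))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.3g} s is shorter than one "
            f"{epoch_len_s:g} s epoch"
        )
    n_used = n_epochs * n_per
    left = rec.left[:n_used].reshape(n_epochs, n_per).copy()
    right = rec.right[:n_used].reshape(n_epochs, n_per).copy()
    return {
        "left": left,
        "right": right,
        "missing_frac_left": np.mean(np.isnan(left), axis=1),
        "missing_frac_right": np.mean(np.isnan(right), axis=1),
        "n_epochs": n_epochs,
        "n_per_epoch": n_per,
    }


def interpolate_missing(epoch: np.ndarray) -> np.ndarray | None:
    """Fill NaN gaps by linear interpolation; hold edges at the nearest value.

    Returns ``None`` when the epoch has no valid sample at all (the caller
    marks it not kept rather than raising).
    """
    x = np.asarray(epoch, dtype=float)
    valid = np.isfinite(x)
    if not valid.any():
        return None
    if valid.all():
        return x.copy()
    idx = np.arange(len(x))
    # np.interp holds the boundary values for out-of-range queries
    return np.interp(idx, idx[valid], x[valid])


def lowpass(epoch: np.ndarray, fs: float, cutoff: float = 50.0) -> np.ndarray:
    """Zero-phase Butterworth low-pass with -3 dB at ``cutoff``.

    DC gain is exactly 1; at frequencies >= 2*cutoff the residual amplitude
    is below 1% of the passband.
    """
    if cutoff * _WARP >= fs / 2:
        raise ValueError(
            f"cutoff {cutoff:g} Hz too close to Nyquist ({fs / 2:g} Hz)"
        )
    x = np.asarray(epoch, dtype=float)
    sos = signal.butter(_BUTTER_ORDER, cutoff * _WARP, btype="low", fs=fs, output="sos")
    padlen = min(3 * 2 * _BUTTER_ORDER, len(x) - 1)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def zscore(epoch: np.ndarray) -> tuple[np.ndarray, bool]:
    """(x - mean)/sd; a constant epoch maps to all zeros, flagged degenerate."""
    x = np.asarray(epoch, dtype=float)
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x), True
    return (x - mu) / sd, False


def preprocess(
    rec: PupilRecording,
    epoch_len_s: float = 5.0,
    cutoff_hz: float = 50.0,
    max_missing_frac: float = 0.5,
) -> EpochSet:
    """Full preprocessing: segment -> interpolate -> low-pass -> z-score."""
    seg = segment(rec, epoch_len_s)
    n_epochs, n_per = seg["n_epochs"], seg["n_per_epoch"]
    out = {}
    degenerate = {}
    all_missing = np.zeros(n_epochs, dtype=bool)
    for eye in ("left", "right"):
        raw = np.empty((n_epochs, n_per))
        z = np.empty((n_epochs, n_per))
        degen = np.zeros(n_epochs, dtype=bool)
        for k in range(n_epochs):
            filled = interpolate_missing(seg[eye][k])
            if filled is None:
                raw[k] = np.nan
                z[k] = np.nan
                all_missing[k] = True
                continue
            raw[k] = lowpass(filled, rec.fs, cutoff_hz)
            z[k], degen[k] = zscore(raw[k])
        out[eye] = raw
        out["z_" + eye] = z
        degenerate[eye] = degen

    kept = (
        ~all_missing
        & (seg["missing_frac_left"] <= max_missing_frac)
        & (seg["missing_frac_right"] <= max_missing_frac)
    )
    return EpochSet(
        subject_id=rec.subject_id,
        fs=rec.fs,
        epoch_len_s=epoch_len_s,
        epochs_left=out["left"],
        epochs_right=out["right"],
        zscored_left=out["z_left"],
        zscored_right=out["z_right"],
        missing_frac_left=seg["missing_frac_left"],
        missing_frac_right=seg["missing_frac_right"],
        kept=kept,
        degenerate_left=degenerate["left"],
        degenerate_right=degenerate["right"],
    )
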