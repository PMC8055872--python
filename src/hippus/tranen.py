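"""Transfer entropy (TranEn) between left and right pupil series.

The directed transfer entropy from X to Y,

    T_{X->Y} = sum p(y_{t+tau}, y_t^{dy}, x_t^{dx})
               * ln[ p(y_{t+tau} | y_t^{dy}, x_t^{dx}) / p(y_{t+tau} | y_t^{dy}) ],

quantifies how much the past of X reduces uncertainty about the future of
Y beyond Y's own past.  The delay vectors x_t^{dx} = (x_t, x_{t-tau}, ...,
x_{t-(dx-1)tau}) use the same lag tau as the prediction horizon.  Defaults
follow the hippus setting: tau = 10 samples (0.033 s at 300 Hz, well faster
than the 2 Hz upper edge of hippus), dx = dy = 5.

Probabilities are estimated by plug-in relative frequencies over an
equiquantal (tertile, Q = 3) discretization of each z-scored epoch.  The
plug-in estimate is the conditional mutual information of the empirical
distribution, hence always >= 0; with ~1.5e3 embedded points and an
11-dimensional joint state it is biased upward, but the bias is shared by
every comparison made with it (original vs surrogate, group contrasts).
Symmetricity of the two eyes is the mean of the two directions, averaged
over epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hippus.preprocess import EpochSet

log = logging.getLogger(__name__)


@dataclass
class TranEnParams:
    tau: int = 10
    dx: int = 5
    dy: int = 5
    n_bins: int = 3
    log_base: float = np.e

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")
        if self.dx < 1 or self.dy < 1:
            raise ValueError("embedding dimensions must be >= 1")
        if self.n_bins < 2:
            raise ValueError("need at least 2 discretization levels")


@dataclass
class TranEnResult:
    te_xy: float
    te_yx: float
    n_samples: int
    degenerate: bool = False

    @property
    def te_mean(self) -> float:
        return 0.5 * (self.te_xy + self.te_yx)


def discretize(x: np.ndarray, q: int = 3) -> tuple[np.ndarray, bool]:
    """Equiquantal symbolization to levels 0..q-1.

    Each sample's symbol is determined by its lower rank (the number of
    values strictly below it), so the mapping is invariant under any
    strictly increasing transform and ties always share a symbol.  A
    constant segment maps to all zeros with the degeneracy flag set.
    """
    x = np.asarray(x, dtype=float)
    if q < 2:
        raise ValueError("need at least 2 levels")
    if len(x) < q:
        raise ValueError(f"segment of length {len(x)} shorter than Q={q}")
    if np.all(x == x[0]):
        return np.zeros(len(x), dtype=np.int64), True
    sx = np.sort(x)
    low_rank = np.searchsorted(sx, x, side="left")
    sym = np.minimum((low_rank * q) // len(x), q - 1).astype(np.int64)
    return sym, False


def _entropy_from_codes(codes: np.ndarray) -> float:
    """Plug-in Shannon entropy (nats) of an integer code sequence."""
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _embed_codes(s: np.ndarray, d: int, tau: int, t_idx: np.ndarray, q: int) -> np.ndarray:
    """Integer-encode the d-dimensional delay vector s_t = (s_t, s_{t-tau}, ...)."""
    code = np.zeros(len(t_idx), dtype=np.int64)
    for k in range(d):
        code = code * q + s[t_idx - k * tau]
    return code


def transfer_entropy(
    sx: np.ndarray, sy: np.ndarray, params: TranEnParams | None = None
) -> float:
    """Plug-in transfer entropy X -> Y (in units of ``log_base``) from
    symbol sequences.

    Evaluated through the entropy identity
    T = H(y+, ypast) + H(ypast, xpast) - H(ypast) - H(y+, ypast, xpast),
    equivalent to the conditional-probability sum with 0*log(.) := 0.
    """
    p = params or TranEnParams()
    sx = np.asarray(sx, dtype=np.int64)
    sy = np.asarray(sy, dtype=np.int64)
    if sx.shape != sy.shape or sx.ndim != 1:
        raise ValueError("symbol sequences must be 1-D and of equal length")
    L = len(sx)
    t0 = (max(p.dx, p.dy) - 1) * p.tau
    t_idx = np.arange(t0, L - p.tau)
    if len(t_idx) < 1:
        raise ValueError(
            f"sequence of length {L} too short for tau={p.tau}, "
            f"dx={p.dx}, dy={p.dy}"
        )
    if np.all(sy == sy[0]):
        log.warning("degenerate target sequence (single symbol): TE set to 0")
        return 0.0
    q = int(max(sx.max(), sy.max())) + 1
    yp = _embed_codes(sy, p.dy, p.tau, t_idx, q)
    xp = _embed_codes(sx, p.dx, p.tau, t_idx, q)
    yf = sy[t_idx + p.tau]
    # joint codes; q**dx etc. stay far below 2**63 for the defaults
    c_yf_yp = yf * q ** p.dy + yp
    c_yp_xp = yp * q ** p.dx + xp
    c_all = c_yf_yp * q ** p.dx + xp
    te = (
        _entropy_from_codes(c_yf_yp)
        + _entropy_from_codes(c_yp_xp)
        - _entropy_from_codes(yp)
        - _entropy_from_codes(c_all)
    )
    te = max(te, 0.0)  # clip the ~1e-16 negatives from float cancellation
    return te if p.log_base == np.e else te / np.log(p.log_base)


def transfer_entropy_from_joint(joint: np.ndarray, log_base: float = np.e) -> float:
    """Transfer entropy evaluated on an *analytic* joint distribution.

    ``joint[y_next, y_past_state, x_past_state]`` holds exact probabilities
    (summing to 1).  The conditional-probability sum is evaluated directly,
    with zero-probability configurations contributing zero, so an exactly
    factorized (independent) distribution yields exactly 0.0.
    """
    joint = np.asarray(joint, dtype=float)
    if joint.ndim != 3:
        raise ValueError("joint must have axes (y_next, y_past, x_past)")
    if not np.isclose(joint.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    p_yp_xp = joint.sum(axis=0)           # (y_past, x_past)
    p_yf_yp = joint.sum(axis=2)           # (y_next, y_past)
    p_yp = joint.sum(axis=(0, 2))         # (y_past,)
    te = 0.0
    ny, nyp, nxp = joint.shape
    for yf in range(ny):
        for ypast in range(nyp):
            for xpast in range(nxp):
                pj = joint[yf, ypast, xpast]
                if pj == 0.0:
                    continue
                cond_full = pj / p_yp_xp[ypast, xpast]
                cond_y = p_yf_yp[yf, ypast] / p_yp[ypast]
                te += pj * np.log(cond_full / cond_y)
    return te / np.log(log_base)


def epoch_transfer_entropy(
    zx: np.ndarray, zy: np.ndarray, params: TranEnParams | None = None
) -> TranEnResult:
    """Both directed TEs between two z-scored epochs (discretize + estimate)."""
    p = params or TranEnParams()
    sx, dgx = discretize(zx, p.n_bins)
    sy, dgy = discretize(zy, p.n_bins)
    t0 = (max(p.dx, p.dy) - 1) * p.tau
    n = len(sx) - p.tau - t0
    return TranEnResult(
        te_xy=transfer_entropy(sx, sy, p),
        te_yx=transfer_entropy(sy, sx, p),
        n_samples=n,
        degenerate=dgx or dgy,
    )


def epoch_average_tranen(es: EpochSet, params: TranEnParams | None = None) -> float:
    """Subject-level TranEn: per kept epoch the mean of left->right and
    right->left, then the mean over kept epochs.  NaN when no epoch is kept."""
    p = params or TranEnParams()
    vals = []
    for k in range(es.n_epochs):
        if not es.kept[k]:
            continue
        res = epoch_transfer_entropy(es.zscored_left[k], es.zscored_right[k], p)
        vals.append(res.te_mean)
    if not vals:
        log.warning("%s: no kept epochs; TranEn feature missing", es.subject_id)
        return float("nan")
    return float(np.mean(vals))
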