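"""Sample entropy (SampEn) of z-scored pupil-diameter epochs.

SampEn(m, r) is the negative natural logarithm of the conditional
probability that two delay-1 template vectors matching within tolerance
``r`` (Chebyshev norm, strict inequality) at length ``m`` also match at
length ``m + 1``:

    h(r, m) = -ln(A / B)

where B and A count ordered template pairs (i != j) matching at lengths m
and m + 1.  Both counts run over the same template range i = 1..N-m so that
every length-m template has a length-(m+1) extension; this guarantees
A <= B and hence h >= 0, and is the convention of the classical PhysioNet
reference implementation.  Defaults r = 0.2 (in z-scored units) and m = 2.
A regular signal (every length-m match extends) gives h = 0; broadband
noise gives large h.

The O(N^2) pair count is exact; the kernel prunes pairs by sorting on the
first template coordinate, which changes nothing about the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from hippus.preprocess import EpochSet

log = logging.getLogger(__name__)


@dataclass
class SampEnParams:
    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not self.r > 0:
            raise ValueError("tolerance r must be positive")


@dataclass
class SampEnResult:
    """SampEn value in nats plus the underlying pair counts.

    ``h`` is NaN (with ``defined=False``) when either count is zero; such
    epochs are excluded from averaging rather than imputed.
    """

    h: float
    counts_m: int       # B: ordered pairs matching at length m
    counts_m1: int      # A: ordered pairs matching at length m+1
    n_templates: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.h)


@njit(cache=True)
def _pair_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Count unordered template pairs matching at lengths m and m+1.

    Templates are x[i:i+m] for i = 0..n-m-1; a pair matches when the
    Chebyshev distance is strictly below r.  Pairs are enumerated in order
    of the first coordinate so the inner loop can stop once the first
    coordinates alone differ by >= r.
    """
    n = x.shape[0]
    nt = n - m
    first = x[:nt].copy()
    order = np.argsort(first)
    b = 0
    a = 0
    for ii in range(nt - 1):
        i = order[ii]
        xi0 = x[i]
        for jj in range(ii + 1, nt):
            j = order[jj]
            if x[j] - xi0 >= r:
                break
            d = 0.0
            for k in range(1, m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
            if d < r:
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    return b, a


def sample_entropy(x: np.ndarray, params: SampEnParams | None = None) -> SampEnResult:
    """SampEn of a (z-scored) segment.

    Raises on non-finite input or on segments too short to form a single
    length-(m+1) template.
    """
    p = params or SampEnParams()
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("input must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if len(x) <= p.m + 1:
        raise ValueError(f"segment of length {len(x)} too short for m={p.m}")
    b, a = _pair_counts(x, p.m, p.r)
    # ordered pairs double the unordered counts; the ratio is unchanged
    b2, a2 = 2 * b, 2 * a
    if a2 == 0 or b2 == 0:
        h = np.nan
    else:
        h = -np.log(a2 / b2) + 0.0  # +0.0 normalizes -0.0 when A == B
    return SampEnResult(h=float(h), counts_m=b2, counts_m1=a2, n_templates=len(x) - p.m)


def epoch_average_sampen(es: EpochSet, params: SampEnParams | None = None) -> float:
    """Subject-level SampEn: mean over kept, defined epochs per eye, then
    the mean of the two eye values.  NaN when either eye has no defined
    epoch (logged)."""
    p = params or SampEnParams()
    eye_means = []
    for eye, z in (("left", es.zscored_left), ("right", es.zscored_right)):
        vals = []
        for k in range(es.n_epochs):
            if not es.kept[k]:
                continue
            res = sample_entropy(z[k], p)
            if res.defined:
                vals.append(res.h)
            else:
                log.warning(
                    "%s %s epoch %d: SampEn undefined (zero pair count), excluded",
                    es.subject_id, eye, k,
                )
        if not vals:
            log.warning("%s %s: no defined SampEn epoch; feature missing", es.subject_id, eye)
            return float("nan")
        eye_means.append(float(np.mean(vals)))
    return float(np.mean(eye_means))
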