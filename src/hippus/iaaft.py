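"""IAAFT surrogates and the original-vs-surrogate determinism test.

An iterative amplitude-adjusted Fourier transform (IAAFT) surrogate
preserves a series' amplitude distribution exactly and its power spectrum
approximately while destroying any nonlinear / deterministic temporal
structure.  Starting from a random permutation of the original values the
algorithm alternates (a) imposing the original Fourier amplitude spectrum
while keeping current phases, and (b) rank-remapping the result onto the
original sorted values, for ``n_iter`` iterations (default 50), ending on
the rank step so the value multiset is exact.

The determinism test recomputes SampEn/TranEn on ``n_surr`` (default 10)
independently seeded surrogates of every kept epoch and compares the
surrogate-mean feature with the original by a paired t-test within each
group: if pupil fluctuations carry deterministic structure, surrogates
destroy it and both entropies rise.

Surrogates are generated per epoch and per eye, independently across
channels: single-channel IAAFT does not preserve cross-channel phase
relations, so the surrogate null also breaks genuine left<->right coupling,
which is what the TranEn comparison requires.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from hippus.preprocess import EpochSet, zscore
from hippus.sampen import SampEnParams, sample_entropy
from hippus.tranen import TranEnParams, epoch_transfer_entropy

log = logging.getLogger(__name__)


@dataclass
class SurrogateParams:
    n_iter: int = 50
    n_surr: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.n_surr < 1:
            raise ValueError("n_iter and n_surr must be >= 1")


def iaaft_surrogate(
    x: np.ndarray, n_iter: int = 50, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One IAAFT surrogate of ``x`` (same length, same value multiset)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if len(x) < 4:
        raise ValueError("segment too short for a meaningful surrogate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    s = rng.permutation(x)
    for _ in range(n_iter):
        spec = np.fft.rfft(s)
        phases = np.angle(spec)
        s = np.fft.irfft(target_amp * np.exp(1j * phases), n=len(x))
        ranks = np.argsort(np.argsort(s))
        s = sorted_x[ranks]
    return s


def spectral_mismatch(x: np.ndarray, surrogate: np.ndarray) -> float:
    """Relative L2 distance between amplitude spectra (0 = identical)."""
    ax = np.abs(np.fft.rfft(x))
    asur = np.abs(np.fft.rfft(surrogate))
    return float(np.linalg.norm(asur - ax) / np.linalg.norm(ax))


def _epoch_seed(base_seed: int, subject_id: str, eye: str, epoch: int, k: int) -> np.random.Generator:
    """Deterministic per-(subject, eye, epoch, surrogate) generator."""
    tag = zlib.crc32(f"{subject_id}|{eye}|{epoch}|{k}".encode())
    return np.random.default_rng(np.random.SeedSequence([base_seed & 0x7FFFFFFF, tag]))


def paired_t(original: np.ndarray, other: np.ndarray) -> tuple[float, float, bool]:
    """Two-tailed paired t-test; returns (t, p, degenerate_sd_flag).

    A zero-variance, zero-mean difference gives (0, 1); a zero-variance
    nonzero shift is flagged with p reported as 0.0 (|t| unbounded).
    """
    d = np.asarray(other, dtype=float) - np.asarray(original, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, 1.0, False
        return float(np.inf) * np.sign(d.mean()), 0.0, True
    t, p = sps.ttest_rel(other, original)
    return float(t), float(p), False


@dataclass
class SurrogateReport:
    """Original vs surrogate-mean feature values and per-group paired tests."""

    feature: str
    params: SurrogateParams
    subjects: list = field(default_factory=list)      # per-subject dicts
    groups: dict = field(default_factory=dict)        # group -> test summary

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "n_iter": self.params.n_iter,
            "n_surr": self.params.n_surr,
            "subjects": self.subjects,
            "groups": self.groups,
        }


def _surrogate_feature(
    es: EpochSet,
    feature: str,
    params: SurrogateParams,
    sampen_params: SampEnParams,
    tranen_params: TranEnParams,
) -> float:
    """Recompute one subject's feature on IAAFT-surrogated epochs.

    For each kept epoch, ``n_surr`` surrogates of each eye's preprocessed
    (raw-mm) epoch are drawn, re-z-scored and fed through the identical
    feature path; averaging is surrogates -> (feature's own rule)."""
    vals_per_surr = []
    for k_surr in range(params.n_surr):
        if feature == "sampen":
            eye_means = []
            for eye, raw in (("left", es.epochs_left), ("right", es.epochs_right)):
                ep_vals = []
                for k in range(es.n_epochs):
                    if not es.kept[k]:
                        continue
                    rng = _epoch_seed(params.seed, es.subject_id, eye, k, k_surr)
                    z, _ = zscore(iaaft_surrogate(raw[k], params.n_iter, rng))
                    res = sample_entropy(z, sampen_params)
                    if res.defined:
                        ep_vals.append(res.h)
                if not ep_vals:
                    return float("nan")
                eye_means.append(np.mean(ep_vals))
            vals_per_surr.append(float(np.mean(eye_means)))
        elif feature == "tranen":
            ep_vals = []
            for k in range(es.n_epochs):
                if not es.kept[k]:
                    continue
                rng_l = _epoch_seed(params.seed, es.subject_id, "left", k, k_surr)
                rng_r = _epoch_seed(params.seed, es.subject_id, "right", k, k_surr)
                zl, _ = zscore(iaaft_surrogate(es.epochs_left[k], params.n_iter, rng_l))
                zr, _ = zscore(iaaft_surrogate(es.epochs_right[k], params.n_iter, rng_r))
                ep_vals.append(epoch_transfer_entropy(zl, zr, tranen_params).te_mean)
            if not ep_vals:
                return float("nan")
            vals_per_surr.append(float(np.mean(ep_vals)))
        else:
            raise ValueError(f"unknown feature {feature!r}")
    return float(np.mean(vals_per_surr))


def surrogate_test(
    epochsets: dict[str, EpochSet],
    original: dict[str, float],
    groups: dict[str, str],
    feature: str,
    params: SurrogateParams | None = None,
    sampen_params: SampEnParams | None = None,
    tranen_params: TranEnParams | None = None,
) -> SurrogateReport:
    """Original-vs-surrogate paired comparison of one entropy feature.

    Parameters
    ----------
    epochsets : subject_id -> preprocessed EpochSet
    original : subject_id -> original feature value (from the feature table)
    groups : subject_id -> group label
    feature : "sampen" or "tranen"
    """
    params = params or SurrogateParams()
    sampen_params = sampen_params or SampEnParams()
    tranen_params = tranen_params or TranEnParams()
    report = SurrogateReport(feature=feature, params=params)
    by_group: dict[str, list[tuple[float, float]]] = {}
    for sid, es in epochsets.items():
        orig = original.get(sid, float("nan"))
        if not np.isfinite(orig):
            log.warning("%s: original %s undefined; dropped from surrogate test", sid, feature)
            continue
        surr = _surrogate_feature(es, feature, params, sampen_params, tranen_params)
        report.subjects.append(
            {"subject_id": sid, "group": groups[sid], "original": orig, "surrogate_mean": surr}
        )
        if np.isfinite(surr):
            by_group.setdefault(groups[sid], []).append((orig, surr))
    for g, pairs in by_group.items():
        if len(pairs) < 2:
            log.warning("group %s: fewer than 2 complete pairs; test skipped", g)
            continue
        o = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs])
        t, p, degen = paired_t(o, s)
        report.groups[g] = {
            "n": len(pairs),
            "original_mean": float(o.mean()),
            "original_sd": float(o.std(ddof=1)),
            "surrogate_mean": float(s.mean()),
            "surrogate_sd": float(s.std(ddof=1)),
            "t": t,
            "p": p,
            "degenerate_sd": degen,
        }
    return report
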