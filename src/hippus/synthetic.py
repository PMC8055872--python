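"""Synthetic bilateral-hippus cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage can be exercised without clinical data:

* band-limited hippus fluctuations occupying 0.04-2.0 Hz;
* a group-dependent baseline diameter (subject baselines drawn from a
  truncated normal);
* a tunable regular-vs-complex drive mixture ``complexity_mix`` (lambda):
  each drive is sqrt(lambda) * broadband band-limited noise +
  sqrt(1-lambda) * a sinusoid with random phase and a frequency drawn
  per drive from 0.2-0.5 Hz (the slow-oscillation range of hippus), both
  unit variance, so lambda = 0 is a pure regular oscillation and
  lambda = 1 pure broadband noise.  A *fixed* common frequency would make
  even private drives correlate across eyes (two equal-frequency
  sinusoids correlate at cos of their phase difference, independent of
  duration), breaking the independence that coupling = 0 promises;
* a tunable left<->right coupling ``coupling`` (c): both eyes share a
  common drive with weight sqrt(c) next to private drives with weight
  sqrt(1-c), and the shared drive reaches the right eye
  ``cross_lag_samples`` later than the left so that the cross-channel
  dependence is genuinely time-asymmetric (a zero-lag common drive would
  leave transfer entropy with nothing but estimator bias to detect).
  For the delay embedding of the transfer-entropy stage (lag tau,
  dimension d) to capture the advance at all, the lag must lie within
  [tau, d*tau] samples; the default is d*tau = 50, which also keeps the
  shared-drive windows seen by source-past and target-past disjoint so
  the estimator bias stays stable across coupling levels.  At 300 Hz this
  is ~167 ms — far longer than any physiological inter-eye latency, a
  deliberate property of the surrogate generator, not of pupils;
* blink-like gaps, simultaneous in both eyes, from a Poisson process.

The generator is a statistical surrogate of hippus, not a physiological
pupil model; defaults give 120 s at 300 Hz.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from hippus.io import PupilRecording, write_recording, write_metadata

HIPPUS_BAND = (0.04, 2.0)
REGULAR_FREQ_BAND_HZ = (0.2, 0.5)


@dataclass
class GroupPreset:
    """Generator settings for one subject group.

    The TD-like and ADHD-like defaults take their baseline means/SDs (mm)
    and ASRS score distributions from the published group descriptives;
    the complexity-mix and coupling values are calibrated only to
    reproduce the reported *directions* of group effects (ADHD-like:
    larger size, lower complexity, lower symmetricity).
    """

    name: str
    n_subjects: int
    baseline_mean_mm: float
    baseline_sd_mm: float
    hippus_amplitude_mm: float = 0.2
    complexity_mix: float = 0.5       # lambda in [0, 1]
    coupling: float = 0.5             # c in [0, 1]
    cross_lag_samples: int = 50
    blink_rate_hz: float = 0.2
    blink_dur_range_s: tuple = (0.1, 0.3)
    duration_s: float = 120.0
    fs: float = 300.0
    age_mean: float = 35.0
    age_sd: float = 8.0
    male_fraction: float = 0.45
    asrs_total_mean: float = 20.4
    asrs_total_sd: float = 11.0
    asrs_in_mean: float = 12.5
    asrs_in_sd: float = 6.64
    asrs_hyp_i_mean: float = 8.3
    asrs_hyp_i_sd: float = 5.42

    def __post_init__(self) -> None:
        if not (0 <= self.complexity_mix <= 1 and 0 <= self.coupling <= 1):
            raise ValueError("complexity_mix and coupling must lie in [0, 1]")
        if self.baseline_mean_mm <= 0:
            raise ValueError("baseline diameter must be positive")
        if self.fs <= 2 * HIPPUS_BAND[1]:
            raise ValueError("sampling rate must exceed twice the hippus band edge")


def td_preset(n_subjects: int = 20, **overrides) -> GroupPreset:
    """TD-like group: 3.56 (0.469) mm baseline, more complex and more
    symmetric hippus, low ASRS."""
    p = GroupPreset(
        name="TD", n_subjects=n_subjects,
        baseline_mean_mm=3.56, baseline_sd_mm=0.469,
        complexity_mix=0.7, coupling=0.7,
        age_mean=37.0, age_sd=7.9, male_fraction=8 / 20,
        asrs_total_mean=20.4, asrs_total_sd=11.0,
        asrs_in_mean=12.5, asrs_in_sd=6.64,
        asrs_hyp_i_mean=8.3, asrs_hyp_i_sd=5.42,
    )
    return replace(p, **overrides) if overrides else p


def adhd_preset(n_subjects: int = 16, **overrides) -> GroupPreset:
    """ADHD-like group: 4.06 (0.324) mm baseline, less complex and less
    symmetric hippus, high ASRS."""
    p = GroupPreset(
        name="ADHD", n_subjects=n_subjects,
        baseline_mean_mm=4.06, baseline_sd_mm=0.324,
        complexity_mix=0.4, coupling=0.4,
        age_mean=32.0, age_sd=8.29, male_fraction=8 / 16,
        asrs_total_mean=42.9, asrs_total_sd=14.0,
        asrs_in_mean=25.5, asrs_in_sd=6.86,
        asrs_hyp_i_mean=17.6, asrs_hyp_i_sd=6.86,
    )
    return replace(p, **overrides) if overrides else p


@dataclass
class CohortSpec:
    groups: list
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")


def band_limited_noise(n: int, fs: float, rng: np.random.Generator,
                       band: tuple = HIPPUS_BAND) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the hippus band.

    The band edges are imposed exactly in the Fourier domain (all variance
    strictly inside [band]); an IIR band-pass at a 0.04 Hz edge would leak
    near-DC drift that dominates cross-channel correlation estimates.
    """
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    if sd == 0:
        raise ValueError("recording too short to carry any in-band component")
    return y / sd


def _drive(n: int, fs: float, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance drive: lambda-mixture of broadband noise and a slow
    sinusoid with random phase and frequency (0.2-0.5 Hz)."""
    noise = band_limited_noise(n, fs, rng)
    phase = rng.uniform(0, 2 * np.pi)
    freq = rng.uniform(*REGULAR_FREQ_BAND_HZ)
    t = np.arange(n) / fs
    regular = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t + phase)
    return np.sqrt(lam) * noise + np.sqrt(1 - lam) * regular


def simulate_subject(preset: GroupPreset, seed, subject_id: str | None = None) -> PupilRecording:
    """Simulate one subject's two-channel recording."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = preset.fs
    n = int(round(preset.duration_s * fs))
    d0 = 0.0
    while d0 <= 0:
        d0 = rng.normal(preset.baseline_mean_mm, preset.baseline_sd_mm)

    delta = preset.cross_lag_samples
    lam, c, a = preset.complexity_mix, preset.coupling, preset.hippus_amplitude_mm
    shared = _drive(n + delta, fs, lam, rng)
    u_left = _drive(n, fs, lam, rng)
    u_right = _drive(n, fs, lam, rng)
    # the shared drive reaches the right eye `delta` samples after the left
    left = d0 + a * (np.sqrt(c) * shared[delta:] + np.sqrt(1 - c) * u_left)
    right = d0 + a * (np.sqrt(c) * shared[:n] + np.sqrt(1 - c) * u_right)

    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(preset.blink_rate_hz * preset.duration_s)
    starts = np.sort(rng.uniform(0, preset.duration_s, n_blinks))
    durs = rng.uniform(*preset.blink_dur_range_s, n_blinks)
    for s0, d in zip(starts, durs):
        i0 = int(s0 * fs)
        i1 = min(n, i0 + int(round(d * fs)))
        valid[i0:i1] = False
    left = left.copy()
    right = right.copy()
    left[~valid] = np.nan
    right[~valid] = np.nan

    return PupilRecording(
        subject_id=subject_id or f"{preset.name}-{0:03d}",
        fs=fs,
        t=np.arange(n) / fs,
        left=left,
        right=right,
        valid_left=valid.copy(),
        valid_right=valid.copy(),
    )


def _meta_row(preset: GroupPreset, rng: np.random.Generator, sid: str) -> dict:
    age = float(np.clip(rng.normal(preset.age_mean, preset.age_sd), 20, 60))
    sex = "M" if rng.random() < preset.male_fraction else "F"
    score = lambda mu, sd: int(max(0, round(rng.normal(mu, sd))))
    return {
        "subject_id": sid,
        "group": preset.name,
        "age": round(age, 1),
        "sex": sex,
        "asrs_total": score(preset.asrs_total_mean, preset.asrs_total_sd),
        "asrs_in": score(preset.asrs_in_mean, preset.asrs_in_sd),
        "asrs_hyp_i": score(preset.asrs_hyp_i_mean, preset.asrs_hyp_i_sd),
    }


def simulate_cohort(spec: CohortSpec) -> tuple[list[PupilRecording], pd.DataFrame]:
    """Simulate all groups of a cohort; optionally write CSVs to
    ``spec.out_dir``.  Per-subject seeds are spawned from the master seed,
    so the output is deterministic given the spec."""
    recordings = []
    meta_rows = []
    for preset in spec.groups:
        for i in range(preset.n_subjects):
            sid = f"{preset.name}-{i:03d}"
            child = np.random.SeedSequence([spec.seed, zlib_tag(sid)])
            rng = np.random.default_rng(child)
            recordings.append(simulate_subject(preset, rng, subject_id=sid))
            meta_rows.append(_meta_row(preset, rng, sid))
    meta = pd.DataFrame(meta_rows)
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_recording(rec, out / f"{rec.subject_id}.csv")
        write_metadata(meta, out / "metadata.csv")
    return recordings, meta


def zlib_tag(s: str) -> int:
    """Stable 32-bit tag for deriving per-subject seeds from string ids."""
    return zlib.crc32(s.encode())
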