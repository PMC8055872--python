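# Methods

This note documents the models, estimators, parameter choices and known
limitations of the `hippus` package in enough detail to interpret — and to
distrust appropriately — what its numbers mean.

## Preprocessing

A recording (nominally 120 s at 300 Hz, two channels in mm) is cut into
consecutive non-overlapping 5 s epochs anchored at the recording start; a
trailing partial window is discarded. Missing samples (blinks, tracking
loss) are linearly interpolated inside an epoch, with leading/trailing
gaps held at the nearest valid value; the per-epoch missing fraction is
recorded *before* interpolation. An epoch is dropped (`kept=False`) when
more than 50% of either eye is missing — entropy estimated from mostly
interpolated data would measure the interpolant. Each epoch is then
low-pass filtered 0–50 Hz with a 4th-order Butterworth applied
forward–backward; the design frequency is pre-warped so the combined
two-pass response is −3 dB at 50 Hz, DC gain is exactly 1, and amplitude
at ≥100 Hz is below 1% of passband. Zero-phase filtering matters here:
any phase lag applied differently to the two eyes would create
artifactual left→right directionality in the transfer-entropy stage.
Entropy features use per-epoch z-scored segments; baseline size uses the
filtered raw millimetres (DC gain 1 makes filtering nearly immaterial for
it). Per-epoch (rather than per-recording) z-scoring was chosen because
the entropy definitions index samples within an epoch-level series.

## Sample entropy (complexity)

`h(r, m) = −ln(A/B)` with B and A the ordered template-pair counts at
lengths m and m+1, Chebyshev norm, strict `< r` matching, defaults
`m = 2`, `r = 0.2` in z-scored units, natural log. Both counts run over
templates `i = 1..N−m` (every length-m template has a length-(m+1)
extension), the convention of the classical PhysioNet implementation;
this guarantees `A ≤ B`, hence `h ≥ 0`. An alternative normalization
counts `N−m+1` templates at length m; the difference is O(1/N) and does
not affect any comparison the pipeline makes. When A or B is zero the
epoch's value is undefined and excluded from averaging (no imputation).
Subject level: mean over kept, defined epochs per eye, then mean of the
two eyes. The O(N²) pair count is exact (no approximate neighbor search);
a sort-based prune on the first template coordinate makes N = 1500 take
milliseconds in the numba kernel without changing any count.

## Transfer entropy (symmetricity)

Directed `T_{X→Y}` with a single lag `τ = 10` samples (33 ms at 300 Hz)
serving as both prediction horizon and embedding lag, `d_x = d_y = 5`,
plug-in probabilities over an equiquantal `Q = 3` discretization, natural
log, computed through the entropy identity
`T = H(y⁺, y_past) + H(y_past, x_past) − H(y_past) − H(y⁺, y_past, x_past)`
with `0·log(·) := 0`. Discretization assigns each sample's symbol from
its lower rank, making it exactly invariant under strictly increasing
transforms and well-defined under ties. Subject level: mean of the two
directions per epoch, then mean over kept epochs. A separate evaluator
(`transfer_entropy_from_joint`) computes the same sum on an analytic
joint distribution; on an exactly factorized distribution it returns
exactly 0 — the estimator's no-causality anchor.

**Bias, and what TranEn actually measures here.** With ~1450 embedded
points against an 11-dimensional joint state (3¹¹ cells), the plug-in
estimate is dominated by sparse-histogram bias (~0.1–0.2 nats), which is
shared by every comparison made with it (original vs surrogate, group
contrasts) but varies only weakly — and non-monotonically — with true
coupling. Worse, a 0.04–2.0 Hz band-limited signal is almost perfectly
extrapolable from its own past over a 33 ms horizon, so the *genuine*
information a coupled partner adds is of order 10⁻³ nats, below the bias
variation, except in the degenerate fully-coupled case. Consequently
subject-level TranEn at these parameters behaves mostly as a second
irregularity index (which is also why it correlates strongly with SampEn)
rather than as a coupling meter; between-group TranEn differences in this
pipeline flow through drive regularity, not through coupling strength.
This limitation is a property of the estimator-parameter combination, not
an implementation defect: the exact brute-force oracle agrees to machine
precision, and no drive-spectrum shape within the hippus band changes it.

## IAAFT surrogates and the determinism test

Starting from a seeded random permutation, each iteration imposes the
original Fourier amplitude spectrum (keeping current phases) and then
rank-remaps onto the original sorted values; 50 iterations, ending on the
rank step, so the value multiset is preserved exactly and the spectrum to
typically <10⁻³ relative L2 on near-linear signals. Surrogates are drawn
per epoch and per eye, independently across eyes (single-channel IAAFT
does not preserve cross-channel phase relations). Ten surrogates per
epoch, seeded reproducibly per (subject, eye, epoch, index). Features are
recomputed through the identical path (z-score → SampEn / discretize →
TranEn), averaged over surrogates and then by each feature's own rule,
and compared with the originals by a two-tailed paired t-test per group;
a zero-variance difference vector is reported as t = 0, p = 1 (all-zero)
or flagged with p = 0 (constant shift). Note one consequence of the bias
discussion above: phase randomization typically *raises* plug-in TranEn
(richer joint-histogram occupancy) even though it destroys genuine
coupling — the same direction the determinism test expects for SampEn.

## Group statistics

Pooled-variance Student t (two-tailed, α = 0.05) and Pearson χ² without
continuity correction for demographics — the simplest canonical forms;
Welch t and the corrected χ² are available by argument. Feature contrasts
use ANCOVA `value ~ group + age` (age affects pupil size), with the group
F from the extra sum of squares, partial η² = SS_group/(SS_group +
SS_residual), covariate-adjusted means at the grand-mean age, and a post
hoc pooled t on the *raw* values (group descriptives are reported raw, so
the post hoc test matches them). A constant age drops the covariate with
a warning, reducing to one-way ANOVA (F = t² for two groups). Pearson
correlations among features and against symptom scores use the t-transform
p-value with n−2 df. Feature combinations for the classifier are gated by
pairwise |R| > 0.8 (strictly above excludes). No multiple-testing
correction is applied anywhere, by design.

## Classification

Binomial GLM with logit link fitted by IRLS (tolerance 1e−8 on the
coefficient step, 100 iterations cap). Zero-variance features get weight
0; with no informative feature the model reduces to the intercept at the
logit of class prevalence. Quasi-separation stops at the iteration cap
and is flagged — the fitted probability *ordering* remains valid for ROC
even when coefficients diverge. Positive class is the ADHD-like label
throughout. The ROC sweeps the probability threshold over
{0} ∪ {fitted probabilities} ∪ {1} (plus an upper sentinel so the (0,0)
endpoint exists even for tied extreme scores); AUC is the trapezoidal
area, which equals the Mann–Whitney pair statistic exactly, ties counted
half. Evaluation is in-sample on the full cohort — the design this
replicates reports no held-out split — with stratified k-fold
cross-validation available as a clearly separated, non-replicative
extension. Features are not standardized before the fit (affects
coefficients, not probabilities or AUC). Two-feature models additionally
export a probability grid over the observed feature rectangle; the
P ≥ 0.5 boundary is the straight line where the linear predictor is zero.

## Synthetic cohort generator

Each subject's baseline `d0` is drawn from a truncated-positive normal
(defaults: TD-like 3.56 ± 0.469 mm, ADHD-like 4.06 ± 0.324 mm — the
published group descriptives used as preset constants). Three independent
unit-variance drives are built — one shared `s`, two private `u_L, u_R` —
and mixed as

    left(t)  = d0 + a·(√c·s(t)      + √(1−c)·u_L(t))
    right(t) = d0 + a·(√c·s(t−δ)    + √(1−c)·u_R(t))

with hippus amplitude `a = 0.2 mm` and coupling `c ∈ [0,1]`. Each drive
is a `λ`-mixture `√λ·noise + √(1−λ)·regular`: the noise is Gaussian,
band-limited to 0.04–2.0 Hz by exact Fourier masking (an IIR band-pass at
a 0.04 Hz edge leaks near-DC drift that fails the generator's own
spectral invariant and fakes cross-eye correlation); the regular part is
a sinusoid with random phase and per-drive frequency drawn from
0.2–0.5 Hz, the slow-oscillation range of hippus. A fixed common
frequency would make even *private* components correlate across eyes at
cos(Δphase) regardless of duration, so per-drive frequency jitter is
required by the `c = 0` independence property. Blink gaps are simultaneous
in both eyes (Poisson rate 0.2 /s, duration uniform 0.1–0.3 s — typical
resting blink statistics) and marked missing, not set to artifact values.

The shared-drive lag is `δ = d_x·τ = 50` samples: for the TE stage's
delay embedding to see the advance at all it must lie within
`[τ, d_x·τ]`, and the upper end keeps the shared-drive windows of
source-past and target-past disjoint, stabilizing estimator bias across
coupling levels. At 300 Hz this is ~167 ms — far beyond any physiological
inter-eye latency; it is a property of the statistical surrogate, chosen
for detectability, not a claim about pupils. Group presets
(λ, c) = (0.7, 0.7) TD-like and (0.4, 0.4) ADHD-like are calibrated only
to reproduce the *directions* of the published group effects (ADHD-like:
larger size, lower SampEn, lower TranEn); no synthetic feature value is
comparable to a clinical one. Ages, sexes and ASRS symptom scores are
drawn per group from the published descriptives (normal, clipped/rounded).

What the generator does not emulate: the pupillary light reflex,
task-evoked responses, gaze- and foreshortening artifacts, asymmetric
(anisocoric) baselines, non-Gaussian burstiness of neural drive, and any
physiologically meaningful inter-eye lag. Passing pipeline tests on this
generator therefore demonstrates estimator and plumbing correctness and
direction-of-effect recovery under the stated statistical structure — not
clinical validity.

## Problem sizes and determinism

Default analysis parameters: epochs 5 s, cutoff 50 Hz, SampEn (m=2,
r=0.2), TranEn (τ=10, d=5, Q=3), IAAFT (50 iterations, 10 surrogates),
|R| gate 0.8, α 0.05. The test suite exercises full-length (120 s)
cohorts for the parameter-recovery and direction-of-effect properties
(100 and 1800 simulated subjects respectively) and smaller 20–30 s
cohorts for structural tests. All randomness flows from explicit seeds
(`numpy` `SeedSequence`/CRC-derived per subject, eye, epoch and
surrogate), so every report, including written CSV/JSON bytes, is a pure
function of config; reruns are byte-identical.
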