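# Methods

This note documents the models, estimators and numerical conventions the
package implements, the choices that were genuinely open, and what the
synthetic data does and does not establish.

## Features

**Vector magnitude.** The three acceleration axes are combined as
m = √(ax² + ay² + az²) *before* any filtering. The magnitude is invariant to
the mounting orientation of the sensor (a rigid rotation of the axes), which
is the reason to prefer it over any single axis; the constant gravity
contribution it contains is removed by the subsequent high-pass.

**High-pass filter.** 4th-order Butterworth, cutoff 0.5 Hz, applied
forward–backward (`sosfiltfilt`) for zero phase. The forward–backward pass
doubles the effective order; DC is rejected exactly. Signals shorter than
the filter's padding length raise a too-short error rather than returning
unreliable output.

**Band powers and the PSD ratio.** Power spectral density by Welch's
method: Hann window, 4 s segments, 50% overlap. The 4 s segment gives
0.25 Hz resolution, enough to resolve the 0.5 Hz lower band edge; recordings
shorter than one segment fall back to a single-segment periodogram with a
logged warning, and segments under 2 s are refused. Band power is the
trapezoidal integral of the PSD over the band, *not* the peak PSD —
integrated power is the only reading that makes the ratio scale-free and
well defined. Band edges are half-open/closed: the voluntary band is
[0.5, 4) Hz and the tremor band [4, 12] Hz, so a component exactly at 4 Hz
counts as tremor and the shared edge is never double-counted. The ratio
ρ = P[4,12] / P[0.5,4) is dimensionless and invariant under unit changes
(g ↔ m/s²) and sensor rotation; both invariances are enforced by tests to
1e-6 relative.

**Task time.** T counts pen-down samples only (pressure > 0), divided by
the pen sampling rate; pen-up gaps inside the task are excluded from T.
The accelerometer, by contrast, is sliced to the closed window
[first pen-down, last pen-down] including interior pen-up gaps — the two
conventions are deliberate and tested. The pressure threshold is exactly
> 0 with no hysteresis; a minimum-stroke-duration filter (default off)
exists for chattery real sensors. Pen and IMU are assumed to share one
clock (the acquisition software integrates both streams); a constant
per-session clock offset is configurable for hardware that does not.

## Severity model

FTM severity is regressed on the features by ordinary least squares. The
bivariate model over (T, ρ) at the mid-forearm sensor ships as a published
constant, FTM̂ = 8.2439 + 0.2791·T + 1.9890·ρ (r² = 0.561, RMSE = 8.158 FTM
points, fitted on 17 ET subjects), alongside per-site univariate ratio-only
models. Conventions:

- RMSE is √(SSE/n), the population form, not the n−p estimator; the choice
  is documented here because both conventions appear in the literature.
- Predictions are clipped at 0 (the FTM scale is non-negative); the scale
  ceiling of 144 is enforced only when *generating* synthetic scores, since
  an unsaturated linear model should be allowed to overshoot in diagnostics.
- Rank-deficient designs (constant or duplicated predictors) raise a
  collinearity error rather than returning a pseudo-inverse fit.

Group comparisons are nonparametric throughout — Mann–Whitney U for two
groups, tie-corrected Kruskal–Wallis across the four phenotype groups —
with Shapiro–Wilk run as a report-only normality check; the pipeline never
switches to t-tests on its outcome. The reported U statistic is
min(U₁, U₂), under which fully separated groups give U = 0. p-values are
always reported at full precision. No multiple-testing correction is
applied by default, matching common practice for a single pre-specified
feature set at each site.

## Phenotype classification

Leave-one-out cross-validation over the cohort: for each held-out subject
the remaining n−1 are z-scored (mean/SD of the training fold only — T is in
seconds, ρ is dimensionless, and RBF kernels are scale sensitive; computing
statistics on the full sample would leak the test point), an SVM is fitted
and the held-out subject predicted. The grid covers feature sets {T}, {ρ},
{T, ρ} × kernels {linear, RBF} × problems {2-class ET-vs-control, 4-class
phenotype}; for each (feature set, problem) the better kernel is reported.
Hyperparameters are fixed for reproducibility: C = 1 and the
variance-scaled RBF bandwidth (`gamma="scale"`); small-n LOOCV is sensitive
to them, so they are exposed in the configuration rather than searched.
Multiclass uses the standard one-vs-one decomposition with deterministic
lexicographic tie-breaking. A class reduced to a single member trains its
fold without that class (with a warning); if a fold's training set
degenerates to one class, the fold predicts that class.

A note on the LOOCV null: with labels randomly permuted, LOOCV accuracy is
*pessimistically* biased below the majority-class rate (the held-out
subject's class is under-represented in its training fold). The calibration
test therefore checks the leakage-sensitive direction strictly — mean
permuted-label accuracy must not exceed the majority rate beyond 2 SE — and
bounds the pessimistic side by the 2-SD spread of replicate accuracies.

## Synthetic cohort generator

The generator defines the study conditions for every test. Defaults
reproduce the reference cohort structure: group sizes 18/6/5/6
(control/ET−0/ET+1/ET+2); mean ± SD PSD-ratio targets per site of
0.55±0.37 / 2.15±1.66 / 3.90±2.59 / 4.74±1.82 (S1),
0.79±1.12 / 2.84±2.42 / 5.16±5.59 / 6.96±6.24 (S2),
0.81±0.60 / 0.88±1.14 / 0.97±0.95 / 2.09±2.59 (S3);
task times 12.64±5.53 / 20.53±14.23 / 19.82±8.04 / 26.92±14.95 s.

**Pen model.** Archimedes spiral r = aθ, 3 turns to a 60 mm maximum radius,
traversed at constant angular rate over the drawn task time at 100 Hz (the
tablet rate is a convention; only pressure timing and smooth positions
matter downstream), with 1 s pen-up lead/trail. Band-limited (0.4–3.2 Hz)
Gaussian positional wobble of 1 mm RMS emulates voluntary speed
fluctuation — real drawing is not metronomic, and without it the voluntary
band would be nearly empty because the spiral's base angular frequency
(≈ 0.2 Hz) lies below the 0.5 Hz high-pass. The wobble is cosine-ramped at
the stroke ends so the unwrapped spiral angle stays well defined near the
origin.

**Accelerometer model.** The voluntary component is the second finite
difference of the pen trajectory (mm → m), low-pass smoothed at 3.5 Hz and
mapped into the sensor frame by two fixed unit vectors (a tilted-tablet
geometry); tremor is an amplitude-modulated sinusoid (depth 0.3 at 0.5 Hz —
the waxing-and-waning envelope typical of action tremor) at a per-subject
frequency drawn uniformly on [4.5, 11.5] Hz, kept away from the band edges
to avoid leakage-driven flakiness, along a fixed unit orientation vector;
white noise (SD 0.005 m/s²) models sensor noise; gravity (9.81 m/s²) is a
constant offset on the z axis. Sampling is 148.1 Hz, matching the nominal
hardware rate.

**Hitting the configured moments.** Per-subject feature targets are drawn
from lower-truncated normals whose *location is solved (Brent's method) so
the truncated mean equals the configured mean*. Several printed SD cells
exceed their means, so naive truncation at 0 would inflate the realised
group means well beyond sampling error; moment matching keeps the generator
centred on the configured values, which is what the fidelity test asserts.
Ratios truncate at 0; task times truncate at 4 s, the shortest drawing that
supports the spectral-estimation floor with margin. The tremor amplitude
per site is then calibrated so the ratio *extracted by the analysis
pipeline itself* hits the drawn target: the extracted ratio is
r(A) = r₀ + kA² to excellent approximation (tremor power adds only to the
high band), so a closed-form guess (band-power inversion A²/2 ≈ ρ·P_low,
corrected for the gravity-axis projection and the AM power factor
1 + depth²/2) plus at most three secant corrections converges to within 2%.
Targets below the tremor-free baseline r₀ get A = 0. Per-site calibration
to per-site drawn targets supersedes a single fixed gain triple: it achieves
the configured per-site moments directly, which fixed gains cannot once
targets are drawn independently per site.

**Clinical scores.** ET subjects' latent FTM is the published severity
model applied to the drawn (T, ρ_S2) target plus a Gaussian residual of
SD 8.158 (the model's reported residual scatter), clipped to the FTM scale
[0, 144]; two synthetic raters add independent N(0, 2²) scoring noise,
sized so blinded raters agree at r² ≈ 0.95. Controls carry no FTM, as in
the emulated study.

**Determinism.** One `SeedSequence` is spawned per subject and again per
trace, so cohorts are bit-identical under a fixed seed, written CSVs are
byte-stable, and adding subjects does not perturb earlier ones.

**What the synthetic data does not show.** The generator emulates the
*group-level feature statistics* of a real cohort, not raw physiology: no
biomechanical arm model, no harmonics or frequency drift in the tremor, no
rest/postural conditions, no gyroscope/EMG channels, no dropped packets or
clock drift (both are handled, but injected only explicitly). Tests passing
on synthetic cohorts establish that the estimators are correct and
calibrated under the stated signal model — not that the headline dataset
results (e.g. a 2-class accuracy of 85.71% or r² = 0.561 on real subjects)
would be reproduced on new clinical data; those depend on per-subject data
that were never deposited. Replicate-cohort tests assert distributional
analogues instead (e.g. ratio-only 2-class LOOCV accuracy ≥ 75% in ≥ 80% of
seeded cohorts).

## Problem sizes and runtime conventions

Test and acceptance computations use the cohort sizes of the emulated study
(35 subjects, three sites): 20 replicate cohorts for generator fidelity,
500 replicates of n = 17 for regression parameter recovery, 1000 null
simulations for test calibration, 200 permutations for the LOOCV null, and
100 random rotations for the invariance suite. These sizes give standard
errors comfortably inside the asserted bands while keeping the whole suite
in a few minutes on one core.

## Known limitations

- The Welch/band-edge conventions (Hann, 4 s, 50%, trapezoidal integration,
  half-open low band) are this package's documented choices; other
  estimator settings shift ρ by a few percent, which matters when comparing
  absolute ratios across implementations.
- The amplitude-calibration model ignores the second-order magnitude
  nonlinearity |g + a| ≈ g + a_z + (a_x² + a_y²)/2g; at physiological
  amplitudes the secant correction absorbs it, but very large tremor
  amplitudes (≫ 1 m/s²) would converge more slowly.
- `mann_whitney_u` follows scipy's automatic exact-vs-asymptotic policy
  (exact only for small tie-free samples); exact p-values for large tied
  samples are out of scope.
- The severity model is linear and unregularised by design; no robust or
  mixed-effects variants are provided.
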