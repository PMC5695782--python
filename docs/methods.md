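# Methods

This note documents the models, conventions and design choices behind
`thighacc`, in the spirit of a methods appendix: what is computed, what
is assumed, and what the synthetic validation does and does not show.

## Signal model and decomposition

The device is a thigh-worn triaxial accelerometer sampling at 60 Hz
with a ±8 g range; axes are X mediolateral, Y along the thigh (vertical
when standing), Z anteroposterior, in units of g. Human movement lives
below ~20 Hz, so the raw signal is first low-passed at 20 Hz to remove
noise, then split at 0.5 Hz: the sub-0.5 Hz *static* stream tracks the
gravity projection (device orientation), and the residual *dynamic*
stream carries movement. Both filters are 4th-order Butterworth designs
applied forward-backward (`scipy.signal.filtfilt`), which cancels phase
delay and squares the magnitude response. "4th order" is interpreted as
the designed order, not the effective order of the double pass; the
alternative reading (2nd-order design, 4th-order net) can be obtained
via the `filter_order` config key. Edge transients from the reflective
padding decay within roughly a second; the analysed gas-sampling
minutes sit in the interior of each 4-min activity, so no analysed
window touches a filter edge. The decomposition satisfies
`static + dynamic = noise_filtered` exactly by construction, and tests
enforce it to 1e-9 g.

Analysis windows are non-overlapping 10-s segments (600 samples),
aligned to the first sample of each gas-sampling minute; an exact
minute yields 6 windows, and a marked minute shorter than 60 s is an
error rather than a silent partial window.

## Window features

Per axis and per stream (static, dynamic), 16 features: mean, sample
(n−1) SD, min, max, median, IQR, adjusted Fisher–Pearson skewness,
excess kurtosis, RMS of the raw values, peak-to-peak amplitude, peak
intensity, zero crossings, lag-1 autocorrelation, dominant frequency,
its amplitude, and normalised spectral entropy. Per stream: the three
lag-0 Pearson cross-correlations between axes and two resultant vectors
(Euclidean norm of the three axis means and of the three axis SDs); the
static stream additionally yields roll/pitch/yaw from the window-mean
gravity vector via the arctangent convention
roll = atan2(x̄, √(ȳ²+z̄²)) (and cyclic permutations), in degrees.
That gives 109 feature columns per window; the documented schema
(`feature_extraction.FEATURE_COLUMNS` plus the JSON side-car) is the
source of truth.

Two features needed explicit conventions because the literature leaves
them underdetermined. *Peak intensity* is the count of strict local
maxima of the mean-removed signal exceeding half of its maximum
absolute value — a reproducible reading of an otherwise vague term.
*Spectral entropy* is the Shannon entropy (base 2) of the normalised
one-sided periodogram of the mean-removed, Hann-windowed signal, DC
bin excluded, divided by log₂ of the bin count so it lies in [0, 1]; a
pure tone scores < 0.2, white noise > 0.9. Constant windows return 0
for skewness/kurtosis and the all-zero spectrum returns dominant
frequency 0 with entropy 0, by convention. Zero crossings are counted
on the mean-removed series with a zero sample inheriting the previous
sign.

## Reference labelling

MET is individual: activity V̇O₂ divided by the participant's measured
resting V̇O₂ (REE), both in ml·kg⁻¹·min⁻¹ — not the 3.5 ml·kg⁻¹·min⁻¹
population convention. Each one-minute gas sample is classified by four
exhaustive rules: MET ≤ 1.5 and not upright → Sedentary; MET ≤ 1.5 and
upright → Standing; 1.5 < MET < 3 → LIPA; MET ≥ 3 → MVPA. The boundary
inequalities (≤ 1.5, ≥ 3) are deterministic and tested. All six 10-s
windows of a minute inherit its label. Observed posture is an input
column (in the study it came from synchronised video); it is distinct
from the *algorithmic* posture detection used at classification time.
Each participant's own REE is used for their MET normalisation.

## Cut-point models

Each window of the dynamic stream is summarised by one metric:

* SVM (g): Σ_{d=1..600} √(x_d²+y_d²+z_d²) — sum of vector magnitudes;
* IMA (g·s): Σ_axes ∫₀¹⁰ |a| dt, rectangle rule at Δt = 1/60 s
  (trapezoid available by config; the two differ by O(Δt²));
* TM (g): √(SDx²+SDy²+SDz²) with sample (n−1) SDs — identical by
  construction to the dynamic resultant-SD feature.

Calibration regresses MET on the metric (metric on the horizontal axis)
over all training windows, fitting five spreadsheet trend families —
linear, logarithmic, exponential, power, quadratic — and keeping the
one with the highest R² computed on the MET scale; ties within 1e-9 go
to the family with fewer parameters. Only curves monotone increasing
over the observed metric range are invertible; if none is, the linear
fit is used with a warning. The fitted curve is inverted (Brent root
finding) at MET 1.5 and MET 3 to give the two cut-offs, which must fall
inside the observed metric range.

Classification: metric ≥ upper cut-off → MVPA; strictly between →
LIPA; at or below the lower cut-off, posture decides Sedentary vs
Standing. Upright means |static Y mean| > 0.5 g: the threshold is the
midpoint between the horizontal-thigh (≈0 g) and vertical-thigh (≈1 g)
gravity projections, and the absolute value makes detection robust to
a flipped device. The threshold is config-exposed
(`posture_threshold_g`).

## Random Forest

Feature selection is two-stage. Correlation pruning greedily removes
one member of every feature pair with |Pearson r| > 0.75 (the member
with the larger mean absolute correlation to the remaining features),
deterministically; correlations with constant columns are defined as 0.
Shadow-feature selection then re-implements the Boruta idea natively:
each iteration appends a row-permuted copy of every feature, trains a
forest, and scores a "hit" for features beating the best shadow
importance; a two-sided binomial test (α = 0.05) confirms or rejects
features as evidence accumulates (≤ 100 iterations, 15 by default in
the pipeline; early stop when all features are decided), and features
still tentative at the end are resolved by comparing their median
importance with the median best-shadow importance. The selected-feature
count is data-dependent output, not a target.

The classifier is a 100-tree Random Forest with the original Breiman
defaults: ⌊√p⌋ candidate features per split, unlimited depth, bootstrap
samples of size n. The out-of-bag error curve is recorded cumulatively
after each tree. Prediction ties break toward the earlier class in the
fixed order (Sedentary, Standing, LIPA, MVPA). A fixed seed makes
selection, training and prediction bit-reproducible.

## Evaluation

Leave-one-subject-out: each participant is the held-out test set
exactly once; cut-point models are recalibrated and the forest is
retrained on the remaining participants in every fold. Feature
selection is performed once on the pooled data before cross-validation,
matching the published workflow in which the feature set was fixed
before algorithm cross-validation. Confusion matrices (rows predicted,
columns reference) are built per participant and summed for the overall
view; the summation identity is an exact integer invariant. Sensitivity,
specificity and balanced accuracy are one-vs-rest per class, as
percentages; the multi-class table arithmetic confirms the one-vs-rest
convention. An absent reference class makes sensitivity undefined and
raises rather than returning 0. Balanced accuracy ≥ 80% is "acceptable",
and benchmarking reports the share of participants reaching it.
Percentages are reported at full precision and rounded half-up to one
decimal only for display.

Robustness testing gates every comparison on Shapiro–Wilk normality
(α = 0.05): Pearson vs Spearman for continuous characteristics, t-test
vs Mann–Whitney U for binary ones, paired t-test vs Wilcoxon for
algorithm comparisons; p-values are adjusted by Bonferroni
(min(1, p·k)) or Šidák (1−(1−p)^k), configurable. Reliability uses
CV(%) = sample SD / mean × 100 per activity per participant, summarised
over the moduli of the CVs by mean (normal) or median (otherwise) with
a ~95% CI; CV < 10% is acceptable.

## Synthetic protocol generator

The generator exists so the pipeline can be validated without access to
the original recordings. Each of 40 default participants (50% female,
ages ≥ 60, baselines drawn around the study moments: age 73.5 ± 6.3 y,
mass 72.2 ± 13.7 kg, height 1.67 ± 0.10 m, REE 2.82 ± 1.00
ml·kg⁻¹·min⁻¹) performs the ten protocol activities for 4 min each,
with minutes 3–4 gas-sampled. The signal is additive — gravity
projection + narrowband oscillation at the activity's dominant
frequency + white noise (SD 0.015 g) — the simplest generative family
whose static/dynamic decomposition is analytically known, enabling
closed-form oracle tests. Oscillation amplitude is 0.18 g per MET above
rest, scaled by a height-linked gain of +1% per cm above the sample
mean to inject the distance-to-joint-centre effect on thigh
acceleration; measured V̇O₂ per minute is true MET × REE with lognormal
noise of CV 4.4%, the reliability of Douglas-Bag calorimetry.

Per-activity true-MET means are conventional compendium-style values
(lying 0.95, sitting 1.10, standing 1.30, sideways shuffling 1.65,
free walking 3.5, cycling 3.3, treadmill 3.2 km/h 3.1, self-selected
3.8, weighted vest 4.3, brisk 5.0; SDs 0.08–0.40), chosen once:
shuffling deliberately straddles the 1.5-MET boundary so the
standing/LIPA misclassification edge case is reproducible, and the
resulting window-class shares (20/12/13/55% for
Sedentary/Standing/LIPA/MVPA) sit within ±20% of the shares implied by
the published window distribution (24.8/10.8/13.2/51.1%). The sedentary
share is structurally capped at 24 of 120 windows per participant —
the fixed protocol contains exactly two non-upright ≤1.5-MET
activities — so its deviation from the published share is irreducible
without distorting the protocol.

What the generator does *not* emulate: biomechanically realistic gait
harmonics, non-steady-state transitions, free-living behaviour
sequences, device calibration error, or skin-motion artefacts. Passing
the end-to-end tests therefore demonstrates the correctness and
internal consistency of the pipeline under a controlled, monotone
metric–MET relationship — not field performance on real recordings.

## Problem sizes and numerical choices

The default simulated study is 40 participants × 120 windows; the test
suite exercises the end-to-end cross-validation on 10 participants and
module behaviour on 2–6, sizes chosen as the smallest that exhibit all
the phenomena of interest (per-fold recalibration, class imbalance,
boundary straddling). The overfitting check uses a 4000-row synthetic
feature table, the calibration-recovery check 4000 noisy window pairs.
Root finding uses Brent's method on the observed metric range;
trend-family fits that require positivity (log, power, exponential)
are skipped when their domain is violated rather than patched.
Degenerate inputs follow explicit conventions documented above
(constant windows, zero spectra, constant correlation columns) or
raise (free-fall gravity vector, zero-mean CV, absent reference class).

## Known limitations

* The two bilateral devices of the original protocol are not fused;
  one configurable side is processed.
* The published study's own cut-off values and chosen trend families
  were never printed, so only the calibration *procedure* is
  reproducible, not its numerical outputs on the human data.
* Boruta is re-implemented natively (shadow features + binomial test);
  results can differ in detail from the R package's rough-fix
  heuristics.
* The posture threshold (0.5 g) is a geometric default, not an
  empirically fitted value.
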