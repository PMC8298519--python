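# Methods

This note documents the models, conventions and design choices behind
`surgforce`, in the order the pipeline runs.

## Data model

A **recording** is a two-channel force time series (left/right forceps
prong, Newtons) with 0-based time in seconds; time must be strictly
increasing and the median step must agree with the declared sampling rate to
within 1%. The sampling rate is never assumed: it is inferred from the time
column or supplied explicitly, because the acquisition hardware's rate is a
property of the device, not of the format.

A **segment** is the atomic analysis unit: the samples of one annotated
episode of force application, carrying its task label (closed 5-label set),
surgeon id and experience level (binarized Expert/Novice; the finer
post-graduate-year band is optional metadata only). Segmentation uses
half-open intervals `[start + offset, end + offset)` so annotations that
tile a recording partition it without double-assigning boundary samples.
Clock misalignment between the annotation track and the force stream is
absorbed by a single scalar `clock_offset` supplied by the caller; audio
processing to estimate it is out of scope. Annotations yielding fewer than
2 samples are dropped with a logged warning rather than an error, since
annotation tracks routinely extend past the force record.

Analysis is single-channel: features, thresholds and models use one
designated prong (default **right**, configurable to left or the
elementwise max). A config switch computes features for both prongs with
suffixed names, but the canonical feature vector is single-channel so that
one segment maps to one row.

## Preprocessing

Smoothing is a 4th-order Butterworth low-pass filter. The default is
**zero-phase** (forward–backward) application: the dashboard compares
magnitudes and timing-sensitive features, and a causal pass would introduce
phase lag that biases duration-aligned statistics. A causal mode is kept
for streaming parity. The cutoff is absolute Hz and must lie below the
segment's Nyquist frequency; both cutoff and sampling rate are explicit
configuration, never hard-coded. Zero-phase filtering needs
`3·(2·n_sections + 1) + 1` samples for edge padding; shorter segments raise
an error naming that minimum.

Outlier screening summarizes each segment by its maximum force, minimum
force and completion time on the analysis channel (after smoothing —
filtering precedes outlier detection). The 1st/99th percentiles of each
statistic over all Expert segments — linear-interpolation percentile
convention, since none is canonical — define the acceptance band; a segment
is an outlier iff **any** statistic leaves its band. Flagging (with reasons
such as `max_force_high`) and removal are separate pure functions so the
decision is auditable. Expert trials are pooled across tasks; per-task
thresholds are a non-goal. On expert-only data the flagged fraction is
bounded near 6% (three criteria × two 1% tails, before overlap).

## Feature engine

Exactly 37 named features per segment, fixed order, every value finite or
NaN (the not-available sentinel); a failing sub-computation degrades its own
entries to NaN and never aborts the table. Downstream consumers either use
complete cases per feature (screening) or impute (models: training-split
median). Conventions:

* dispersion statistics are sample (n−1) moments; `cv = sd/mean` is NaN at
  zero mean; `mean_ci95_halfwidth` is `t(0.975, n−1)·sd/√n` (half-width, not
  endpoints).
* `skewness`/`kurtosis` are bias-adjusted; kurtosis is excess. The `_2se`
  variants divide by twice the closed-form standard errors
  `SE_skew = √(6n(n−1)/((n−2)(n+1)(n+3)))` and
  `SE_kurt = 2·SE_skew·√((n²−1)/((n−3)(n+5)))`, so |value| > 1 reads as
  significant at ≈0.05. Normality is the Shapiro–Wilk W and p (3 ≤ n ≤ 5000).
* peaks are strict local maxima with topographic prominence ≥ 5% of the
  segment range (configurable fraction; no canonical prominence rule
  exists, so it is an explicit knob). `cycle_length` is the mean inter-peak
  interval in seconds; `d1_sd` is the sample SD of the first difference
  divided by the sample period (N/s).
* `flat_spots` bins the value range into ten equal-width bins and returns
  the longest run of consecutive samples in one bin; a constant segment
  returns n.
* spectral features use the mean-removed periodogram: `dominant_freq` is the
  largest ordinate's frequency; `spectral_entropy` is Shannon entropy of the
  normalized periodogram divided by log(#ordinates), in [0, 1] (white noise
  → ≈1, a pure tone → ≈0).
* the decomposition block fits a loess trend on the sample index (span 0.75,
  two robustifying iterations, interpolation delta 1% of n for speed);
  `trend = max(0, 1 − var(remainder)/var(series))`; `spikiness` is the
  variance of leave-one-out variances of the remainder (computed in closed
  form, O(n)); `curvature` is the second-degree coefficient of an
  orthonormal-polynomial quadratic regression on time, with basis signs
  fixed so the coefficient carries the sign of the quadratic shape;
  `linearity` is the Teräsvirta neural-network nonlinearity chi-squared
  statistic at lag 1 (authored here: auxiliary regression of the linear-fit
  residuals on quadratic and cubic lag products; the series is standardized
  first for conditioning).
* `fluctuation` — the dashboard's variability index — is defined here as the
  mean-crossing rate: sign changes of the mean-centred series divided by
  (n−1), bounded in [0, 1] and scale-invariant. This is an explicit
  interpretation (no formula is canonical) and is isolated so it can be
  swapped.
* windowed features tile the series into non-overlapping 10-sample windows
  (width configurable): `stability` is the variance of window means,
  `lumpiness` the variance of window variances. The shift statistics slide
  a pair of adjacent windows one sample at a time and report the largest
  |Δmean|, |Δvariance| and Gaussian KL divergence
  `0.5·(log(v₂/v₁) + (v₁+(m₁−m₂)²)/v₂ − 1)` with variances floored at 1e−8.
* `kpss_stat` is the stationarity statistic around a linear trend with
  lag-1 Bartlett long-run variance; `acf_*` features come from the sample
  ACF (first local minimum lag, first zero crossing with linear
  interpolation between lags — both in seconds — the lag-1 coefficient, and
  the sum of the first ten squared coefficients).

Invariants enforced by tests: catalogue closure, scale equivariance
(force-scaled features scale, shape features do not), time-reversal
invariance of distributional features, and brute-force oracle equivalence
for flat spots, spikiness, window shifts, KPSS and peak counting.

## Screening

Each feature gets an independent-measures two-way ANOVA with interaction
(experience × task) on complete cases. **Type II sums of squares** are used
because realistic segment layouts are heavily unbalanced (e.g. >1000
Coagulation segments vs a few dozen Dissecting); on balanced designs Type II
reduces to the classical decomposition, which the tests verify against a
nested-regression oracle. Raw per-feature p-values are reported;
Benjamini–Hochberg adjustment is an opt-in flag. Segments are treated as
independent observations — a deliberate simplification (repeated measures
per surgeon are ignored) that users should keep in mind. Post-hoc task
contrasts use Tukey HSD (no method is canonical; HSD is the standard choice
for all-pairs means). Subset selection is either the fixed rule (drop the
12 features that showed no useful group separation — duration, min, cv,
skewness, skewness_2se, d1_sd, peak_count, cycle_length, spikiness,
kpss_stat, acf_first_zero_time, acf_e10 — keeping 25) or a p-value
threshold on the main effects.

## Skill model

Median imputation → standardization → PCA (components retaining 95% of
training variance, configurable) → RBF-SVM, all fitted inside one pipeline
on the training split only (leak-free by construction). The split is
stratified 70/30 and seeded; cost/gamma are grid-searched by 5-fold
cross-validated accuracy, and the grids include 0.1·10^0.1 ≈ 0.126, the
value the original dashboard's tuning settled on. Sensitivity is Expert
recall, specificity Novice recall, AUC from decision scores on the test
split. Classes are unweighted by default (a class-weight flag exists).
Split fraction, fold count and the PCA rule are recorded in the result
object since no canonical values exist for them.

## Task model

Variable-length segments become fixed-length inputs by linear interpolation
onto 100 equally spaced points spanning the segment, then per-vector
standardization (zero-variance → zero vector). Resampling is isolated in
`resample_segment` so padding/truncation alternatives can be swapped.

The network is exactly: input → single-layer LSTM (100 units) → dropout 0.5
→ dense 100 ReLU → softmax(5), trained with Adam (lr 1e−3) on categorical
cross-entropy, batch size 20. It is implemented in NumPy (`surgforce.nn`):
forward pass, full backpropagation through time, inverted dropout and Adam,
in float32 with the per-timestep input contributions batched into one
matmul — a 100-unit model trains in seconds per epoch on one CPU core, and
the analytic gradients are verified against central differences in the
tests. Training runs `n_repeats` times (default 4) from seeds derived from
the master seed via `SeedSequence`; the evaluation split is stratified
70/30, shared across repeats, and all reported metrics are **held-out**:
cross-entropy loss, accuracy, and the MSE between one-hot labels and
softmax outputs (a metric, not the loss), each as mean (SD) over repeats.
The desk-scale default is 200 epochs; the full-scale 1000-epoch setting is
config-reachable.

## Performance gauges

The four dashboard metrics map to feature columns: completion time ←
`duration`, force range ← `range`, variability index ← `fluctuation`,
uncertainty index ← `spectral_entropy`. The expert baseline is the mean and
sample SD over all Expert segments; a surgeon's gauge value is the
unweighted mean over their segments in the selected case range (per-case
weighting is a config switch), with z-score `(value − mean)/sd` (NaN when
the expert SD is 0). Reporting z-scores keeps the rendering-side band
convention (±1 SD, range, …) free.

## Synthetic generator

The generator emulates the study conditions rather than tissue mechanics.
Per (task, experience) cell: durations and force ranges are drawn from
log-normal distributions moment-matched to the published per-task mean/SD
values (durations are positive and right-skewed; `μ = ln m − σ²/2`,
`σ² = ln(1 + (sd/m)²)`), durations floored at 0.5 s so every segment meets
all feature preconditions at the default 100 Hz (published durations then
give ≈540–1210 samples per typical segment). Each segment is a
task-specific motif scaled to its drawn range plus a 0.2 N baseline and
Gaussian noise; the left prong is a 0.95-scaled copy with independent
noise. Motifs: Coagulation — sustained plateau; Retracting — fast grasp
with slow partial relaxation; Manipulation — ≈1.2 Hz oscillation; Pulling —
rising ramp with terminal release; Dissecting — ≈0.8 Hz burst train. They
are mutually distinct so task recognition is learnable by construction.

Experience effects follow the published contrasts, which are in variability
rather than means: the novice force-range scale is multiplied by 0.39/0.35
(the peak-force ratio) and novice noise SD is 0.065 N vs 0.05 N for the
expert, targeting the within-segment SD contrast 0.27 vs 0.23 N. The drawn
duration and range are stored in segment metadata so moment-fidelity checks
measure the draws directly (the observed range of the noisy signal is
noise-inflated until smoothing). Per-cell counts default to the published
table (2895 segments, 1645 Expert / 1250 Novice); `tiny` (10/cell) is the
fast test profile. Randomness: one `SeedSequence` per dataset, one child
stream per cell in a fixed key order — regeneration is bitwise identical.

What the generator does **not** emulate: tissue heterogeneity and
physiological noise spectra, inter-surgeon variation beyond the binary
experience effect, within-case correlation, annotation errors, or the weak
class overlap of real data. Passing model-recovery tests therefore shows
the pipeline recovers injected structure, not that clinical performance
(e.g. the far weaker clinical skill separability) is reproduced.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen as the smallest
sizes with comfortable statistical power: 10 segments/cell for fixtures,
50/cell (500 segments) for model recovery, 100 replicates for simulation
checks, 200 epochs for the task model. Tolerances: oracle equivalences at
relative 1e−9 (1e−6 for KPSS, which crosses two linear-algebra paths),
filter gain at the cutoff ±0.02, scale equivariance at 1e−6. Degenerate
inputs (constant series, zero mean, too-short segments) return NaN rather
than raising wherever the contract allows, and every such rule is
unit-tested.
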