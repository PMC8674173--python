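# Methods

This note documents the models, parameter choices and numerical
conventions of `reachdecomp`, and what the synthetic cohort generator
does and does not emulate.

## Movement-element model

A 3D reaching motion is treated, per body axis, as a concatenation of
1D sub-movements ("movement elements") with zero initial and terminal
velocity. Operationally an element is a maximal run of velocity
samples of a single sign; boundaries are placed at every sign change
between consecutive samples, and an exact-zero sample closes the
element it terminates (its last sample) with the next element opening
immediately after. This rule is deterministic and order-independent;
leading and trailing partial lobes are kept and pass through the same
exclusion filter as interior elements. Elements with distance
< 1 mm **or** duration < 5 ms (strict inequalities) are treated as
potential sensor noise and excluded; the excluded fraction of total
duration is reported per recording (typically ~5% on synthetic data).

Per element we compute duration `T = n/f_s` (n samples at sampling
rate `f_s`), signed distance `D` as the trapezoidal integral of the
velocity profile, and mean speed `v̄ = |D|/T`. In unimpaired reaching,
`v̄` and `|D|` follow the two-thirds power law `v̄ ∝ |D|^(2/3)`; the
fitted exponent `α` (OLS slope of `log v̄` on `log |D|`, natural logs)
is both a feature and the primary generator-validation quantity.

## Pre-processing chain

* Gravity: the per-axis mean of the raw acceleration is subtracted;
  the renormalized mean vector is the gravity direction estimate. Over
  a 40-s task with near-zero net velocity change the mean specific
  force is gravity-dominated.
* Filtering: nominal 6th-order Butterworth filters (20 Hz low-pass on
  acceleration; 0.1–20 Hz band-pass on velocity) are realised as
  order-3 designs applied forward–backward (`sosfiltfilt`). Zero-phase
  filtering is essential because phase distortion would displace the
  zero-crossings that define segmentation. The net magnitude is the
  6-pole `1/(1+w^6)`, which matches the analytic single-pass 6th-order
  magnitude to better than 1% in the far stop band; note that near
  Nyquist the bilinear transform deepens attenuation well beyond the
  analog prototype (at 50 Hz with `f_s = 128` the measured attenuation
  is ~80× stronger than the analog value — tests assert "at least the
  analog attenuation" there and exact agreement with the filter's own
  frequency response at 30 Hz).
* Axis alignment: RC is the projection of velocity onto the gravity
  direction; AP is the principal eigenvector of the velocity
  covariance restricted to the gravity-orthogonal plane (guaranteeing
  AP ⊥ RC exactly); ML completes a right-handed frame. The AP sign is
  fixed so the single largest-distance excursion is positive (towards
  the target). Because alignment is linear, filtering before or after
  alignment is equivalent up to numerical noise.

## Feature set (53 features)

Nine aggregations (mean, SD, min, max, range, IQR, median, 10th/90th
percentile; SD is the n−1 sample version, percentiles linearly
interpolated) are applied to element duration, `log |D|` and `log v̄`
(27), to log-ratios of consecutive distances within each (hand, axis)
stream (9), and to LOSO-PCA scores PC1/PC2 of normalized morphologies
(18); plus `α` (1) and the four central cells of the transition
histogram (4). Six aggregations — the minima and ranges of duration,
log-distance, log-speed and log-ratio families listed in
`DEFAULT_EXCLUDED` — are dropped because they are pinned by the
exclusion thresholds and recording length rather than behaviour,
yielding 59 − 6 = 53. The composition is configuration, not
arithmetic: every piece (small-region size, bin edges, exclusion list)
lives in `FeatureConfig`.

Transition histogram: consecutive retained AP elements within one hand
form pairs `(D_i, D_{i+1})` of signed distances. Edges span ±0.5 m
with 4 outer bins per side and a 2×2 central grid covering
|D| ≤ 0.02 m; distances beyond the range are clipped into the edge
bins so probabilities always sum to 1. The four central-cell
probabilities — small consecutive movements in each direction
combination — are the features; they rise with dysmetric
fragmentation. Size/speed/duration, ratio and morphology features pool
all three axes and both hands; transition features use the AP axis
only, where the task's nose–target alternation lives.

## Morphology

Element profiles are sign-flipped to non-negative, divided by their
mean (spatial normalization), linearly resampled to 60 samples on
normalized time, and re-normalized to exactly unit mean. PCA is fit
leave-one-subject-out — a participant's own elements never shape the
basis that scores them — implemented incrementally from total minus
per-participant scatter matrices (algebraically identical to refitting
per fold; cross-checked against sklearn's PCA in tests). Component
signs follow the convention that each loading's largest-magnitude
coordinate is positive. The within-task optimization analysis compares
SD(PC1), SD(PC2) and the mean coefficient of determination `r²`
against the minimum-jerk reference `s(τ) = 30 τ²(1−τ)²` (unit mean on
[0, 1], peak 1.875) between the first and second 20 s of the task,
with one-sample t-tests of the deltas against zero. `r²` is computed
on the unit-mean profiles without per-element amplitude rescaling; the
reference profile is injectable for users who prefer a different
theoretical form.

## Severity models

`GPSeverityRegressor` / `GPGroupClassifier` wrap sklearn Gaussian
processes with an RBF kernel (unit initial length-scale, bounds
[1e-2, 1e3], plus a constant factor and white-noise term for the
regressor; 5 optimizer restarts, fixed seed). Features are min-max
scaled to the training fold's [0, 1] range; out-of-range test values
are *not* clipped. Regression labels are z-scored per training fold;
if a training fold's labels are constant the model predicts that
constant. LOSO folds group all visits of a participant; pediatric
participants are excluded from training (immature motor patterns) but
still estimated. Hand-specific estimates re-run the identical protocol
on features computed from one hand's elements. Per-fold fitted
transforms and kernel hyperparameters are exposed for leakage audits.

## Evaluation statistics

RMSE and squared Pearson `r²` (the coefficient of determination is
also available separately); AUC via the Mann–Whitney relation with a
participant-level bootstrap percentile 95% CI (2000 resamples, seeded;
single-class resamples are redrawn); ICC(3,1) (single-rater,
consistency, two-way mixed) from the two-way mean squares with the
F-based CI of McGraw & Wong, restricted to complete visit pairs;
Welch's ANOVA, Games-Howell post hoc (studentized-range reference,
q = t√2), Welch's and one-sample t-tests via pingouin/scipy, each
cross-checked in the test suite against independently coded
direct formulas.

A note on LOSO classification under chance: with shuffled labels the
held-out participant's class is depleted from the training prior, so
prior-reverting probabilities anti-correlate with the labels and the
AUC falls far *below* 0.5. Tests therefore assert absence of positive
skill rather than AUC ≈ 0.5.

## Synthetic cohort generator

The generator is a lobe-composition model, not a biomechanical
simulation. Per hand it schedules alternating nose→target and
target→nose reaches (0.45 m AP with ML/RC companions of 30%/20%
amplitude; the target side alternates every 10 s), separated by holds
containing chains of small alternating "micro" lobes (median 5 mm,
lognormal σ 0.5, ~1.3 per hold when healthy) that emulate physiologic
jitter and corrective micro-movements. Every lobe is a (possibly
skewed or multi-peaked) minimum-jerk-like profile whose duration comes
from a pivoted power law

    v̄ = d_p^(2/3) · (D/d_p)^α(s),   d_p = 0.05 m,
    α(s) = 2/3 − (2/3 − 0.4)·s/30,

which reduces to `v̄ = D^(2/3)` at severity `s = 0` and makes large
movements *slower* as the exponent falls (the unpivoted form would
speed them up for all D < 1 m). Severity adds: reach splitting into
lognormally shrinking sub-lobes (Poisson rate 0.09·s), endpoint
direction reversals (~8 mm, rate 0.06·s), higher micro-lobe rates with
log-shrinking distances, and growing shape noise / multi-peak
probability. For severity < 8 the shape noise decays in the second
half of the task (a practice effect), reproducing the
healthy-convergence pattern of the half-task morphology analysis.
Parkinsonism-like participants get 0.6× amplitude and speed but single
smooth lobes — slow yet unfragmented. Body-frame velocity is
differentiated, rotated by a per-participant random sensor-mount
rotation (SD 6°), gravity (9.81 m/s²) is added on the rostrocaudal
axis, and white noise (SD 0.03 m/s²) is applied.

Clinical labels: score = severity + N(0, 1) rater noise, clipped to
[0, 30] and rounded to half points; an upper-limb subscore (0–8) is
derived proportionally; parkinsonism-like participants carry a
separate UPDRS-like score never used for regression. Cohorts draw
ataxia severities uniformly from [3, 24], flag 15% of ataxia
participants pediatric, and can add drifted repeat visits for
reliability analysis.

Default constants were calibrated once so that the default healthy
condition lands in the intended element-count window (~420 retained
elements per participant, within 350–550, both hands and three axes)
and recovers the two-thirds exponent: the full pipeline measures
`α ≈ 0.63` on healthy cohorts, ~0.035 below the generating 2/3. The
residual bias is measurement physics, not a generator defect: the
0.1 Hz high-pass rebound perturbs small elements multiplicatively
along a slope-1 direction in log-log space, which sits below the 2/3
line (the same mechanism operates on real recordings).

**What the generator does not emulate:** tremor spectra and their
frequency structure, age/arm-length effects, fatigue, truncal motion,
gaze-hand coordination errors, sensor drift/calibration error, and —
importantly — the near-equality of element counts across real
phenotype groups: synthetic severity raises element counts strongly,
whereas in real cohorts fragmentation trades off against slowness to
leave counts roughly constant. Passing end-to-end tests therefore
demonstrates that the pipeline recovers structure the generator
encodes; it does not certify performance on clinical data, where label
noise and phenotype overlap are far larger (real-cohort severity
estimation is substantially harder than the synthetic analogue).

## Problem sizes and runtime

The acceptance computation uses 30 healthy / 60 ataxia / 20
parkinsonism participants with 15 repeat visits (250 recordings of
40 s at 128 Hz), chosen as the smallest cohort that stabilizes the
LOSO estimates and the ICC while keeping a full run in the low
minutes on one CPU. Unit tests use 10–20-s recordings.

## Known limitations

* The 53-feature composition is one defensible configuration; the
  exact historical composition of such feature sets is generally not
  recoverable from publications, so the exclusion list is explicit and
  configurable rather than claimed as ground truth.
* AP sign fixing by largest excursion can flip if a return movement
  happens to out-distance every outward reach; the generator biases
  outward reaches slightly larger to keep the convention stable.
* The bootstrap AUC CI degenerates to a point at AUC = 1 on separable
  synthetic cohorts.
* ICC confidence intervals with few repeat pairs (< 10) are very wide;
  the pipeline reports them as computed.
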