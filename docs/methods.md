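# Methods

`bendreturn` analyses the instrumented trunk bending-and-return (b&r) test:
a participant repeatedly bends forward to touch a stool target and returns
to standing, as fast as comfortable, for 70 s, while three inertial sensors
record triaxial acceleration (g) and angular velocity (deg/s) at 100 Hz —
SENS1 at T12 (lower thoracic spine), SENS2 at S2 (sacrum), SENS3 on the
lateral thigh.  The package turns those 18 raw channels per participant into
movement-complexity measures, per-cycle kinematics, feature tables, group
statistics and a supervised classification benchmark for separating chronic
low back pain (CLBP) patients from healthy (NLBP) participants.

## Preprocessing

The first 10 s are treated as warm-up and everything beyond 70 s is
dropped, leaving a 60 s analysis window of N = 6000 samples per channel.
A recording shorter than 70 s (a participant who stopped early) is rejected
rather than padded.  Two derived channel families are available: angular
acceleration by numerical differentiation (central differences, one-sided
at the endpoints, preserving length) and drift-corrected angle by cumulative
trapezoidal integration followed by subtraction of the least-squares
straight line fitted over the whole window.  The single-line drift model is
deliberate: gyroscope bias over one minute is well approximated as constant,
and any residual linear trend is removed identically by construction.

Units are metadata only.  Sample entropy uses a tolerance proportional to
each series' own SD, and the describers are unit-covariant, so expressing
acceleration in g or m/s² changes no entropy value and no classification
result; this is asserted in the test suite rather than assumed.

## Sample entropy and complexity factors

SampEn(m, r, N) counts pairs of length-m template vectors (B) and
length-(m+1) template vectors (A) whose Chebyshev distance is at most
r, excluding self-matches, with the same N − m starting points for both
lengths, and reports −ln(A/B).  Defaults: m = 2, r = 0.2·SD (sample SD,
ddof = 1), N = 6000.  Conventions the literature leaves open are explicit
options: `n_templates` ("n-m", default, vs "n-m-1") and `strict`
(`<` instead of the default `≤`).  A constant series has r = 0 and all
distances 0, so A = B and SampEn = 0 — maximal regularity, not an error.
If either count is zero the value is undefined and propagates as missing
(never as 0 or ∞), so it cannot silently bias group statistics.

Two implementations exist with identical counting semantics: a chunked
vectorised version used everywhere, and a plain double-loop enumerator kept
as the independent oracle for the test suite.  The suite asserts exact
integer agreement of (A, B) on hundreds of random series.

The complexity factors condense sensor pairs into two scalars:
LCF = SampEn(Gyr Y SENS1 − Gyr Y SENS2) for the lumbar spine and
HCF = SampEn((−Gyr Z SENS3) − Gyr Y SENS2) for the hip.  SENS3 is mounted
rotated on the thigh, so −Gyr Z plays the role its Gyr Y would play.  Each
difference series supplies its own SD to r.

A note on an intrinsic floor: a sampled sinusoid at these parameters has
SampEn ≈ 0.107 (mirror-phase template pairs match at length m but diverge
at m + 1), so no smooth periodic movement signal scores arbitrarily close
to zero.  Noise-free synthetic subjects sit at this floor; noisy defaults
sit well above it.

## Cycle segmentation

Each b&r repetition leaves one pronounced minimum in SENS1 Acc Z (at deep
flexion the sensor's Z axis points away from gravity).  Five steps:
smooth with a rolling centred mean (25 samples = 0.25 s); set the threshold
at the global minimum + 40% of the global amplitude of the smoothed series;
keep contiguous runs strictly below the threshold (this gates out shallow
local minima above it); take the argmin of each run and place a cycle limit
at the rounded mean position of each pair of consecutive minima; cut every
channel of every sensor at those limits and resample each cycle to 450
points by linear interpolation ("itime" is the normalised index).

Choices the procedure leaves open, fixed here: the centred window shrinks
symmetrically at the edges (no invented samples); the threshold is computed
on the smoothed series, the same series the minima are detected on;
half-sample limit positions round down; tied argmins take the earliest
sample.  K detected minima give K − 1 limits and K − 2 complete
between-limit cycles; the partial stretches before the first limit and
after the last are discarded.  Because the threshold is amplitude-relative,
segmentation is exactly invariant to adding a constant or positively
rescaling the signal.

## Features and statistics

Every channel is summarised by seven describers — max, min, mean, median,
Q1, Q3 (linear-interpolation quartiles) and SD (ddof = 1) — giving
3 × 6 × 7 = 126 whole-sequence features per participant; derived channels
double that when enabled, and per-channel SampEn (18 columns) or the two
complexity factors can be added or used alone.  Cycle mode computes the
same describers per normalised cycle, one row per cycle, each row tagged
with its subject.

Group comparisons use Shapiro–Wilk at α = 0.05 on each group: both normal →
two-sided t-test with mean/SD/SEM descriptives, otherwise Mann–Whitney with
median/quartiles.  For a between-group difference with SD and per-group
N: SEM = SD/√N, CI = 1.96·SEM (95% half-width), MDC = 1.96·√2·SEM, so
MDC = √2·CI identically; the z-multiplier 1.96 is used throughout rather
than a t-quantile.  No multiple-testing correction is applied across the
18 per-channel comparisons, matching the protocol this package implements.

## Classification benchmark

Seven algorithms (brute-force KNN, linear SVM, RBF SVM, decision tree,
random forest, AdaBoost, Gaussian naive Bayes) with published candidate
grids and default selected values.  Grid search is performed once on the
full table (cross-validated accuracy, ties to the first-listed candidate);
a nested-per-fold option is deliberately not the default, matching the
single winning setting the protocol reports.

Evaluation: per repetition, rows are re-ordered with a repetition-specific
seed and split into stratified 5 folds (n is a config knob; 5 is the
default for 40 participants); per fold, a pipeline standardises features
on the training rows only and fits the classifier; accuracy and ROC AUC
(class probabilities where available, decision scores otherwise) are
pooled over the repetition's folds; the report is mean ± SD over 100
repetitions.  The same base seed reproduces the benchmark bit-for-bit.
In cycle mode the protocol's `grouping="subject"` keeps all cycles of a
participant on one side of every split — the leakage-safe default — while
`grouping="row"` treats cycles as independent, reproducing the optimistic
variant; the choice is surfaced rather than guessed.

Feature ranking runs a greedy sequential selector once per (algorithm,
repetition): 7 × 100 = 700 runs.  Forward selection records the first and
second features added; backward elimination drops the weakest feature until
one survives (survivor first, last-dropped second).  Only the first two
ranks are resolved, which keeps the forward selector at O(F) subset
evaluations per run.  For these many-run studies `reduced_specs()` trims
the ensemble sizes (RF and AdaBoost to 10 estimators); everything else
keeps its selected values.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, with
analytic ground truth; it is not a biomechanical simulation.  Per subject:
cycle durations ~ N(1.43 s, 0.15 s) cycle-to-cycle around a subject period
drawn with SD 0.08 s (≈ 42 cycles per 60 s window); a biphasic velocity
pulse −A_k·sin(2πs) per cycle (flexion lobe, then return); per-cycle
amplitudes around a subject peak drawn from the group distribution; the
trunk sensor swings 1.35× the pelvis, the thigh 0.60×, carried on −Gyr Z;
Acc Z on SENS1 is a gravity projection, 1 g standing with a dip of 0.8 g at
deep flexion, so segmentation applies exactly as on real data.

Variability has three parts: per-cycle amplitude jitter (8%), a shared
multiplicative "tremor" (SD 6%) common to the whole kinematic chain — which
is why it largely cancels in the sensor-difference series feeding the
complexity factors — and independent per-sensor noise (SD 3% of peak
velocity; 0.02 g on accelerometers).  All three mix white and
AR(1)-correlated components; the mixing weight (`white_frac`) is the
complexity control.  Entropy is therefore an emergent property of noise
structure, never a direct target.

Group presets encode the clinical directions: NLBP peak velocity
120 ± 12 deg/s with white fraction 0.7; CLBP 92 ± 12 deg/s with white
fraction 0.25 (slower and more stereotyped).  Under these defaults the
pelvis-channel SampEn lands near 0.26 (NLBP) and 0.20 (CLBP) and HCF near
0.56/0.35 — inside the plausible clinical range — and a null cohort
(identical presets for both labels) drives the benchmark to chance.  These
values were fixed once against those qualitative conditions and are not
tuned per experiment.

What the generator does *not* emulate: axis cross-talk and sensor
misalignment, fatigue drift across the minute, asymmetric
flexion-vs-return durations, non-stationary pain-related pauses, and real
accelerometer dynamics beyond the gravity projection.  Passing tests
therefore demonstrate that the pipeline recovers structure it is designed
to detect under its own assumptions — not that the clinical effect sizes
transfer to real recordings.

## Problem sizes and determinism

Default study sizes are the protocol's own: 20 + 20 subjects, 60 s at
100 Hz, 100 repetitions, 700 selector runs.  The test suite and the
acceptance script use these sizes for the headline checks and smaller
cohorts (e.g. 3 + 3 subjects, 5-20 repetitions) for structural checks,
chosen as the smallest sizes at which the asserted property is stable.
Every stochastic component — generator, fold shuffling, stochastic
classifiers — derives from explicit seeds; identical seeds give
byte-identical outputs, which the pipeline manifest test asserts.

## Known limitations

* The on-disk format is wide delimited text with a column map; proprietary
  binary exports must be converted first.
* Cycle-limit counting follows the between-limit definition (K minima →
  K − 2 complete cycles); protocols that keep the leading/trailing partial
  cycles will count two more per recording.
* Undefined SampEn values propagate as missing and must be dropped or the
  feature set restricted before classification; no imputation is offered.
* The published HCF confidence-interval cell is inconsistent with its own
  formula (0.046 printed vs 0.049 = 1.96·0.111/√20); this package
  reproduces the formula, not that cell.
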