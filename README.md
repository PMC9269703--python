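# bendreturn

Analysis of the instrumented trunk **bending-and-return (b&r) test** for
low back pain research: from raw 3-sensor IMU time series to movement
complexity, per-cycle kinematics, group statistics, and a supervised
classification benchmark.

In the b&r test a participant repeatedly bends forward to touch a stool
target and returns to standing, as fast as comfortable, for 70 s.  Three
inertial sensors — SENS1 at T12 (lower thoracic spine), SENS2 at S2
(sacrum), SENS3 on the lateral thigh — record triaxial acceleration and
angular velocity at 100 Hz.  The package is for movement scientists and
clinical researchers who want to quantify how chronic low back pain (CLBP)
changes the kinematics and the *variability structure* of this movement
relative to healthy (NLBP) controls.

## What it computes

* **Sample entropy.**  SampEn(m, r, N) = −ln(A/B), where B counts pairs of
  length-m template vectors within Chebyshev tolerance r = 0.2·SD and A the
  same for length m+1 (self-matches excluded; defaults m = 2, N = 6000).
  Low SampEn = regular, stereotyped motion.  Two sensor-difference
  complexity factors condense the flexion channels: LCF =
  SampEn(Gyr Y SENS1 − Gyr Y SENS2) and HCF =
  SampEn((−Gyr Z SENS3) − Gyr Y SENS2).
* **Cycle segmentation.**  Each repetition leaves one deep-flexion minimum
  in SENS1 Acc Z; a five-step procedure (25-sample centred smoothing, 40%
  amplitude threshold, run-gated minima, midpoint cycle limits, 450-point
  linear resampling) cuts every channel into normalised cycles.
* **Features & statistics.**  Seven describers (max, min, mean, median,
  Q1, Q3, SD) per channel give a 126-column table per cohort; group
  comparisons are normality-gated (Shapiro–Wilk → t-test or Mann–Whitney);
  difference metrics SEM = SD/√N, CI = 1.96·SEM, MDC = 1.96·√2·SEM.
* **Classification.**  Seven algorithms (KNN, linear/RBF SVM, decision
  tree, random forest, AdaBoost, Gaussian naive Bayes) with grid search and
  a repeated (100×) stratified 5-fold protocol, scaler fit on training
  folds only; plus sequential forward/backward feature ranking over
  7 × 100 = 700 selector runs.
* **Synthetic cohorts.**  A seeded generator produces 3-sensor recordings
  with quasi-periodic biphasic velocity pulses, structured noise whose
  white/AR(1) mix controls entropy, and ground-truth cycle boundaries —
  the pipeline's built-in test bed.

## Worked example

```sh
python examples/01_sample_entropy.py
```

```
SampEn Gyr Y SENS2 : 0.274   (A=1303687, B=1713838)
LCF                : 0.641
HCF                : 0.635
```

A healthy synthetic subject's pelvis flexion channel: 1.71 M template pairs
match at length 2 within r, of which 1.30 M still match at length 3, giving
SampEn = −ln(A/B) ≈ 0.27 — comfortably above the ≈ 0.11 floor of a pure
sinusoid, reflecting cycle-to-cycle variability.  CLBP-preset subjects land
lower (≈ 0.19, more stereotyped motion).

```sh
python examples/04_classifier_benchmark.py
```

```
               Accuracy          AUC
BF KNN      0.86 ± 0.02  0.92 ± 0.02
Linear SVM  0.90 ± 0.00  0.96 ± 0.01
...
GaussianNB  0.90 ± 0.01  0.94 ± 0.01
```

On a contrasted synthetic cohort (20 + 20), the whole-sequence describer
table separates the groups well above chance for every algorithm; on a
*null* cohort (identical presets for both labels) the same protocol returns
≈ 0.50 accuracy, confirming the benchmark is calibrated.

The remaining examples cover segmentation (`02`), group statistics (`03`),
feature ranking (`05`) and the all-in-one pipeline (`06`).  A thin CLI
wraps the same functions:

```sh
bendreturn synth --out cohort/ --n-per-group 20 --seed 7
bendreturn run --synth paper-like --seed 7 --out results/
```

Real recordings are read from wide delimited text (one row per sample,
columns `SENS<k> <Acc|Gyr> <X|Y|Z>`, or any header via a YAML column map)
with a `labels.csv` naming each file's subject and group.

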