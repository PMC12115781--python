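# Methods

This note documents the models, conventions and design choices behind
`stresswear`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were resolved.

## Signals and preprocessing

The pipeline assumes three wrist-worn channels: electrodermal activity
(EDA, µS, native 4 Hz), heart rate (HR, beats/min, native 1 Hz) and
peripheral skin temperature (TEMP, °C, native 4 Hz), stored one file per
channel in the E4 export dialect (row 1 UNIX start time, row 2 rate in Hz,
rows 3+ samples; blank or `NaN` cells are missing).  Timestamps are plain
epoch seconds.

All channels are brought to a single 4 Hz grid by linear interpolation
between non-missing samples.  The lower-rate HR stream is upsampled rather
than EDA/TEMP downsampled, so no recorded information is discarded.  The
session grid is anchored at the latest channel start and truncated to the
intersection of the spans, including both endpoints
(`length = floor(span·rate) + 1` — a deterministic, testable boundary
rule).  Grid points whose bracketing input samples are all missing remain
missing through interpolation; resampling therefore never invents data
inside a gap.  Missing values are then imputed with the per-channel,
per-session median, computed over the whole session (imputation after
resampling, so missingness propagates to the grid and is filled exactly
once; the median is robust to the SCR-driven right skew of EDA).

## Window features

Sliding windows of 40 samples (10 s) advance by 20 samples (50% overlap).
Nineteen per-window features:

* min, max, mean, standard deviation for each channel (12).  The standard
  deviation uses the population denominator *n*;
* EDA sample skewness (Fisher–Pearson moment coefficient) and excess
  kurtosis (normal → 0), both defined as 0 for zero-variance windows (2);
* EDA peak analysis (3): peaks are strict local maxima with topographic
  prominence ≥ 0.01 µS (configurable; chosen at the conventional low end of
  SCR detection thresholds so small phasic responses at dry baseline
  levels still count).  The window reports the peak count, the summed
  prominences ("total amplitude") and the summed widths measured at
  `peak height − 0.5·prominence`, converted to seconds (width at half
  prominence, the standard SCR duration convention);
* RMS of successive differences for HR and TEMP (2), a short-term
  variability measure.

Lag features append, for each channel, the window mean from k = 1..10
windows earlier *within the same subject* (30 columns).  The first 10
windows of each subject are dropped rather than zero-padded — fabricating
history would leak a constant into the scaler — and a subject with fewer
than 11 windows contributes no rows (with a warning).  "Previous k
windows" is read as the single window k steps back, not a running average;
either reading yields 30 columns, and the single-window reading preserves
more temporal detail.

Min-max scaling maps each column to [0, 1] with training-fold statistics
only; zero-range columns map to 0.  Scaling inside every training split
(inner CV folds included) avoids the leakage that fitting the scaler on
the full data before splitting would introduce; with per-window features
of stable range the numerical effect is small, but the non-leaky protocol
is the defensible one.

## Labels

A continuous observer-style stress annotation on [0, 1] labels each
window by its mean value *m* over [start, start+10 s): class 0 ("no
stress") for m < θ₁, class 1 ("medium") for θ₁ ≤ m < θ₂, class 2 ("high")
otherwise.  Intervals are left-closed so boundary values are
deterministic.  The thresholds default to the tertile cut-points 1/3 and
2/3 of the scale — the natural uninformative choice when the annotation
instrument's own calibration is unavailable — and are fully configurable.
Per-window labeling (rather than one label per session) is used because
the classifiers train and evaluate on per-window rows; session-level
means are available through the same thresholding function.

## Model selection and evaluation

The protocol is: one stratified 80/20 train/test split; nested
cross-validation on the training part; final refit and a single evaluation
on the untouched 20%.  Nested CV uses stratified 5-fold loops at both
levels: for each outer fold, every candidate configuration is scored by
inner 5-fold accuracy on the outer-training part, the winner is refit on
that part and scored once on the outer-test part.  The mean of the five
winning inner accuracies minus the mean outer accuracy is the
"inner/outer gap" — the overfitting indicator; a selection that overfits
its inner folds shows a large positive gap.

Randomized search draws 100 configurations (20 in the reduced acceptance
runs) uniformly from:

* RF — n_estimators 50–300, max_depth 10–30, max_features {sqrt, log2},
  min_samples_split 2–20, min_samples_leaf 1–10, bootstrap {on, off};
* GB — n_estimators 50–300, max_depth 3–10, learning_rate uniform on
  [0.01, 0.31].

Integer ranges include both endpoints.  The grid learners use exhaustive
5-fold searches sized 45 (LR: C ∈ {0.001..10} × {liblinear, lbfgs, saga} ×
max_iter {100, 500, 1000}), 24 (SVM), 16 (k-NN) and 125 (AdaBoost).
liblinear is inherently binary and is wrapped one-vs-rest for the 3-class
problem.  Accuracy is the selection criterion throughout.

The stacking classifier trains RF and GB base learners, collects their
out-of-fold class probabilities from an internal stratified 5-fold split
(6 meta-features: 3 classes × 2 models) and fits a multinomial logistic
meta-learner on them.  All randomness flows from one seed; a fixed seed
reproduces folds, sampled configurations and fits bit-for-bit.

Reports follow the standard classification-report schema: per-class
precision/recall/F1/support with the 0-for-0/0 convention, accuracy, and
macro (unweighted) plus support-weighted averages.

## Interpretation

* **MDI importance.**  For feature f, the Gini-impurity decreases of all
  nodes splitting on f are summed within each tree, averaged over the T
  trees, and the vector is normalized to sum to 1:
  I(f) = (1/T) Σₜ Σ_{n∈N_f,t} Δi(n), then I(f) / Σ_g I(g).  Note the
  normalization order: raw per-tree sums are averaged first and normalized
  once at the end, whereas scikit-learn's `feature_importances_`
  normalizes each tree before averaging (for forests).  The two coincide
  exactly for a single tree — which the tests use as an independent
  cross-check — and differ only marginally for ensembles of similar trees.
* **Group statistics.**  Per-level means of HR_Mean/TEMP_Mean/EDA_Mean and
  two-sided Welch unequal-variance t-tests for level 1 vs 0 and 2 vs 0
  (direction: elevated level minus level 0), flagged at α = 0.001.  A
  literally paired test is impossible across unequal-sized window groups;
  a subject-paired variant on per-subject level means is available as an
  option.
* **Time in levels.**  Per-subject class fractions; `flag_high_stress`
  is strictly greater than 25% of windows at level 2 (so exactly 25% does
  not flag), cross-tabulated with the optional treatment-success flag.
* **Emergency-segment validation.**  A subject passes when at least 50%
  (configurable) of its windows in the emergency scenario segment
  (default segment 4 of 6) are labeled level ≥ 1.  The pass rule is this
  package's own operationalization of "classified as stressed during the
  emergency"; only the outcome, not a rule, is standard.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
study scale by default: 12 subjects × 7200 s (86,400 s total), six
scenario segments per session with segment 4 a forced-high-stress
emergency, and ~1.02% missing samples (MCAR — only a rate, not a
mechanism, is being emulated).

* **Stress profile** (1 Hz): piecewise-constant base values 1/6, 1/2, 5/6
  (the class-band centres) per segment plus smooth Gaussian-filtered
  jitter (sd 0.04, hard-clipped at ±0.10 < the ±1/6 band half-width, so
  every instant keeps its intended class), clipped to [0, 1].  Segment
  levels are a shuffled near-balanced multiset of {0, 1, 2} with the
  emergency forced to 2, so every subject visits all three classes.
* **HR** (1 Hz): per-level target mean + stationary AR(1) noise
  (φ = 0.9, sd 1.2 bpm — heart-rate-like short-term autocorrelation).
* **TEMP** (4 Hz): per-level target + a slow 20-min sinusoidal drift
  (amplitude 0.08 °C, random phase) + white noise (sd 0.05 °C).
* **EDA** (4 Hz): tonic level at the per-level target (smoothed over ~1 s
  to avoid step artifacts) + phasic SCRs as a Poisson process whose rate
  increases with stress (1/4/8 events·min⁻¹ at levels 0/1/2) convolved
  with a bi-exponential kernel (rise 0.75 s, decay 2 s, amplitudes uniform
  on 0.2–0.4 µS — standard SCR shape parameters) + smoothed noise, floored
  at 0 µS.

Per-level calibration targets are HR 82.23/86.30/84.79 bpm,
TEMP 31.81/31.49/31.23 °C, EDA 0.68/2.09/1.87 µS.  The HR target at
level 2 sits deliberately *below* level 1 — the generator follows its
calibration table, not a monotone idealization — so HR monotonicity holds
for levels 0→1 while TEMP and EDA are monotone throughout (EDA levels 1–2
both well above level 0).  Channel means are piecewise by the discrete
stress level of each instant, which pins the per-level empirical means to
the targets; the phasic SCR train adds < 10% to the EDA mean, inside that
channel's 15% calibration band.  Per-subject seeds spawn deterministically
from the master seed.

What the generator does *not* emulate: motion artifacts, sensor drift and
detachment, inter-subject baseline differences, circadian effects,
informative missingness, and the autocorrelated annotation lag of a human
observer.  Passing tests on this generator therefore demonstrate the
pipeline's correctness and its behavior under the assumed statistical
structure — not field performance on recorded data.

## Problem sizes for tests and acceptance runs

The acceptance script and acceptance tests scale the cohorts so the full
protocol (two learners × 5 outer folds × 20 configurations × 5 inner
folds) remains tractable on a single core, as this package's own choice
of reduced study conditions:

* feature-schema and cohort-scale checks: defaults (12 × 7200 s for the
  scale check itself);
* group statistics and generator calibration: 12 subjects × 1200 s
  (~2700 feature rows, ~10⁵ aligned samples per channel);
* modeling (nested CV, stacking, grid bookkeeping): 3 subjects × 480 s
  (~255 feature rows).  Longer sessions with fewer subjects are preferred
  over many short sessions because windows straddling segment boundaries —
  transitional, intrinsically ambiguous rows — scale with the number of
  boundaries, and short sessions would over-represent them relative to
  the study-scale cohort;
* importance structure: a 4-subject × 480 s cohort in which only EDA
  carries class signal (HR/TEMP are stress-independent noise).

## Numerical conventions and degenerate inputs

* Left-closed intervals everywhere a threshold is applied (labels,
  flags), so boundary values are deterministic.
* Zero-variance windows: skewness = kurtosis = 0; zero-range scaler
  columns map to 0; metrics with zero denominators report 0.
* Ties in model selection resolve to the first-seen configuration
  (deterministic draw order under the seed).
* Feature-table round-trips hold to 12 significant digits (CSV format
  `%.12g`).
* All-missing vectors, sub-window signals, disjoint channel spans,
  classes smaller than the fold count, and uncovered label windows raise
  typed errors rather than degrading silently.

## Known limitations

* The stress-annotation thresholds are study-calibration parameters; the
  tertile defaults are a convention, not an estimate.
* MDI importance is biased toward high-cardinality/continuous features
  and is reported as a descriptive, not inferential, quantity.
* Welch tests on overlapping windows inherit the windows' serial
  correlation; p-values are anti-conservative in that respect (the signs
  and orderings, which the acceptance checks use, are unaffected).
* The CLI covers synthetic end-to-end runs; recorded-data workflows use
  the library functions directly.
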