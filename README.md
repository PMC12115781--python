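# stresswear

Windowed physiological stress classification for wrist-worn sensor data.

Clinical training simulations (and other high-pressure tasks) elicit acute
stress that shows up in wearable physiology: heart rate (HR) rises,
electrodermal activity (EDA) rises in both its tonic level and its phasic
skin-conductance-response (SCR) rate, and peripheral skin temperature
(TEMP) falls through vasoconstriction.  `stresswear` turns raw
Empatica-E4-style channel exports plus a continuous observer stress
annotation on [0, 1] into a 3-class stress analysis, for researchers who
want a tested, reproducible version of this common wearable-sensing
workflow.

## What it computes

1. **Preprocessing** — each channel (EDA/TEMP at 4 Hz, HR at 1 Hz) is
   linearly resampled to a common 4 Hz grid; missing samples are filled
   with the channel's session median.
2. **Features** — sliding windows of 40 samples with step 20 (10 s windows,
   50% overlap).  Per window: min/max/mean/std for each channel, EDA
   skewness and excess kurtosis, EDA peak analysis (SCR count, total
   prominence, total duration at half prominence), RMS of first differences
   for HR and TEMP — 19 features — plus the channel means of the previous
   1–10 windows (30 lag features, never crossing subject boundaries).
   Min-max scaling to [0, 1] is fit on training folds only.
3. **Labels** — each window's class is its mean annotation value *m*
   thresholded at θ₁ < θ₂ (defaults 1/3, 2/3):
   class 0 if m < θ₁, class 1 if θ₁ ≤ m < θ₂, else class 2.
4. **Models** — nested stratified 5×5-fold cross-validation with randomized
   hyperparameter search (100 draws by default) selects random-forest and
   gradient-boosting classifiers; a stacking classifier combines their
   out-of-fold class probabilities through a multinomial logistic
   meta-learner.  Exhaustive grids are provided for logistic regression,
   SVM, k-NN and AdaBoost (45/24/16/125 candidates).
5. **Interpretation** — mean-decrease-in-impurity feature importance
   I(f) = (1/T) Σₜ Σ_{n∈N_f,t} Δi(n), normalized to sum to 1; feature
   correlation matrices; per-level physiological means with Welch t-tests
   (1 vs 0, 2 vs 0); per-subject time-in-level fractions with a
   high-stress flag (> 25% of windows at level 2); emergency-segment
   validation.
6. **Synthetic cohorts** — a generator emulating the statistical structure
   above (six scenario segments, one forced-high-stress emergency, ~1%
   missing samples, per-level channel means calibrated to
   HR 82.23/86.30/84.79 bpm, TEMP 31.81/31.49/31.23 °C,
   EDA 0.68/2.09/1.87 µS) so the whole pipeline is testable without any
   recorded data.

## Worked example

```python
import stresswear as sw
from stresswear.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="results/demo",
    seed=7,
    generator=sw.GeneratorParams(n_subjects=4, session_duration=300.0, seed=7),
    models=("RF", "GB", "STACK"),
    search_iterations=5,  # keep the demo quick; the default is 100
)
run_pipeline(config)
```

This simulates four 5-minute subjects, extracts 196 rows of 49-column
features, labels them, runs nested CV and writes all artifacts under
`results/demo/`.  A run printed:

```
$ python -c "import json;\
  r=json.load(open('results/demo/report_stack.json'));\
  cv=json.load(open('results/demo/cv_rf.json'));\
  print('stacking holdout accuracy:', r['accuracy']);\
  print('RF outer-CV mean accuracy:', round(cv['mean_accuracy'], 4));\
  print('RF inner/outer gap:', round(cv['inner_outer_gap'], 4))"
stacking holdout accuracy: 0.975
RF outer-CV mean accuracy: 0.9744
RF inner/outer gap: 0.0047
```

The holdout accuracy is the stacking classifier's score on the stratified
20% test split; the outer-CV mean estimates generalization, and the small
inner/outer gap indicates the selection did not overfit.  The same
directory carries per-class precision/recall/F1 reports, the MDI importance
table (EDA-derived columns rank highest), the per-level mean table with
Welch t-statistics (HR and EDA positive, TEMP negative), per-subject
time-in-level fractions and the emergency-segment validation summary.

The same pipeline runs from a shell:

```
stresswear run --seed 7 --out results/demo --subjects 4 --duration 300 \
    --search-iterations 5
stresswear simulate --out results/cohort --seed 7   # E4-style CSVs + traces
```

For recorded data, read each channel with
`sw.read_channel_csv(path, "EDA")` (E4 export dialect: row 1 start time,
row 2 rate, rows 3+ samples) and the annotation with
`sw.read_stress_trace(path)`, then call the stage functions directly.

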