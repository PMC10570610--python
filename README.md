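# thermoscreen

Dynamic-thermography screening of cutaneous and subcutaneous masses.

Dermal and subcutaneous lumps are among the most common presentations in
small-animal practice, and most of them are benign (lipomas above all).
A *rule-out* screening test lets a clinician safely skip fine-needle
aspiration for masses the test calls benign, provided the test has high
sensitivity and a high negative predictive value (NPV).  Dynamic (active)
thermography is one such test: the mass and its adjacent healthy skin are
heated by an LED for 10 s and filmed by a thermal camera for 40 s of cooling;
malignant tissue, being densely perfused, sheds the deposited heat faster
than healthy skin, while a lipoma heats up less but cools normally.

`thermoscreen` is a tested, reusable implementation of that analysis for
people studying screening classifiers of this kind: it simulates heat-cool
scans and whole cohorts with realistic structure (multiple masses per dog,
patient-level perfusion effects, non-diagnostic cytology), extracts
differential thermal-decay features, trains and validates a three-feature
linear rule-out classifier, and computes the standard screening statistics.

## Model

Each site's mean temperature follows lumped Newton heating/cooling:

```
T(t) = T0                                     before LED onset
T(t) = T0 + G (1 - e^{-a t})                  during heating   (t from onset)
T(t) = T0 + dT_h e^{-k (t - t_h)}             during cooling
```

with gain `G` (K), heating rate `a` (1/s), cooling decay rate `k` (1/s), and
`dT_h` the rise accumulated by the end of heating `t_h`.  The cooling rate is
estimated per site by log-linear least squares and combined into
*differential* features (mass − healthy), cancelling patient- and site-level
effects.  Features are z-scored with statistics frozen from the training
cohort, the top three features by absolute point-biserial correlation with
the benign/malignant label feed an unregularized logistic score
`s = w·x + b`, and the decision threshold maximizes specificity subject to a
training-sensitivity floor (default 0.85).  A mass with `s ≥ threshold` is
flagged as *requires further investigation*.  Training performance is
measured by leave-one-out with the entire pipeline (normalization, selection,
fit, threshold) refit inside every fold; validation applies the frozen model
with no refitting of any kind.

Reported metrics: accuracy, sensitivity, specificity, PPV, NPV, each also
rendered as half-up-rounded integer percents, with optional Clopper–Pearson
95% intervals.

## Worked example

```python
import logging; logging.basicConfig(level=logging.ERROR)
from thermoscreen.pipeline import (default_training_experiment, default_validation_experiment,
                                   run_training_experiment, run_validation_experiment)

training = run_training_experiment(default_training_experiment(seed=1))
print("LOO confusion (training):", training["confusion"])
print("LOO metrics (%):", training["metrics"]["rounded_percent"])
print("selected features:", training["model"].feature_ids)

validation = run_validation_experiment(default_validation_experiment(seed=2), training["model"])
print("fixed-model confusion (validation):", validation["confusion"])
print("fixed-model metrics (%):", validation["metrics"]["rounded_percent"])
print("excluded non-diagnostic:", validation["n_excluded_nondiagnostic"])
```

prints

```
LOO confusion (training): {'tp': 40, 'tn': 174, 'fp': 12, 'fn': 7}
LOO metrics (%): {'accuracy': 92, 'sensitivity': 85, 'specificity': 94, 'ppv': 77, 'npv': 96}
selected features: ['cool_rate_diff', 'cool_rate_mass', 'cool_auc_diff']
fixed-model confusion (validation): {'tp': 38, 'tn': 357, 'fp': 21, 'fn': 15}
fixed-model metrics (%): {'accuracy': 92, 'sensitivity': 72, 'specificity': 94, 'ppv': 64, 'npv': 96}
excluded non-diagnostic: 94
```

The training cohort mimics a 233-mass study (186 benign / 47 malignant);
leave-one-out sensitivity lands at the 85% design floor.  The validation
cohort mimics a 525-mass screening population: 94 masses with non-diagnostic
cytology are excluded, the frozen model is applied to the remaining 431, and
— as a rule-out test should — NPV (96%) is far above PPV (64%): a negative
call is trustworthy, a positive call mainly triggers cytology that would have
been done anyway.  The selected features are all cooling-decay summaries,
matching the physical expectation that decay rate separates the classes.

A CLI wraps the same stages:

```
thermoscreen simulate --out cohort_dir --seed 7
thermoscreen train --out fit_dir --seed 7
thermoscreen validate --model fit_dir/model.json --out val_dir --seed 8
thermoscreen metrics-from-counts 45 253 125 8
```

The last command computes the five screening metrics directly from the four
confusion-matrix cells (TP TN FP FN) — useful for checking any published
matrix without simulation.

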