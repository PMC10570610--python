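# Methods

## The screening problem

A rule-out test for cutaneous/subcutaneous masses must keep sensitivity and
negative predictive value high: a missed malignancy (false negative) sends a
dog home untreated, whereas a false positive merely triggers the fine-needle
aspirate that would otherwise have been done anyway.  The pipeline therefore
fixes a training-sensitivity floor and evaluates everything against the five
screening statistics (accuracy, sensitivity, specificity, PPV, NPV), with
malignant = positive = "requires further investigation" throughout.

## Tissue thermal model

Scans are modelled at the level the analysis actually consumes: the ROI-mean
temperature of two sites (mass, adjacent healthy skin) over a 50 s protocol —
0.5 s pre-illumination baseline (5 frames), 10 s of LED heating, 40 s of
cooling, sampled at 10 Hz.  Each site follows lumped two-phase Newton
heating/cooling with four parameters:

| parameter | units | meaning | healthy default |
|---|---|---|---|
| `baseline_temp` | °C | resting skin temperature | 32 ± 0.5 (dog-level) |
| `gain` | K | asymptotic rise under sustained illumination | 2.5 |
| `heat_rate` | 1/s | inverse heating time constant | 0.35 |
| `cool_rate` | 1/s | exponential cooling decay constant | 0.10 |

A spatial bioheat PDE would add cost without changing the analysis surface:
the classifier only ever sees ROI-mean curves, and observed heat-cool
signatures are smooth near-exponential rises and decays.  Heating and
cooling rates are separate parameters so that classes with normal decay but
aberrant heating (lipoma, cysts) are expressible.

### Tissue class library

Per tumor type, the mass-site and healthy-site parameters are drawn from
lognormal priors (mean exact, coefficient of variation 0.15 across lesions):

- malignant masses: `cool_rate` mean 0.18 /s — densely perfused tissue sheds
  heat markedly faster than healthy skin (0.10 /s);
- mast cell tumors: a 2:1 mixture of the malignant component and a
  *low-grade* component (`cool_rate` 0.125 /s) — low-grade mast cell tumors
  behave thermally much like benign tissue and are the canonical
  false-negative class;
- lipoma: gain 1.5 K (60% of healthy) with normal decay — fat heats up less
  but cools unremarkably;
- cystic/inflamed benign lesions (epithelial/adnexal cysts, inflammatory
  processes): reduced gain 1.9 K, slower heat uptake (0.25 /s), mildly
  elevated decay (0.11 /s) — the classic false-positive classes;
- other benign types: thermally close to healthy skin.

On top of the lesion-level scatter, each *dog* carries multiplicative
factors shared by both sites of all its masses: a perfusion factor (CV 0.20)
scaling every cooling rate and an absorption factor (CV 0.15) scaling every
gain, plus a dog-level baseline temperature.  These patient-level effects
are exactly what differential (mass − healthy) features exist to cancel;
without them, absolute per-site features separate the classes almost
perfectly and the screening problem becomes trivial, which no field study of
this kind shows.  All effect sizes were fixed once at these values.

### Camera and noise

The camera model is a 160 × 120 (19,200-pixel) long-wave-infrared array,
per-frame Gaussian noise 0.05 K per pixel, a per-pixel fixed-pattern offset
map (sd 0.1 K) removable by flat-field correction, 6.5 × 4 cm field of view,
FPA stabilised at 35 °C.  `render_scan` produces full frame stacks (mass
circle, healthy circle, healthy-baseline background, fixed pattern + noise).

Cohort generation defaults to drawing ROI-mean curves directly: the mean of
N iid Gaussian pixels is Gaussian with sd `noise_sd/√N`, and the ROI-mean
fixed-pattern offset is one constant per site.  This is distributionally
identical to rendering and averaging (asserted by a Monte-Carlo test) while
avoiding ~10 GB of pixel traffic per 525-scan cohort; full rendering remains
available via `render="scans"`.

### Cohort structure

`generate_cohort` emits *exact* class counts — the roster is built per type
and shuffled, never Bernoulli-sampled — so bookkeeping invariants hold
deterministically.  Non-diagnostic lesions carry an underlying tissue class
(they are real masses whose cytology failed) but no usable label, and are
excluded downstream exactly as a screening study excludes them.  Dogs
receive 1–6 masses from a configurable distribution, repaired
deterministically so the assignment sums to the exact mass total.  All
randomness fans out from one seed through `numpy.random.SeedSequence.spawn`
(separate streams for cohort structure, tissue parameters, and sensor
noise), so equal seeds give byte-identical datasets.

The two bundled study-mimicking configurations: training — 233 masses from
147 dogs, 186 benign / 47 malignant, all diagnostic, histopathology on
59/233; validation — 525 masses from 299 dogs, 94 non-diagnostic, leaving
378 benign / 53 malignant.  The tumor-type breakdown of the non-diagnostic
94 is unknowable (their cytology failed); they are spread roughly
proportionally to the cohort composition, which does not affect any
diagnostic-cohort marginal.

## Signal processing and features

- Flat-field correction subtracts `(reference − mean(reference))` from every
  frame: per-pixel offsets cancel exactly, per-frame spatial means are
  preserved, and the operation is idempotent.
- ROI extraction averages pixels whose centers fall inside the marked
  circle (0-based coordinates, membership `(px−cx)² + (py−cy)² ≤ r²`).
- The basal temperature is the median over baseline frames (robust to a
  single bad frame).
- Cooling decay is fitted by OLS of `ln(max(T − T_base, ε))` against time
  since cooling onset over positive-excess frames, `ε = 1e-6` K guarding the
  logarithm; rate = −slope, amplitude = exp(intercept).  On noiseless
  exponentials this is exact to machine precision.  Under frame noise the
  positive-excess restriction biases the rate slightly upward once the late
  excess drops below the noise floor (about +2% at 0.05 K noise, rate
  0.1 /s, amplitude 2 K); the test suite quantifies this with a seeded
  simulation study rather than hiding it.
- The feature catalog (16 columns) holds per-site peak rise, heating slope,
  cooling rate, cooling half-time (`ln 2 / k`), and normalized cooling area
  (trapezoid integral of the cooling excess divided by peak rise × cooling
  duration), each with a mass − healthy differential, plus the baseline
  temperature difference.  Subtraction (not ratio) keeps differentials
  defined when healthy values are near zero.  The catalog is a documented
  stand-in for a proprietary device's feature set and is extensible through
  `FEATURE_REGISTRY`.
- Rows with non-finite features (degenerate fits) are dropped as QC when
  building the table.

## Classifier

Normalization is cohort-level z-scoring; the training-set means and sds are
frozen into the model so validation is a genuinely fixed algorithm.
Selection ranks features by absolute point-biserial correlation with the
label, ties broken lexicographically (fully deterministic), and keeps three.
The score is an unregularized logistic regression (lbfgs, tol 1e-8) — any
linear fit would serialize identically since weights, bias, threshold and
normalization are all stored in the model JSON.

The threshold maximizes specificity subject to training sensitivity ≥
`min_sensitivity` (default 0.85), ties broken toward higher sensitivity; on
a separable score set this yields 100%/100%.  A score exactly at the
threshold is flagged — the conservative choice for a rule-out test.

Leave-one-out refits *everything* (normalization, selection, weights,
threshold) inside each fold to avoid leakage; the unit is one lesion by
default, with leave-one-dog-out available (`group_by_dog`) since dogs
contribute multiple masses.  Folds whose training half loses a class are
flagged and excluded from the matrix.  The final model's threshold is tuned
on the full training fit, not on LOO scores.

## Metrics and reporting

Zero-denominator metrics are explicitly `None`, never silent NaN.  Integer
percents use half-up rounding, isolated in `percent_half_up` (so 78.5% →
79).  Histopathology overrides cytology; non-diagnostic cytology without
histopathology excludes the lesion.  The per-type report counts predictions
per (diagnosis class × tumor type) with class totals and a grand total, and
collapses exactly back to the confusion matrix.  Clopper–Pearson 95%
intervals are an extension beyond the headline point estimates.

## Problem sizes used in tests and acceptance

The simulation-backed checks run at the mimic sizes themselves (233- and
525-mass cohorts; leave-one-out over 431 lesions × 10 seeds in the
operating-point check), Monte-Carlo rendering checks at a reduced 30 × 40
sensor and 3 s protocol over ≥ 200 seeds, and oracle-equivalence checks on
30-lesion tables × 5 seeds.  These sizes make the full suite run in a couple
of minutes while keeping every cohort-level count at study scale.

## What the synthetic generator does and does not show

Passing tests demonstrate that the *pipeline* is correct (exact bookkeeping,
closed-form feature recovery, leakage-free LOO equal to a brute-force
oracle, fixed-model purity) and that under plausible tissue physics the
screening design lands where it should (sensitivity at the floor, NPV ≫
PPV).  They do not validate the device's real-world operating point: real
tissue is spatially heterogeneous, probe pressure and contact vary, fur and
clipping affect coupling, lesion depth attenuates heating, and the true
feature set and class-conditional distributions of the device are
proprietary.  Simulated effect sizes were chosen for realism, not fitted to
reproduce any published matrix — the published matrices enter only as exact
inputs to the statistics layer.

## Known limitations

- No spatial heat diffusion between sites; curves are independent given
  parameters.
- Single-exponential cooling; real decays are multi-compartment, and the
  log-linear estimator's small positive bias at low tail SNR is documented
  above.
- Cytology labels (when diagnostic) are assumed correct unless overridden
  by histopathology; label noise is not modelled.
- Ambient-temperature drift, motion, and re-scan artifacts are out of
  scope (the data-ingest rule "keep the latest scan per lesion" covers
  re-scans).
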