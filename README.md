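# gaitconf

Balance-confidence classification from smartphone gait signals recorded
during a six-minute walk test (6MWT).

People with lower limb amputation often report low confidence in their
balance — measured clinically with the Activities-specific Balance
Confidence (ABC) scale, a 16-item questionnaire scored 0–100% per item and
averaged, with ≥ 80% conventionally labeling *high confidence*. Low
confidence drives activity avoidance; confidence mismatched with ability
raises fall risk. `gaitconf` implements, as a reusable and tested
pipeline, an analysis that predicts the high/low confidence group directly
from the inertial signals of a pelvis-worn smartphone collected while the
person walks for six minutes — so the classification comes "for free" from
an assessment clinics already run. It is aimed at gait-analysis and
digital-biomarker researchers who want every stage of such a pipeline
explicit, configurable and verifiable against ground truth.

## What the pipeline does

1. **Signal conditioning** — variably-sampled (~50 Hz) accelerometer and
   orientation channels are linearly interpolated to a fixed 50 Hz and
   filtered with a fourth-order zero-lag Butterworth low-pass at 4 Hz;
   device axes map to body axes (ML/AP/vertical acceleration,
   tilt/rotation/obliquity orientation).
2. **Foot strikes** — candidate strikes (from the built-in AP-peak
   detector or an external labeler) are cleaned with two heuristics:
   removal of extra predictions crowding one anterior–posterior (AP)
   acceleration peak, and insertion of missed steps wherever an
   inter-strike gap is ≥ 1.5× the preceding one, placing the new strike at
   the largest AP peak outside an adaptive locking period.
3. **Features** — each step (consecutive foot strikes) yields 62 features:
   5 temporal (cadence, right/left step time, stride time, symmetry index
   |R−L|/(½(R+L))×100), 27 descriptive statistics and 30 frequency-domain
   features (quartile FFT, max FFT, SD FFT, peak distinction, even/odd
   harmonic energy ratio REOH, per channel). Min/max/mean/SD over all
   steps give the 248-feature trial vector.
4. **Classification** — correlation-based feature selection (CFS, merit
   `k·r̄_cf / √(k + k(k−1)·r̄_ff)` with best-first search) feeds a
   100-tree random forest, evaluated with participant-level leave-one-out
   cross-validation; ties in the tree vote go to the clinically
   conservative *low confidence*.
5. **Synthetic cohorts** — a generator produces 6MWT-like recordings with
   known foot-strike times, class-conditional gait differences (cadence,
   step-time variability, sway, asymmetry) and ABC scores, so every stage
   is testable without clinical data.

## Worked example

End to end on a small synthetic cohort (five participants per class,
one-minute trials, separated class parameters):

```python
from gaitconf import GaitParams
from gaitconf.synthetic import CohortSpec, generate_cohort
from gaitconf.pipeline import features_from_records
from gaitconf.model import ForestConfig, loocv

spec = CohortSpec(
    n_per_class=5,
    seed=42,
    params_high=GaitParams(cadence=105, step_time_cv=0.04, asymmetry=0.04,
                           ml_sway_amp=0.6, duration=60),
    params_low=GaitParams(cadence=85, step_time_cv=0.10, asymmetry=0.12,
                          ml_sway_amp=1.2, duration=60),
)
cohort = features_from_records(generate_cohort(spec))
print("feature matrix:", cohort.features.shape)
result = loocv(cohort, ForestConfig(seed=42))
print("selected features:", result.selected)
print("confusion:", result.confusion)
print("metrics:", result.metrics.as_dict())
```

prints

```
feature matrix: (10, 248)
selected features: ['quartile_fft_ap__min']
confusion: ConfusionMatrix(tp=5, fn=0, fp=0, tn=5)
metrics: {'accuracy': 100.0, 'sensitivity': 100.0, 'specificity': 100.0, 'precision': 100.0}
```

Each trial became a 248-feature vector; CFS found a single frequency
feature of the AP channel sufficient to separate the classes, and the
ten leave-one-out folds (one model per held-out participant) classified
every participant correctly — expected here, since the synthetic classes
are strongly separated. The positive class throughout is *high
confidence*, so sensitivity is the detection rate of high-confidence
participants and specificity that of low-confidence ones.

The same stages are available from the shell:

```sh
gaitconf simulate --n-per-class 5 --seed 42 --out data/
gaitconf run-all --in data/ --out out/ --seed 42     # writes out/report.{json,md}
gaitconf detect-steps --in data/high001.csv --out strikes.csv
gaitconf evaluate --features out/features.csv --cohort data/cohort.csv --seed 42
```

## Analysis drivers

Numbered scripts under `analysis/` rebuild the study tables from scratch:
cohort simulation (`01`), foot-strike quality against ground truth (`02`),
feature extraction (`03`), classification under both the headline
(selection-once) and leakage-safe (per-fold selection) protocols (`04`),
and the metric recomputation from the published 58-participant confusion
matrix (`05`). Compact outputs land in `results/`; bulky intermediates in
`scratch/` (not part of the repository). `docs/methods.md` documents the
models, parameter choices and limitations — including why a null cohort
evaluated with selection-before-cross-validation scores above chance.

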