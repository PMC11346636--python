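# Methods

`gaitconf` reimplements, as a tested pipeline, an analysis that classifies
people with lower limb amputation into high- and low-balance-confidence
groups from smartphone inertial signals recorded during a six-minute walk
test (6MWT). This note documents the models, the concrete numerical choices
made where the procedure was underdetermined, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Signal conditioning

Smartphone sensor logs sample at a variable rate near 50 Hz. Each channel
(three body-frame accelerations ML/AP/Vert in m/s², three orientation
angles tilt/rotation/obliquity in degrees) is linearly interpolated onto
the fixed grid `t_k = t_0 + k/50` for `k = 0 … floor((t_last − t_0)·50)` —
anchored at the first timestamp, never extrapolated — and then filtered
with a fourth-order Butterworth low-pass at 4 Hz applied forward and
backward (`scipy.signal.filtfilt`), which doubles the attenuation
(squared magnitude `1/(1+(f/4)^8)`) and cancels phase. Edges use reflective
padding of 3× the filter order. Gravity is deliberately *not* removed: the
features operate on filtered raw accelerations, so the vertical channel
carries a ≈9.81 m/s² offset that only affects mean/RMS-type features
uniformly.

Device axes map to body axes through a configurable `AxisMap`; the default
assumes a portrait phone at the posterior pelvis (device y→Vert, x→ML,
z→AP; pitch→tilt, azimuth→rotation, roll→obliquity). Real deployments
should set this per mounting.

## Foot-strike events

A foot strike appears as a peak in the AP acceleration. Candidates come
either from the baseline detector (local maxima of the filtered AP channel
with prominence ≥ 0.3× the trial's AP standard deviation — a deliberately
simple, trial-adaptive stand-in; externally produced candidate labels can
be supplied instead and flow through the same cleanup) or from an external
file. Cleanup has three parts:

1. **Extra-prediction removal.** Each candidate is assigned to its nearest
   AP local maximum; when several candidates share an apex, only the one
   closest to it survives (equidistant ties keep the earlier candidate —
   deterministic and order-stable).
2. **Missed-step insertion.** An inter-strike gap at least 1.5× the
   immediately preceding inter-strike interval is flagged. Inside a flagged
   gap, the largest AP local maximum lying at least `L` samples from both
   flanking strikes is inserted (`source="inserted"`); if no local maximum
   exists in the admissible window, nothing is inserted — no peak, no
   evidence of a step. The locking period `L` is 0.5× the trial's median
   inter-strike interval, recomputed at each pass; passes repeat until no
   gap is flagged (at most 10).
3. **Minimum separation.** A final pass drops the smaller-AP strike of any
   pair closer than `L`. The first two steps alone cannot guarantee this
   spacing (a spurious candidate can attach to a small noise apex adjacent
   to a true one), and downstream step segmentation assumes physiologically
   separated strikes.

The "1.5× the previous pair" gap rule is read as comparing against the
single immediately preceding inter-strike interval; this reading is
isolated behind `CleanupConfig(gap_factor=…)`. On noise-free periodic
synthetic gait the detector plus cleanup recover the generated strikes
exactly at the sample level; on the default noisy cohort, cleanup of
candidates corrupted with 5% spurious and 5% deleted strikes restores
F1 ≥ 0.95 at 100 ms tolerance (both are test assertions).

## Gait features

A *step* spans consecutive (contralateral) strikes, half-open in samples.
Sides alternate strictly; the first window's side comes from the sign of
its mean ML acceleration (positive → left, overridable), since a single
pelvis sensor cannot observe the side directly. Per step, 62 features:

- **Temporal (5).** Cadence `60/step time`; right and left step times (most
  recent step of that side at or before the window); stride time (interval
  between consecutive ipsilateral strikes); symmetry index
  `|R − L| / (0.5(R + L)) × 100` over the most recent right and left step
  times. The earliest one or two windows lack stride/contralateral context
  and carry NaN markers there.
- **Descriptive (27).** Min/max of ML, AP, Vert; mean, SD, RMS of all six
  channels; range of the three orientation channels — all over the window's
  samples.
- **Frequency (30).** From the one-sided amplitude spectrum of the
  mean-removed window zero-padded to a fixed 128-point FFT (uniform bin
  resolution across steps, whose raw length is only ~25 samples at 50 Hz):
  quartile FFT (lowest frequency where cumulative squared amplitude reaches
  25% of the total), maximum FFT amplitude, SD of the amplitude spectrum,
  peak distinction `(max − mean)/mean`, and REOH — the ratio of summed
  squared amplitude at even vs odd harmonics 1–10 of the fundamental
  `1/window duration`, each harmonic read at its nearest bin and the odd
  (denominator) sum floored at machine epsilon. Windows shorter than 8
  samples yield NaN markers for all 30 values.

The trial vector is the min/max/mean/SD (sample SD, ddof 1) of each of the
62 features over all steps, NaN-aware: 248 named values
(`<base>__<stat>`), plus the step count as metadata. A base feature with
fewer than two non-missing steps aborts with an error naming it.

## Labeling, selection, classification

The Activities-specific Balance Confidence (ABC) scale is a 16-item
questionnaire, each item 0–100%; the total is the item mean, and a total of
80% or greater labels the participant *high confidence* (boundary
inclusive). Fall history is carried as metadata only and never enters the
feature matrix.

Correlation-based feature selection (CFS) scores a subset `S` of `k`
features by `merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` with `r̄_cf` the
mean absolute feature–class correlation and `r̄_ff` the mean absolute
pairwise feature–feature correlation. Correlations are Pearson
(point-biserial against the binary label) on internally standardized
features — a deterministic choice in place of discretization-based
symmetrical-uncertainty variants; the merit function is pluggable.
Zero-variance features get correlation 0 (logged). Search is best-first
forward: expand the highest-merit open subset by one feature at a time and
stop after 5 consecutive expansions that fail to improve the best merit.
Ties break toward earlier column order, so selection is deterministic and
permutation-consistent.

The classifier is a random forest (scikit-learn) with 100 trees,
`floor(log2 p) + 1` candidate features per split, unlimited depth and
bootstrap resampling at full sample size. Prediction requires a strict
majority of tree votes for *high*; exact ties go to *low*, the clinically
conservative class (a low-confidence flag triggers follow-up, the cheaper
error). Evaluation is participant-level leave-one-out cross-validation:
one model per held-out participant, confusion matrix accumulated over all
folds, positive class = high confidence, metrics (accuracy, sensitivity,
specificity, precision) reported in percent to one decimal.

Feature selection has two modes. The default, `global`, runs CFS once on
the full cohort before LOOCV — matching an analysis that reports a single
selected-feature set — and is **optimistically biased**: the selected
features have seen the held-out labels. The `nested` mode re-runs CFS
inside every training fold and is the leakage-safe variant. The bias is
not hypothetical: on a null synthetic cohort (identical class parameters,
20 per class) global selection yields LOOCV accuracies systematically
around 65% against a 50% chance baseline, while nested selection is
unbiased (mean ≈ 45% across cohort seeds). Even unbiased, single-cohort
null accuracy is widely dispersed (roughly 30–65% across draws) because
LOOCV training sets overlap almost completely, so fold predictions are
strongly correlated; null-calibration conclusions should average over
cohort draws rather than trust one.

## Synthetic cohorts

The generator emulates the signal statistics the pipeline consumes, not
biomechanics — this grants exact ground truth. Foot strikes follow an
alternating-side renewal process: step durations are lognormal with mean
`60/cadence` (per-side means split ±asymmetry/2) and fractional SD
`step_time_cv`. Signals, evaluated at timestamps jittered lognormally
around 20 ms: AP = 2.5 m/s² Gaussian pulses (SD 0.05 s) at strike times
plus a 20% step-frequency harmonic; Vert = gravity + 1.5 m/s² at step
frequency; ML and the orientation channels are stride-frequency sinusoids
(so their sign alternates with side); white noise (SD 0.15 m/s²) on the
accelerations. Trials last 360 s. All randomness derives from one cohort
seed via per-trial seeds.

Class defaults, chosen once as clinically plausible for lower-limb-amputee
6MWT gait and consistent with low confidence accompanying slower, more
variable, more sway-laden walking: high confidence — cadence 105
steps/min, step-time CV 0.04, asymmetry 0.04, ML sway 0.6 m/s²; low
confidence — cadence 85, CV 0.10, asymmetry 0.12, ML sway 1.2 m/s². ABC
scores are drawn uniformly in [80, 100] (high) and [20, 79.9] (low), so
labels and scores agree by construction.

What the generator does **not** emulate — hence what passing tests do not
show about clinical data: prosthetic-specific waveform shapes, turns at
the hallway ends, fatigue drift, sensor bias/saturation, between-
participant heterogeneity within a class (every participant of a class
shares one parameter set, so trial features cluster far more tightly than
real cohorts), and any overlap between the classes' gait distributions.
Pipeline accuracy on the separated synthetic cohort is therefore a
correctness check, not a performance claim.

## Numerical conventions and degenerate inputs

- Resampling requires trial duration > 2 sample intervals; filtering
  requires > 9× the filter order in samples.
- Descriptive SDs within a step window use population SD (ddof 0, a window
  is the whole object); across-step aggregation uses sample SD (ddof 1,
  steps are draws).
- A constant AP channel yields zero detected candidates (not an error);
  fewer than 3 strikes skip insertion with a warning; fewer than 4 strikes
  abort segmentation (stride and symmetry need context).
- Undefined metric ratios (zero denominator) return NaN and are logged,
  never silently zeroed.
- Reports serialize with sorted keys; identical config + seed reruns are
  byte-identical.

## Problem sizes used in tests and drivers

Unit and property tests run on 45–60 s trials (≈75–100 steps), which
exercise every code path at a fraction of the cost of full trials; the
end-to-end checks and the analysis drivers use full 360 s trials with 20
participants per class, the scale the cohort design describes.
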