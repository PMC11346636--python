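"""Synthetic 6MWT smartphone recordings with ground-truth foot strikes.

The generator emulates the statistical structure the pipeline consumes
rather than simulating biomechanics: foot strikes follow an
alternating-side renewal process (lognormal step durations with a
configurable CV, per-side means split by an asymmetry fraction); the AP
acceleration carries a Gaussian pulse (width 0.1 s) locked to every strike
plus a step-frequency harmonic; the vertical channel oscillates at step
frequency around gravity; ML sway and the three orientation channels are
smooth stride-frequency sinusoids whose sign alternates between sides;
white sensor noise is added to the accelerations, and timestamps are
jittered around the nominal 20 ms spacing.  Class-conditional parameter
sets separate low- from high-confidence gait (slower, more variable, more
sway, more asymmetric).

All randomness flows from a single seed via per-trial derived seeds, so
every fixture is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gaitconf.errors import ValidationError
from gaitconf.preprocess import AxisMap, RawTrial

GRAVITY = 9.81
PULSE_SD_S = 0.05  # Gaussian foot-strike pulse: 0.1 s characteristic width
AP_HARMONIC_FRACTION = 0.2  # step-frequency harmonic relative to pulse amp


@dataclass(frozen=True)
class GaitParams:
    """Parameters of one synthetic trial.

    Units: cadence steps/min; amplitudes m/s^2 (orientation degrees);
    step_time_cv and sampling_jitter are fractional SDs; asymmetry is the
    fractional right/left step-time difference; duration seconds.
    """

    cadence: float = 100.0
    step_time_cv: float = 0.05
    asymmetry: float = 0.05
    ap_pulse_amp: float = 2.5
    ml_sway_amp: float = 0.8
    vert_amp: float = 1.5
    orientation_amp: float = 4.0
    noise_sd: float = 0.15
    sampling_jitter: float = 0.05
    duration: float = 360.0
    nominal_rate: float = 50.0

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValidationError("cadence must be positive")
        if not 0 <= self.step_time_cv < 0.5:
            raise ValidationError("step_time_cv must be in [0, 0.5)")
        if not 0 <= self.asymmetry < 1:
            raise ValidationError("asymmetry must be in [0, 1)")


#: Class defaults: low confidence walks slower, more variably, with more
#: sway and asymmetry than high confidence.
HIGH_CONFIDENCE_PARAMS = GaitParams(
    cadence=105.0, step_time_cv=0.04, asymmetry=0.04, ml_sway_amp=0.6
)
LOW_CONFIDENCE_PARAMS = GaitParams(
    cadence=85.0, step_time_cv=0.10, asymmetry=0.12, ml_sway_amp=1.2
)


@dataclass
class GroundTruth:
    """What the generator knows: true strikes, label, parameters."""

    strike_times: np.ndarray  # seconds, strictly increasing
    sides: np.ndarray  # left / right per strike
    label: str | None = None  # high / low confidence class
    params: GaitParams | None = None

    def __post_init__(self) -> None:
        self.strike_times = np.asarray(self.strike_times, dtype=float)
        self.sides = np.asarray(self.sides, dtype=object)
        if self.strike_times.size and not np.all(np.diff(self.strike_times) > 0):
            raise ValidationError("ground-truth strike times must be increasing")

    def strike_indices(self, rate: float) -> np.ndarray:
        return np.round(self.strike_times * rate).astype(int)


def _lognormal_durations(rng, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _strike_process(params: GaitParams, rng) -> tuple[np.ndarray, np.ndarray]:
    mean_step = 60.0 / params.cadence
    side_means = {
        "right": mean_step * (1 + params.asymmetry / 2),
        "left": mean_step * (1 - params.asymmetry / 2),
    }
    # generous upper bound on the number of steps, then truncate
    n_max = int(np.ceil(params.duration / mean_step * 1.5)) + 4
    times, sides = [], []
    t = mean_step  # first strike one nominal step into the trial
    side = "left"
    draws = {
        s: iter(_lognormal_durations(rng, side_means[s], params.step_time_cv, n_max))
        for s in ("left", "right")
    }
    while t < params.duration:
        times.append(t)
        sides.append(side)
        side = "right" if side == "left" else "left"
        t = t + next(draws[side])
    return np.asarray(times), np.asarray(sides, dtype=object)


def _jittered_timestamps(params: GaitParams, rng) -> np.ndarray:
    nominal_dt = 1.0 / params.nominal_rate
    n = int(np.ceil(params.duration / nominal_dt)) + 1
    dts = _lognormal_durations(rng, nominal_dt, params.sampling_jitter, n)
    t = np.concatenate([[0.0], np.cumsum(dts)])
    return t[t <= params.duration]


def _ap_pulses(t: np.ndarray, strike_times: np.ndarray, amp: float) -> np.ndarray:
    ap = np.zeros_like(t)
    half = 5 * PULSE_SD_S
    for tk in strike_times:
        lo = np.searchsorted(t, tk - half)
        hi = np.searchsorted(t, tk + half)
        ap[lo:hi] += amp * np.exp(-((t[lo:hi] - tk) ** 2) / (2 * PULSE_SD_S**2))
    return ap


def generate_trial(
    params: GaitParams, seed: int, participant_id: str = "synthetic"
) -> tuple[RawTrial, GroundTruth]:
    """One synthetic trial plus its ground truth; same seed, same bits."""
    rng = np.random.default_rng(seed)
    strike_times, sides = _strike_process(params, rng)
    t = _jittered_timestamps(params, rng)

    f_step = params.cadence / 60.0
    f_stride = f_step / 2.0
    t0 = strike_times[0] if strike_times.size else 0.0
    phase_step = 2 * np.pi * f_step * (t - t0)
    phase_stride = 2 * np.pi * f_stride * (t - t0)

    ap = _ap_pulses(t, strike_times, params.ap_pulse_amp)
    ap += AP_HARMONIC_FRACTION * params.ap_pulse_amp * np.cos(phase_step)
    vert = GRAVITY + params.vert_amp * np.sin(phase_step)
    ml = params.ml_sway_amp * np.sin(phase_stride)
    tilt = 5.0 + params.orientation_amp * np.sin(phase_stride)
    rotation = params.orientation_amp * np.sin(phase_stride + 2 * np.pi / 3)
    obliquity = params.orientation_amp * np.sin(phase_stride + 4 * np.pi / 3)
    if params.noise_sd > 0:
        ml = ml + rng.normal(0, params.noise_sd, t.size)
        ap = ap + rng.normal(0, params.noise_sd, t.size)
        vert = vert + rng.normal(0, params.noise_sd, t.size)

    raw = RawTrial(
        participant_id=participant_id,
        timestamps=t,
        ml=ml,
        ap=ap,
        vert=vert,
        tilt=tilt,
        rotation=rotation,
        obliquity=obliquity,
    )
    truth = GroundTruth(strike_times, sides, params=params)
    return raw, truth


@dataclass(frozen=True)
class CohortSpec:
    """A labeled two-class synthetic cohort."""

    n_per_class: int = 20
    params_high: GaitParams = field(default_factory=lambda: HIGH_CONFIDENCE_PARAMS)
    params_low: GaitParams = field(default_factory=lambda: LOW_CONFIDENCE_PARAMS)
    abc_range_high: tuple[float, float] = (80.0, 100.0)
    abc_range_low: tuple[float, float] = (20.0, 79.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 3:
            raise ValidationError("n_per_class must be >= 3")

    def null_variant(self) -> "CohortSpec":
        """Identical class parameters: no class signal beyond noise."""
        return replace(self, params_low=self.params_high)


@dataclass
class CohortTrial:
    participant_id: str
    raw: RawTrial
    truth: GroundTruth
    abc_score: float
    label: str


def generate_cohort(spec: CohortSpec) -> list[CohortTrial]:
    """n_per_class trials per class, ABC scores consistent with labels."""
    rng = np.random.default_rng(spec.seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=2 * spec.n_per_class)
    records: list[CohortTrial] = []
    k = 0
    for label, params, abc_range in (
        ("high", spec.params_high, spec.abc_range_high),
        ("low", spec.params_low, spec.abc_range_low),
    ):
        for i in range(spec.n_per_class):
            pid = f"{label}{i + 1:03d}"
            raw, truth = generate_trial(params, int(trial_seeds[k]), pid)
            truth.label = label
            abc = float(rng.uniform(*abc_range))
            records.append(CohortTrial(pid, raw, truth, abc, label))
            k += 1
    return records


def write_trial_csv(raw: RawTrial, path, axis_map: AxisMap | None = None) -> None:
    """Write a RawTrial in the trial CSV schema (body->device via axis_map)."""
    axis_map = axis_map or AxisMap()
    n = raw.timestamps.size
    cols = {
        "time_s": raw.timestamps,
        "ax": np.zeros(n),
        "ay": np.zeros(n),
        "az": np.zeros(n),
        "gx": raw.gyro[:, 0] if raw.gyro is not None else np.zeros(n),
        "gy": raw.gyro[:, 1] if raw.gyro is not None else np.zeros(n),
        "gz": raw.gyro[:, 2] if raw.gyro is not None else np.zeros(n),
        "azimuth_deg": np.zeros(n),
        "pitch_deg": np.zeros(n),
        "roll_deg": np.zeros(n),
    }
    for body, device in axis_map.as_dict().items():
        cols[device] = getattr(raw, body)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def write_truth_csv(truth: GroundTruth, path) -> None:
    pd.DataFrame(
        {"strike_time_s": truth.strike_times, "side": truth.sides}
    ).to_csv(path, index=False, float_format="%.6f")


def write_cohort(records: list[CohortTrial], outdir, axis_map: AxisMap | None = None) -> pd.DataFrame:
    """Write trial CSVs, ground-truth strike CSVs and the cohort manifest."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for rec in records:
        write_trial_csv(rec.raw, os.path.join(outdir, f"{rec.participant_id}.csv"), axis_map)
        write_truth_csv(rec.truth, os.path.join(outdir, f"{rec.participant_id}_truth.csv"))
        rows.append(
            {
                "participant_id": rec.participant_id,
                "class": rec.label,
                "abc_score": round(rec.abc_score, 2),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(outdir, "cohort.csv"), index=False)
    return manifest
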