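"""Per-step gait features and trial-level aggregation.

A *step* spans consecutive (contralateral) foot strikes, half-open in
samples.  For each step 62 features are computed:

* temporal (5): cadence, right/left step time, stride time, symmetry index
  ``|R - L| / (0.5 (R + L)) x 100`` over the most recent right and left step
  times;
* descriptive statistics (27): min/max of the ML/AP/Vert accelerations,
  mean/SD/RMS of all six channels, and range of the three orientation
  channels, over the window's samples;
* frequency domain (30): quartile FFT, maximum FFT, SD of the FFT,
  peak distinction and REOH (even/odd harmonic energy ratio) for each of
  the six channels, from the one-sided amplitude spectrum of the
  mean-removed window zero-padded to a fixed FFT length.

The trial feature vector is the min/max/mean/SD of each per-step feature
over all steps: 62 x 4 = 248 named values.  Earliest windows lacking
stride/symmetry context carry NaN markers, which aggregation excludes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gaitconf.errors import ValidationError
from gaitconf.footstrike import FootStrikeSeries
from gaitconf.preprocess import CHANNEL_NAMES, UniformTrial

logger = logging.getLogger(__name__)

ACCEL_CHANNELS = ("ml", "ap", "vert")
ORIENT_CHANNELS = ("tilt", "rotation", "obliquity")

TEMPORAL_NAMES = (
    "cadence",
    "step_time_right",
    "step_time_left",
    "stride_time",
    "symmetry_index",
)
DESCRIPTIVE_NAMES = (
    tuple(f"min_{c}" for c in ACCEL_CHANNELS)
    + tuple(f"max_{c}" for c in ACCEL_CHANNELS)
    + tuple(f"mean_{c}" for c in CHANNEL_NAMES)
    + tuple(f"range_{c}" for c in ORIENT_CHANNELS)
    + tuple(f"sd_{c}" for c in CHANNEL_NAMES)
    + tuple(f"rms_{c}" for c in CHANNEL_NAMES)
)
FREQUENCY_BASES = ("quartile_fft", "max_fft", "sd_fft", "peak_distinction", "reoh")
FREQUENCY_NAMES = tuple(
    f"{base}_{c}" for base in FREQUENCY_BASES for c in CHANNEL_NAMES
)

#: The 62 per-step feature names, schema-stable across trials.
STEP_FEATURE_NAMES = TEMPORAL_NAMES + DESCRIPTIVE_NAMES + FREQUENCY_NAMES
assert len(STEP_FEATURE_NAMES) == 62

AGG_STATS = ("min", "max", "mean", "sd")

#: The 248 trial feature names: ``<base>__<stat>``.
TRIAL_FEATURE_NAMES = tuple(
    f"{base}__{stat}" for base in STEP_FEATURE_NAMES for stat in AGG_STATS
)
assert len(TRIAL_FEATURE_NAMES) == 248

DEFAULT_FFT_LEN = 128
MIN_FREQ_WINDOW = 8
REOH_HARMONICS = 10


@dataclass(frozen=True)
class StepWindow:
    """Half-open sample window [start, end) for one step."""

    start: int
    end: int
    side: str  # left / right
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("step window must have end > start")


def segment_steps(
    strikes: FootStrikeSeries, trial: UniformTrial, first_side: str | None = None
) -> list[StepWindow]:
    """Partition [first strike, last strike) into step windows.

    Sides alternate strictly; the first window's side defaults to the sign
    heuristic on the mean ML acceleration of the first window (positive ->
    left), overridable via ``first_side``.
    """
    if len(strikes) < 4:
        raise ValidationError(
            f"trial {trial.participant_id!r}: need >= 4 strikes for stride and "
            f"symmetry features, got {len(strikes)}"
        )
    strikes.validate_against(trial)
    idx = strikes.strikes
    if first_side is None:
        first_ml = trial.ml[idx[0] : idx[1]]
        first_side = "left" if float(np.mean(first_ml)) > 0 else "right"
    if first_side not in ("left", "right"):
        raise ValidationError(f"invalid side {first_side!r}")
    other = {"left": "right", "right": "left"}
    windows = []
    side = first_side
    for s, e in zip(idx[:-1], idx[1:]):
        windows.append(
            StepWindow(int(s), int(e), side, duration=float(e - s) / trial.rate)
        )
        side = other[side]
    return windows


def temporal_features(
    i: int, windows: list[StepWindow], rate: float
) -> dict[str, float]:
    """The 5 temporal features for window ``i``.

    Step times are the duration of the most recent step of each side at or
    before window ``i``; stride time spans consecutive ipsilateral strikes.
    Earliest windows lacking context carry NaN.
    """
    w = windows[i]
    if w.duration <= 0:
        raise ValidationError("non-positive step duration")
    out = dict.fromkeys(TEMPORAL_NAMES, np.nan)
    out["cadence"] = 60.0 / w.duration
    last: dict[str, float] = {}
    for j in range(i, -1, -1):
        if windows[j].side not in last:
            last[windows[j].side] = windows[j].duration
        if len(last) == 2:
            break
    if "right" in last:
        out["step_time_right"] = last["right"]
    if "left" in last:
        out["step_time_left"] = last["left"]
    if i >= 2:
        # sides alternate, so the previous ipsilateral strike opens window i-2
        out["stride_time"] = (windows[i].start - windows[i - 2].start) / rate
    if len(last) == 2:
        r, l = last["right"], last["left"]
        out["symmetry_index"] = abs(r - l) / (0.5 * (r + l)) * 100.0
    return out


def descriptive_features(w: StepWindow, trial: UniformTrial) -> dict[str, float]:
    """The 27 descriptive statistics over the window's samples."""
    out: dict[str, float] = {}
    for name in CHANNEL_NAMES:
        x = getattr(trial, name)[w.start : w.end]
        if name in ACCEL_CHANNELS:
            out[f"min_{name}"] = float(np.min(x))
            out[f"max_{name}"] = float(np.max(x))
        else:
            out[f"range_{name}"] = float(np.max(x) - np.min(x))
        out[f"mean_{name}"] = float(np.mean(x))
        out[f"sd_{name}"] = float(np.std(x))
        out[f"rms_{name}"] = float(np.sqrt(np.mean(x**2)))
    return {k: out[k] for k in DESCRIPTIVE_NAMES}


def _amplitude_spectrum(
    x: np.ndarray, rate: float, fft_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of the mean-removed, zero-padded window."""
    x = x - np.mean(x)
    nfft = max(fft_len, x.size)
    amp = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    return freqs, amp


def frequency_features(
    w: StepWindow, trial: UniformTrial, fft_len: int = DEFAULT_FFT_LEN
) -> dict[str, float]:
    """The 30 frequency-domain features for one step window.

    REOH compares spectral energy at even vs odd harmonics (1-10) of the
    fundamental ``1 / window duration``, reading each harmonic at its
    nearest FFT bin; the odd-energy denominator is guarded by machine
    epsilon.  Windows shorter than 8 samples yield NaN markers.
    """
    out = dict.fromkeys(FREQUENCY_NAMES, np.nan)
    n = w.end - w.start
    if n < MIN_FREQ_WINDOW:
        logger.warning(
            "trial %r: step window of %d samples too short for spectral features",
            trial.participant_id,
            n,
        )
        return out
    f0 = 1.0 / w.duration
    for name in CHANNEL_NAMES:
        x = getattr(trial, name)[w.start : w.end]
        freqs, amp = _amplitude_spectrum(x, trial.rate, fft_len)
        power = amp**2
        total = float(np.sum(power))
        if total > 0:
            cum = np.cumsum(power)
            out[f"quartile_fft_{name}"] = float(freqs[np.searchsorted(cum, 0.25 * total)])
        else:
            out[f"quartile_fft_{name}"] = 0.0
        out[f"max_fft_{name}"] = float(np.max(amp))
        out[f"sd_fft_{name}"] = float(np.std(amp))
        mean_amp = float(np.mean(amp))
        out[f"peak_distinction_{name}"] = (
            (float(np.max(amp)) - mean_amp) / mean_amp if mean_amp > 0 else 0.0
        )
        harmonics = f0 * np.arange(1, REOH_HARMONICS + 1)
        bins = np.clip(
            np.round(harmonics / (freqs[1] - freqs[0])).astype(int), 0, amp.size - 1
        )
        even = float(np.sum(power[bins[1::2]]))  # harmonics 2, 4, ...
        odd = float(np.sum(power[bins[0::2]]))  # harmonics 1, 3, ...
        out[f"reoh_{name}"] = even / max(odd, np.finfo(float).eps)
    return out


def step_features(
    i: int,
    windows: list[StepWindow],
    trial: UniformTrial,
    fft_len: int = DEFAULT_FFT_LEN,
) -> dict[str, float]:
    """All 62 features for window ``i``, in schema order."""
    w = windows[i]
    row = temporal_features(i, windows, trial.rate)
    row.update(descriptive_features(w, trial))
    row.update(frequency_features(w, trial, fft_len))
    return {k: row[k] for k in STEP_FEATURE_NAMES}


def extract_step_matrix(
    trial: UniformTrial,
    strikes: FootStrikeSeries,
    fft_len: int = DEFAULT_FFT_LEN,
    first_side: str | None = None,
) -> pd.DataFrame:
    """n_steps x 62 feature matrix, one row per step window, schema-stable."""
    windows = segment_steps(strikes, trial, first_side=first_side)
    rows = [step_features(i, windows, trial, fft_len) for i in range(len(windows))]
    df = pd.DataFrame(rows, columns=list(STEP_FEATURE_NAMES))
    df.index.name = "step_index"
    return df


def aggregate_trial(step_matrix: pd.DataFrame) -> pd.Series:
    """Aggregate a step matrix to the 248-entry trial feature vector.

    Each base feature contributes its min, max, mean and SD (sample SD,
    ddof=1) over steps, excluding NaN markers; a base feature needs >= 2
    non-missing steps, otherwise a validation error names it.
    """
    if list(step_matrix.columns) != list(STEP_FEATURE_NAMES):
        raise ValidationError("step matrix columns do not match the 62-feature schema")
    out: dict[str, float] = {}
    for base in STEP_FEATURE_NAMES:
        x = step_matrix[base].to_numpy(float)
        x = x[~np.isnan(x)]
        if x.size < 2:
            raise ValidationError(
                f"feature {base!r}: {x.size} non-missing steps, need >= 2"
            )
        out[f"{base}__min"] = float(np.min(x))
        out[f"{base}__max"] = float(np.max(x))
        out[f"{base}__mean"] = float(np.mean(x))
        out[f"{base}__sd"] = float(np.std(x, ddof=1))
    vec = pd.Series(out, dtype=float).reindex(list(TRIAL_FEATURE_NAMES))
    vec.attrs["step_count"] = int(len(step_matrix))
    return vec


def extract_trial_features(
    trial: UniformTrial,
    strikes: FootStrikeSeries,
    fft_len: int = DEFAULT_FFT_LEN,
) -> pd.Series:
    """Convenience: step matrix + aggregation in one call."""
    return aggregate_trial(extract_step_matrix(trial, strikes, fft_len))
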