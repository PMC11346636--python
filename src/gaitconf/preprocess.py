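"""Signal conditioning for smartphone 6MWT recordings.

Smartphone sensor logs have a variable sampling rate near 50 Hz.  Each
channel is linearly interpolated onto a fixed 50 Hz grid anchored at the
first timestamp, then low-pass filtered with a fourth-order zero-lag
(forward-backward) Butterworth filter with a 4 Hz cut-off.  Device axes are
mapped to body axes at the posterior pelvis: medio-lateral (ML),
anterior-posterior (AP) and vertical (Vert) acceleration, and tilt /
rotation / obliquity orientation angles.  Gravity is not removed; features
downstream operate on the filtered raw accelerations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import signal

from gaitconf.errors import ParseError, SchemaError, ValidationError

#: Columns every trial CSV must carry, in no particular order.
TRIAL_CSV_COLUMNS = (
    "time_s",
    "ax",
    "ay",
    "az",
    "gx",
    "gy",
    "gz",
    "azimuth_deg",
    "pitch_deg",
    "roll_deg",
)


@dataclass(frozen=True)
class AxisMap:
    """Mapping from device channels to body-frame channels.

    Defaults assume a portrait phone strapped at the posterior pelvis:
    device y points up (Vert), x across the body (ML), z forward/backward
    (AP); orientation pitch is sagittal tilt, azimuth transverse rotation,
    roll frontal obliquity.
    """

    ml: str = "ax"
    ap: str = "az"
    vert: str = "ay"
    tilt: str = "pitch_deg"
    rotation: str = "azimuth_deg"
    obliquity: str = "roll_deg"

    def as_dict(self) -> dict[str, str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class RawTrial:
    """Variably-sampled multichannel recording, already in body axes."""

    participant_id: str
    timestamps: np.ndarray  # seconds, strictly increasing
    ml: np.ndarray  # m/s^2
    ap: np.ndarray
    vert: np.ndarray
    tilt: np.ndarray  # degrees
    rotation: np.ndarray
    obliquity: np.ndarray
    gyro: np.ndarray | None = None  # (n, 3) rad/s, carried but unused

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        if t.size < 2:
            raise ValidationError(
                f"trial {self.participant_id!r}: need >= 2 samples, got {t.size}"
            )
        if not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"trial {self.participant_id!r}: timestamps must be strictly increasing"
            )
        self.timestamps = t
        for name in ("ml", "ap", "vert", "tilt", "rotation", "obliquity"):
            ch = np.asarray(getattr(self, name), dtype=float)
            if ch.shape != t.shape:
                raise ValidationError(
                    f"trial {self.participant_id!r}: channel {name} has length "
                    f"{ch.size}, expected {t.size}"
                )
            setattr(self, name, ch)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


CHANNEL_NAMES = ("ml", "ap", "vert", "tilt", "rotation", "obliquity")


@dataclass
class UniformTrial:
    """Fixed-rate, body-frame recording (post resampling/filtering)."""

    participant_id: str
    rate: float
    ml: np.ndarray
    ap: np.ndarray
    vert: np.ndarray
    tilt: np.ndarray
    rotation: np.ndarray
    obliquity: np.ndarray

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        n = len(self.ml)
        for name in CHANNEL_NAMES:
            ch = np.asarray(getattr(self, name), dtype=float)
            if ch.size != n:
                raise ValidationError(
                    f"channel {name} has length {ch.size}, expected {n}"
                )
            setattr(self, name, ch)

    @property
    def n_samples(self) -> int:
        return int(len(self.ml))

    def channels(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNEL_NAMES}

    def replace_channels(self, **channels: np.ndarray) -> "UniformTrial":
        data = self.channels()
        data.update(channels)
        return UniformTrial(self.participant_id, self.rate, **data)


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate_hz: float = 50.0
    filter_order: int = 4
    cutoff_hz: float = 4.0
    axis_map: AxisMap = field(default_factory=AxisMap)

    def __post_init__(self) -> None:
        if self.cutoff_hz >= self.target_rate_hz / 2:
            raise ValidationError("cutoff_hz must be below the Nyquist frequency")
        if self.filter_order < 2 or self.filter_order % 2 != 0:
            raise ValidationError("filter_order must be even and >= 2")


def load_trial(path, axis_map: AxisMap | None = None, participant_id: str | None = None) -> RawTrial:
    """Read one trial CSV and map device channels onto body axes.

    The CSV must carry the header ``time_s,ax,ay,az,gx,gy,gz,azimuth_deg,
    pitch_deg,roll_deg``.  Non-increasing timestamps and malformed rows are
    rejected with errors naming the offending line.
    """
    axis_map = axis_map or AxisMap()
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in TRIAL_CSV_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna())[0]) + 2  # 1-based + header
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    t = df["time_s"].to_numpy(float)
    if not np.all(np.diff(t) > 0):
        line = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise ValidationError(f"{path}: non-increasing timestamp at line {line}")
    if participant_id is None:
        import os

        participant_id = os.path.splitext(os.path.basename(str(path)))[0]
    m = axis_map.as_dict()
    return RawTrial(
        participant_id=participant_id,
        timestamps=t,
        ml=df[m["ml"]].to_numpy(float),
        ap=df[m["ap"]].to_numpy(float),
        vert=df[m["vert"]].to_numpy(float),
        tilt=df[m["tilt"]].to_numpy(float),
        rotation=df[m["rotation"]].to_numpy(float),
        obliquity=df[m["obliquity"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
    )


def resample_fixed_rate(raw: RawTrial, cfg: PreprocessConfig | None = None) -> UniformTrial:
    """Linearly interpolate every channel onto a fixed-rate grid.

    The grid is ``t_k = t_0 + k / rate`` for ``k = 0 .. floor((t_last - t_0)
    * rate)``; no sample is extrapolated beyond the recording.
    """
    cfg = cfg or PreprocessConfig()
    rate = cfg.target_rate_hz
    if raw.duration <= 2.0 / rate:
        raise ValidationError(
            f"trial {raw.participant_id!r}: duration {raw.duration:.4f}s too short "
            f"to resample at {rate} Hz"
        )
    t0 = raw.timestamps[0]
    n_out = int(np.floor(raw.duration * rate)) + 1
    grid = t0 + np.arange(n_out) / rate
    out = {
        name: np.interp(grid, raw.timestamps, getattr(raw, name))
        for name in CHANNEL_NAMES
    }
    return UniformTrial(raw.participant_id, rate, **out)


def lowpass_zero_lag(trial: UniformTrial, cfg: PreprocessConfig | None = None) -> UniformTrial:
    """Zero-lag Butterworth low-pass of all six channels.

    A ``filter_order`` Butterworth filter at ``cutoff_hz`` is applied forward
    then backward (net phase zero, squared magnitude response).  Edges are
    handled by reflective padding of length 3x the filter order.
    """
    cfg = cfg or PreprocessConfig()
    padlen = 3 * cfg.filter_order
    if trial.n_samples <= 3 * padlen:
        raise ValidationError(
            f"trial {trial.participant_id!r}: {trial.n_samples} samples too few "
            f"for stable forward-backward filtering (need > {3 * padlen})"
        )
    b, a = signal.butter(cfg.filter_order, cfg.cutoff_hz, btype="low", fs=trial.rate)
    filtered = {
        name: signal.filtfilt(b, a, ch, padtype="even", padlen=padlen)
        for name, ch in trial.channels().items()
    }
    return trial.replace_channels(**filtered)


def preprocess_trial(raw: RawTrial, cfg: PreprocessConfig | None = None) -> UniformTrial:
    """Resample to the target rate then low-pass filter (the full stage)."""
    cfg = cfg or PreprocessConfig()
    return lowpass_zero_lag(resample_fixed_rate(raw, cfg), cfg)
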