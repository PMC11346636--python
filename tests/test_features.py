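"""Step segmentation, the 62 per-step features, and 248-feature aggregation."""

import numpy as np
import pandas as pd
import pytest

from gaitconf.errors import ValidationError
from gaitconf.features import (
    ACCEL_CHANNELS,
    STEP_FEATURE_NAMES,
    TRIAL_FEATURE_NAMES,
    StepWindow,
    aggregate_trial,
    descriptive_features,
    extract_step_matrix,
    frequency_features,
    segment_steps,
    step_features,
    temporal_features,
)
from gaitconf.footstrike import FootStrikeSeries, clean_footstrikes, detect_candidates
from gaitconf.preprocess import CHANNEL_NAMES, UniformTrial


def _trial(n=400, rate=50.0, **channels) -> UniformTrial:
    data = {name: channels.get(name, np.zeros(n)) for name in CHANNEL_NAMES}
    return UniformTrial("t", rate, **data)


def _windows(durations_s, rate=50.0, first_side="left"):
    """Step windows from a list of step durations (seconds)."""
    bounds = np.concatenate([[0], np.cumsum(np.asarray(durations_s) * rate)]).astype(int)
    sides = [first_side if i % 2 == 0 else ("right" if first_side == "left" else "left")
             for i in range(len(durations_s))]
    return [
        StepWindow(int(s), int(e), side, (e - s) / rate)
        for s, e, side in zip(bounds[:-1], bounds[1:], sides)
    ]


class TestSegmentSteps:
    def test_partitions_interval_between_strikes(self):
        strikes = FootStrikeSeries.from_indices(np.arange(10) * 30)
        windows = segment_steps(strikes, _trial(n=300))
        assert len(windows) == 9
        assert windows[0].start == 0 and windows[-1].end == 270
        for a, b in zip(windows[:-1], windows[1:]):
            assert a.end == b.start

    def test_durations_from_sample_indices(self):
        strikes = FootStrikeSeries.from_indices([0, 25, 50, 75])
        windows = segment_steps(strikes, _trial(n=100))
        assert [w.duration for w in windows] == [0.5, 0.5, 0.5]

    def test_sides_strictly_alternate(self):
        strikes = FootStrikeSeries.from_indices(np.arange(8) * 25)
        windows = segment_steps(strikes, _trial(n=250))
        sides = [w.side for w in windows]
        assert all(a != b for a, b in zip(sides[:-1], sides[1:]))

    def test_first_side_from_ml_sign(self):
        ml = np.ones(250)
        strikes = FootStrikeSeries.from_indices(np.arange(8) * 25)
        assert segment_steps(strikes, _trial(n=250, ml=ml))[0].side == "left"
        assert segment_steps(strikes, _trial(n=250, ml=-ml))[0].side == "right"

    def test_too_few_strikes_rejected(self):
        strikes = FootStrikeSeries.from_indices([0, 25, 50])
        with pytest.raises(ValidationError, match="4 strikes"):
            segment_steps(strikes, _trial(n=100))


class TestTemporal:
    def test_cadence_from_step_duration(self):
        w = _windows([0.5, 0.5, 0.5, 0.5])
        assert temporal_features(2, w, 50.0)["cadence"] == pytest.approx(120.0)

    def test_symmetric_steps_give_zero_index(self):
        w = _windows([0.5, 0.5, 0.5, 0.5])
        assert temporal_features(3, w, 50.0)["symmetry_index"] == pytest.approx(0.0)

    def test_asymmetric_steps_give_forty_percent(self):
        # most recent left = 0.4 s, right = 0.6 s: |0.6-0.4|/0.5 * 100 / (0.5+0.5)
        w = _windows([0.4, 0.6, 0.4, 0.6], first_side="left")
        f = temporal_features(3, w, 50.0)
        assert f["step_time_right"] == pytest.approx(0.6)
        assert f["step_time_left"] == pytest.approx(0.4)
        assert f["symmetry_index"] == pytest.approx(40.0)

    def test_stride_time_spans_ipsilateral_strikes(self):
        w = _windows([0.4, 0.6, 0.4, 0.6])
        # strike opening window 2 is at 1.0 s; previous ipsilateral at 0.0 s
        assert temporal_features(2, w, 50.0)["stride_time"] == pytest.approx(1.0)

    def test_earliest_windows_carry_missing_markers(self):
        w = _windows([0.5, 0.5, 0.5, 0.5], first_side="left")
        f0 = temporal_features(0, w, 50.0)
        assert np.isnan(f0["stride_time"]) and np.isnan(f0["symmetry_index"])
        assert np.isnan(f0["step_time_right"])
        assert f0["step_time_left"] == pytest.approx(0.5)
        f1 = temporal_features(1, w, 50.0)
        assert np.isnan(f1["stride_time"])
        assert not np.isnan(f1["symmetry_index"])


class TestDescriptive:
    def test_constant_channel(self):
        trial = _trial(vert=np.full(400, 9.81))
        f = descriptive_features(StepWindow(0, 50, "left", 1.0), trial)
        for stat in ("min", "max", "mean", "rms"):
            assert f[f"{stat}_vert"] == pytest.approx(9.81)
        assert f["sd_vert"] == pytest.approx(0.0)

    def test_zero_mean_unit_rms(self):
        ml = np.tile([-1.0, 1.0], 200)
        f = descriptive_features(StepWindow(0, 50, "left", 1.0), _trial(ml=ml))
        assert f["mean_ml"] == pytest.approx(0.0)
        assert f["rms_ml"] == pytest.approx(1.0)

    def test_orientation_range(self):
        tilt = np.linspace(-3, 5, 400)
        f = descriptive_features(StepWindow(0, 400, "left", 8.0), _trial(tilt=tilt))
        assert f["range_tilt"] == pytest.approx(8.0)

    def test_min_mean_max_ordering(self, rng):
        trial = _trial(ap=rng.normal(size=400))
        f = descriptive_features(StepWindow(10, 60, "left", 1.0), trial)
        for c in ACCEL_CHANNELS:
            assert f[f"min_{c}"] <= f[f"mean_{c}"] <= f[f"max_{c}"]
            assert f[f"rms_{c}"] >= abs(f[f"mean_{c}"])


class TestFrequency:
    # 64-sample window at 50 Hz zero-padded to 128: the fundamental
    # 1/1.28 s = 0.78125 Hz falls exactly on bin 2, its harmonics on even
    # bins, and the rectangular-window nulls on every other even bin.

    def _window_trial(self, freq_hz, n=64):
        t = np.arange(200) / 50.0
        return (
            _trial(n=200, ap=np.sin(2 * np.pi * freq_hz * t)),
            StepWindow(0, n, "left", n / 50.0),
        )

    def test_fundamental_sine_has_near_zero_reoh(self):
        trial, w = self._window_trial(0.78125)
        assert frequency_features(w, trial)["reoh_ap"] < 1e-6

    def test_second_harmonic_sine_has_huge_reoh(self):
        trial, w = self._window_trial(2 * 0.78125)
        assert frequency_features(w, trial)["reoh_ap"] > 1e3

    def test_quartile_fft_at_single_line(self):
        # 128-sample window needs no padding: a bin-exact sine is a single
        # spectral line, so cumulative power crosses 25% right at its bin
        trial, w = self._window_trial(3 * 0.390625, n=128)
        assert frequency_features(w, trial)["quartile_fft_ap"] == pytest.approx(
            3 * 0.390625
        )

    def test_short_window_yields_missing_markers(self):
        trial = _trial()
        f = frequency_features(StepWindow(0, 5, "left", 0.1), trial)
        assert all(np.isnan(v) for v in f.values())

    def test_spectrum_statistics_against_direct_fft(self, rng):
        trial = _trial(ap=rng.normal(size=400))
        w = StepWindow(20, 52, "left", 32 / 50.0)
        f = frequency_features(w, trial)
        x = trial.ap[20:52]
        amp = np.abs(np.fft.rfft(x - x.mean(), n=128))
        assert f["max_fft_ap"] == pytest.approx(np.max(amp))
        assert f["sd_fft_ap"] == pytest.approx(np.std(amp))
        assert f["peak_distinction_ap"] == pytest.approx(
            (np.max(amp) - np.mean(amp)) / np.mean(amp)
        )


class TestStepMatrix:
    def test_shape_and_schema(self, synthetic_trial, cleaned_strikes):
        trial, _ = synthetic_trial
        mat = extract_step_matrix(trial, cleaned_strikes)
        assert mat.shape == (len(cleaned_strikes) - 1, 62)
        assert list(mat.columns) == list(STEP_FEATURE_NAMES)

    def test_missing_only_in_earliest_windows(self, synthetic_trial, cleaned_strikes):
        trial, _ = synthetic_trial
        mat = extract_step_matrix(trial, cleaned_strikes)
        assert not mat.iloc[2:].isna().any().any()

    def test_three_step_toy_against_hand_computation(self):
        # strikes at 0, 25, 50, 75 (0.5 s steps); simple deterministic channels
        rate = 50.0
        n = 100
        t = np.arange(n) / rate
        trial = _trial(
            n=n,
            ml=np.ones(n),
            ap=2 * t,
            vert=np.full(n, 9.81),
            tilt=np.linspace(0, 9.9, n),
        )
        strikes = FootStrikeSeries.from_indices([0, 25, 50, 75])
        mat = extract_step_matrix(trial, strikes, first_side="left")
        row = mat.iloc[0]
        assert row["cadence"] == pytest.approx(120.0)
        assert row["step_time_left"] == pytest.approx(0.5)
        assert np.isnan(row["step_time_right"])
        # AP = 2t over window [0, 0.5): min 0, max 2*(24/50)=0.96
        assert row["min_ap"] == pytest.approx(0.0)
        assert row["max_ap"] == pytest.approx(0.96)
        assert row["mean_ap"] == pytest.approx(np.mean(2 * t[:25]))
        assert row["sd_ap"] == pytest.approx(np.std(2 * t[:25]))
        assert row["rms_ap"] == pytest.approx(np.sqrt(np.mean((2 * t[:25]) ** 2)))
        assert row["mean_ml"] == pytest.approx(1.0)
        assert row["sd_ml"] == pytest.approx(0.0)
        # tilt rises 0.1 deg per sample: range over 25 samples = 2.4
        assert row["range_tilt"] == pytest.approx(2.4)


class TestAggregate:
    def test_vector_has_248_named_entries(self, synthetic_trial, cleaned_strikes):
        trial, _ = synthetic_trial
        vec = aggregate_trial(extract_step_matrix(trial, cleaned_strikes))
        assert vec.size == 248
        assert list(vec.index) == list(TRIAL_FEATURE_NAMES)

    def test_identical_steps_collapse(self):
        row = {name: float(i) for i, name in enumerate(STEP_FEATURE_NAMES)}
        mat = pd.DataFrame([row] * 5, columns=list(STEP_FEATURE_NAMES))
        vec = aggregate_trial(mat)
        for i, base in enumerate(STEP_FEATURE_NAMES):
            assert vec[f"{base}__sd"] == pytest.approx(0.0)
            assert vec[f"{base}__min"] == vec[f"{base}__max"] == float(i)

    def test_two_step_toy_matches_hand_computation(self):
        mat = pd.DataFrame(
            [dict.fromkeys(STEP_FEATURE_NAMES, 1.0), dict.fromkeys(STEP_FEATURE_NAMES, 3.0)],
            columns=list(STEP_FEATURE_NAMES),
        )
        vec = aggregate_trial(mat)
        assert vec["cadence__min"] == 1.0 and vec["cadence__max"] == 3.0
        assert vec["cadence__mean"] == pytest.approx(2.0)
        assert vec["cadence__sd"] == pytest.approx(np.sqrt(2))  # ddof=1

    def test_aggregated_ordering_invariant(self, synthetic_trial, cleaned_strikes):
        trial, _ = synthetic_trial
        vec = aggregate_trial(extract_step_matrix(trial, cleaned_strikes))
        for base in STEP_FEATURE_NAMES:
            assert vec[f"{base}__min"] <= vec[f"{base}__mean"] <= vec[f"{base}__max"]

    def test_entirely_missing_feature_rejected(self):
        mat = pd.DataFrame(
            [dict.fromkeys(STEP_FEATURE_NAMES, 1.0)] * 4,
            columns=list(STEP_FEATURE_NAMES),
        )
        mat["stride_time"] = np.nan
        with pytest.raises(ValidationError, match="stride_time"):
            aggregate_trial(mat)


class TestFeatureInvariants:
    def test_time_shift_leaves_features_unchanged(self, synthetic_trial, cleaned_strikes):
        trial, _ = synthetic_trial
        k = 40
        shifted = UniformTrial(
            trial.participant_id,
            trial.rate,
            **{n: np.concatenate([np.zeros(k), ch]) for n, ch in trial.channels().items()},
        )
        strikes_shifted = FootStrikeSeries.from_indices(cleaned_strikes.strikes + k)
        a = extract_step_matrix(trial, cleaned_strikes, first_side="left")
        b = extract_step_matrix(shifted, strikes_shifted, first_side="left")
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9, equal_nan=True)

    def test_amplitude_scaling_behaviour(self, synthetic_trial, cleaned_strikes):
        trial, _ = synthetic_trial
        c = 2.5
        scaled = trial.replace_channels(
            ml=c * trial.ml, ap=c * trial.ap, vert=c * trial.vert
        )
        a = extract_step_matrix(trial, cleaned_strikes, first_side="left")
        b = extract_step_matrix(scaled, cleaned_strikes, first_side="left")
        scale_by_c = [
            f"{stat}_{ch}" for stat in ("min", "max", "mean", "sd", "rms") for ch in ACCEL_CHANNELS
        ] + [f"{stat}_{ch}" for stat in ("max_fft", "sd_fft") for ch in ACCEL_CHANNELS]
        unchanged = list(STEP_FEATURE_NAMES[:5]) + [
            f"{stat}_{ch}"
            for stat in ("quartile_fft", "peak_distinction", "reoh")
            for ch in ACCEL_CHANNELS
        ]
        for col in scale_by_c:
            assert np.allclose(b[col], c * a[col], rtol=1e-9, equal_nan=True)
        for col in unchanged:
            assert np.allclose(b[col], a[col], rtol=1e-9, equal_nan=True)

    def test_periodic_gait_gives_constant_features(self, noiseless_trial):
        trial, truth = noiseless_trial
        strikes = FootStrikeSeries.from_indices(truth.strike_indices(trial.rate))
        mat = extract_step_matrix(trial, strikes).iloc[4:-4]
        # stride-periodic channels repeat only side-to-side: check same-side steps
        for parity in (0, 1):
            sub = mat.iloc[parity::2]
            # normalize by the feature's scale, floored so features whose
            # value is itself ~0 (e.g. min ML at a zero crossing) do not
            # inflate a float-precision wobble into a large relative SD
            rel = sub.std() / sub.abs().mean().clip(lower=1e-3)
            assert float(rel.max()) < 1e-6
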