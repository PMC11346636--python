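import dataclasses

import numpy as np
import pytest

from gaitconf.footstrike import clean_footstrikes, detect_candidates
from gaitconf.preprocess import preprocess_trial
from gaitconf.synthetic import GaitParams, generate_trial

SHORT = dict(duration=60.0)


@pytest.fixture(scope="session")
def default_params():
    """One-minute trial with the generator's default gait regime."""
    return GaitParams(**SHORT)


@pytest.fixture(scope="session")
def noiseless_params():
    """Perfectly periodic gait: no step-time jitter, noise, or asymmetry."""
    return GaitParams(
        cadence=120.0,
        step_time_cv=0.0,
        asymmetry=0.0,
        noise_sd=0.0,
        sampling_jitter=0.0,
        **SHORT,
    )


@pytest.fixture(scope="session")
def synthetic_trial(default_params):
    raw, truth = generate_trial(default_params, seed=11, participant_id="syn")
    return preprocess_trial(raw), truth


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_params):
    raw, truth = generate_trial(noiseless_params, seed=3, participant_id="clean")
    return preprocess_trial(raw), truth


@pytest.fixture(scope="session")
def cleaned_strikes(synthetic_trial):
    trial, _ = synthetic_trial
    return clean_footstrikes(detect_candidates(trial), trial)


def short_params(**overrides) -> GaitParams:
    return dataclasses.replace(GaitParams(**SHORT), **overrides)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
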