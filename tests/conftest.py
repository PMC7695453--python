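import numpy as np
import pytest
from hypothesis import settings

import betafeedback as bf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

TEST_RATE = 512.0  # keeps the suite fast; the default study rate is 2048 Hz


@pytest.fixture(scope="session")
def small_config():
    return bf.default_config(sampling_rate=TEST_RATE, n_trials_per_condition=3, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    return bf.generate_session(small_config)


@pytest.fixture(scope="session")
def analyzed_session(small_session):
    rec, events, gt = small_session
    band = bf.BetaBandSpec(channel="LFP", center_f=20.0)
    table = bf.analyze_session(rec, events, band, hemisphere="H0")
    return table, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
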