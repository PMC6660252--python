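import numpy as np
import pytest

from seegspeed import spectral
from seegspeed.synthetic import SimulationConfig, generate_session

SMALL_PAIR = (1, "beta", 0.5)


@pytest.fixture(scope="session")
def small_config():
    """A 4-channel, 30-trial session with one informative beta-band pair —
    small enough for repeated spectral analysis in tests."""
    return SimulationConfig(n_channels=4, n_trials=30,
                            informative_pairs=(SMALL_PAIR,), rng_seed=7)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_spectrograms(small_session):
    return spectral.compute_session_spectrograms(small_session)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
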