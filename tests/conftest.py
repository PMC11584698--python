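import numpy as np
import pytest

from cardiomotor import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_trials_left=15, n_trials_right=15, seed=7)


@pytest.fixture(scope="session")
def session_and_truth(small_config):
    session, events, truth = simulate_session(small_config)
    return session, events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
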