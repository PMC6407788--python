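import numpy as np
import pytest

from placedecode import ArenaSpec, validate_session
from placedecode.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A short open-field session shared by decoder/evaluation tests."""
    cfg = SimConfig(n_place_units=12, n_interneurons=1, duration_s=180,
                    rng_seed=7)
    spikes, traj, tuning = simulate_session(cfg, ArenaSpec())
    return cfg, spikes, traj, tuning


@pytest.fixture(scope="session")
def small_span(small_session):
    _, spikes, traj, _ = small_session
    return validate_session(spikes, traj).usable_span


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
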