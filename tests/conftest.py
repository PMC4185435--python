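import numpy as np
import pytest

from scratchabc import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def paper_sim_config():
    """Reference geometry: 36 x 27 sites, band Y0=10, N0=100, tau=1/24 h."""
    return SimulationConfig(
        X=36, Y=27, Y0=10, N0=100, Pm=0.25, Pp=2e-3,
        delta=25.0, tau=1.0 / 24.0, snapshot_times=[4.0, 8.0, 12.0], seed=7,
    )


@pytest.fixture
def small_sim_config():
    """Small, fast geometry for chain-level tests."""
    return SimulationConfig(
        X=12, Y=10, Y0=4, N0=20, Pm=0.3, Pp=5e-3,
        delta=25.0, tau=1.0 / 24.0, snapshot_times=[1.0, 2.0], seed=3,
    )
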