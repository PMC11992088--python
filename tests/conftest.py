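import numpy as np
import pytest

from longcal.config import SimulationConfig
from longcal.simulate import render_sessions


@pytest.fixture(scope="session")
def single_session():
    """One simulated session at the default study conditions (scaled FOV)."""
    cfg = SimulationConfig(fov_shape=(96, 128), n_neurons=30,
                           frames_per_session=400, n_sessions=1, seed=7)
    videos, truth = render_sessions(cfg)
    return cfg, videos[0], truth


@pytest.fixture(scope="session")
def misaligned_pair():
    """Two sessions with ~8 um (4 px) non-rigid inter-session misalignment."""
    cfg = SimulationConfig(fov_shape=(96, 128), n_neurons=40,
                           frames_per_session=300, n_sessions=2,
                           misalign_amplitude_um=8.0, seed=3)
    videos, truth = render_sessions(cfg)
    return cfg, videos, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
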