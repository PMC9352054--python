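import numpy as np
import pytest

from cionaswim import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_recording():
    """A 30-s default-condition simulated recording with ground truth."""
    cfg = sd.SwimSimConfig(duration_s=30.0, seed=42)
    return sd.simulate_recording(cfg) + (cfg,)


@pytest.fixture(scope="session")
def straight_skeleton():
    """49 collinear points along +x, 2 px apart."""
    pts = np.zeros((49, 2))
    pts[:, 0] = np.arange(49) * 2.0
    return pts


@pytest.fixture
def rng():
    return np.random.default_rng(0)
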