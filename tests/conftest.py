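import numpy as np
import pytest

from astroca.config import SimulationConfig
from astroca.datatypes import CompartmentMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cmap():
    """16x16 map: one soma label, one process label, neuropil as fov."""
    labels = np.ones((16, 16), dtype=int)
    labels[2:6, 2:6] = 2
    labels[8:12, 8:14] = 3
    return CompartmentMap(labels=labels, classes={1: "fov", 2: "soma", 3: "process"})


@pytest.fixture
def quick_sim():
    """Small, quiet-noise simulation used by several detection tests."""
    return SimulationConfig(seed=11, duration=20.0, n_events=3, noise_sigma=0.0)
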