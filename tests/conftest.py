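import numpy as np
import pytest

from phenoseg.synthetic_scene import simulate_scene


@pytest.fixture(scope="session")
def small_scene():
    """200x200 px mixed-class scene with moderate noise."""
    return simulate_scene(extent=(600.0, 600.0), noise_sd=0.02, seed=3)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Small noiseless scene for exactness checks."""
    return simulate_scene(extent=(450.0, 450.0), noise_sd=0.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
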