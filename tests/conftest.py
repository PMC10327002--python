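import numpy as np
import pytest

from punctacoloc import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240712)


@pytest.fixture
def small_sim_config():
    """A down-scaled simulation: 30 positions on a 256x256 image."""
    return SimulationConfig(
        width=256,
        height=256,
        n_positions=30,
        n_red_only=10,
        n_green_only=10,
        n_both=10,
        n_images_per_level=2,
        noise_multipliers=(0.0, 1.0),
        seed=7,
    )
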