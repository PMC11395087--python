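import numpy as np
import pytest

from ginkgoflav.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A desk-sized dataset: 12 samples, 32x32 cubes, 60 bands."""
    return SimulationConfig(
        n_lobed=6, n_unlobed=6, image_height=32, image_width=32,
        n_bands=60, n_gross_outliers=0, seed=7)


@pytest.fixture
def small_table(small_config):
    from ginkgoflav.simulate import simulate_spectra_table

    return simulate_spectra_table(small_config)
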