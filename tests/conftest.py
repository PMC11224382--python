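import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from podfusion.synthetic import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, fast generator configuration for unit tests."""
    return GeneratorConfig(n_per_class=3, rgb_size=(44, 42), seed=7)


@pytest.fixture
def clean_config():
    """Noise- and scatter-free configuration: spectra equal class templates."""
    return GeneratorConfig(
        n_per_class=2,
        spectral_noise_sd=0.0,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        rgb_size=(44, 42),
        seed=7,
    )
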