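import numpy as np
import pytest

from ramanoise import (GeneratorConfig, NoiseSimConfig, SpectralAxis,
                       estimate_noise_svd, simulate_noise_bank)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    """256-channel axis spanning 0-1600 cm^-1, cheap enough for unit tests."""
    return SpectralAxis.from_range(0.0, 1600.0, 256)


@pytest.fixture
def small_gen_cfg(small_axis):
    return GeneratorConfig(axis=small_axis, target_snr_db=None)


@pytest.fixture
def small_noise_bank(small_axis):
    """Noise-only bank on the small axis (background removed by SVD)."""
    cfg = NoiseSimConfig(axis=small_axis, n_per_condition=40,
                         integration_times_s=(0.1, 0.3, 0.5), seed=7)
    return estimate_noise_svd(simulate_noise_bank(cfg))
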