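import numpy as np
import pytest

from clampkit import GeneratorConfig, SpikeShape


@pytest.fixture
def clean_cfg():
    """Noise-free, unfiltered acquisition: exact round trips."""
    return GeneratorConfig(duration=5.0, noise_sd=0.0, lowpass_cutoff=None, seed=1)


@pytest.fixture
def noisy_cfg():
    """Realistic acquisition chain: 0.3 mV noise, 1 kHz low-pass."""
    return GeneratorConfig(duration=5.0, noise_sd=0.3, lowpass_cutoff=1000.0, seed=1)


@pytest.fixture
def default_shape():
    return SpikeShape()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
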