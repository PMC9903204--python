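import numpy as np
import pytest

from chromassay import synthio


@pytest.fixture
def quiet_cfg():
    """Zero-noise generator config with fine lane sampling."""
    return synthio.SynthConfig(seed=0, noise_sd=0.0, sampling=1200)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
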