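import numpy as np
import pytest

from aggremap import AnalysisConfig


@pytest.fixture
def config():
    """Default analysis + generator configuration."""
    return AnalysisConfig()


@pytest.fixture
def clean_config():
    """Noise-free generator: no blur, no background, no shot/read noise."""
    return AnalysisConfig(psf_sigma_px=0.0, background_level=0.0,
                          read_noise_sigma=0.0, poisson_noise=False,
                          spurious_count=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
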