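import numpy as np
import pytest

from sonoseg.graph import RgbParams


@pytest.fixture
def two_half_image():
    """8x8 image, left half 50 / right half 200: merges into two regions."""
    img = np.zeros((8, 8), dtype=np.uint8)
    img[:, :4] = 50
    img[:, 4:] = 200
    return img


@pytest.fixture
def two_half_params():
    return RgbParams(k=100, alpha=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
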