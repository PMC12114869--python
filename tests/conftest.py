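import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mask_pair(rng):
    a = np.where(rng.random((8, 8)) > 0.5, 255, 0).astype(np.uint8)
    b = np.where(rng.random((8, 8)) > 0.5, 255, 0).astype(np.uint8)
    return a, b
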