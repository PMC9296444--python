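import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_similarity(rng, dim, scale=2.5):
    """A random similarity transform: rotation + positive scale + shift."""
    Q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    shift = rng.standard_normal(dim) * 3.0
    return lambda X: scale * X @ Q + shift


@pytest.fixture
def similarity():
    return random_similarity
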