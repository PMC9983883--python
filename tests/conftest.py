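import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_image():
    """A small fuzzy image with a spread of membership levels."""
    import inspire as ip

    gen = np.random.default_rng(42)
    return ip.FuzzyImage(gen.random((8, 8)))
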