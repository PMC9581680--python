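import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    """A generic mid-size random gray image."""
    return rng.uniform(0.0, 1.0, size=(32, 32))


@pytest.fixture
def phantom_pair():
    from irgfuse import make_pair

    return make_pair(128, 7)
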