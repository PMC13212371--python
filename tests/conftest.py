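import numpy as np
import pytest

from helpers_phantoms import make_random_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_phantom():
    return make_random_phantom(seed=7)
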