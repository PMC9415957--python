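import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def motivating_probs():
    """Ring probabilities of the two five-ring scatters whose distribution
    entropies coincide but whose radial layouts differ (inner -> outer)."""
    return np.array([1 / 15, 2 / 15, 1 / 5, 4 / 15, 1 / 3])
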