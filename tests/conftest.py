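import numpy as np
import pytest

from panicwave import SocialNetwork, make_fixture


@pytest.fixture
def micro_net() -> SocialNetwork:
    """Deterministic 5-node star, hub 0."""
    return make_fixture("micro_net")


@pytest.fixture
def path3() -> SocialNetwork:
    """3-node path 0-1-2."""
    return SocialNetwork(3, 1, np.array([[0, 1], [1, 2]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
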