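import numpy as np
import pytest

from msgnet.synthetic import CommunitySpec, default_community, generate_censuses


@pytest.fixture(scope="session")
def community() -> CommunitySpec:
    return default_community(seed=7)


@pytest.fixture(scope="session")
def census(community):
    return generate_censuses(community)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
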