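import pytest

from netpharm.network import functional_profile_matrix
from netpharm.synthetic import generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world: 1000-node network, 200 drugs in 20
    families, feature noise 0.3, 50 leave-one-out queries, seed 42."""
    return generate_world(seed=42)


@pytest.fixture(scope="session")
def default_profiles(default_world):
    w = default_world
    return functional_profile_matrix(w.net, w.space)


@pytest.fixture(scope="session")
def small_world():
    """A desk-size world for fast pipeline-level tests."""
    return generate_world(seed=7, n_nodes=200, n_drugs=40, n_families=8, n_queries=10)
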