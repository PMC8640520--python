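import pytest

from mesplice.simulate import (
    WorldConfig,
    build_world,
    make_scn1a_like_fixture,
)


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by read-only tests."""
    return build_world(WorldConfig(seed=11, n_genes=80))


@pytest.fixture(scope="session")
def scn_fixture(small_world):
    return make_scn1a_like_fixture(small_world)
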