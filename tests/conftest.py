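import numpy as np
import pytest

from tescout import build_kmer_index, make_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world, seed-pinned, shared across tests."""
    return make_world(seed=1)


@pytest.fixture(scope="session")
def kmer_index(world):
    return build_kmer_index(world.genome, 40)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
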