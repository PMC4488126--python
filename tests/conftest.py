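import numpy as np
import pytest

from rrbskit.reference import MSPI, digest, index_cytosines
from rrbskit.simulate import random_genome


@pytest.fixture(scope="session")
def small_genome():
    """100 kb random chromosome shared by simulation-based tests."""
    return random_genome(100_000, seed=20240901)


@pytest.fixture(scope="session")
def small_fragments(small_genome):
    return digest(small_genome, [MSPI], 90, 220)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return index_cytosines(small_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
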