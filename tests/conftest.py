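import numpy as np
import pytest

from treesink.phylo import read_newick, simulate_birth_death

CHERRY = "((A:1,B:1):1,C:2);"          # 3 tips, depth 2
CHAIN = "((B:0.5,(C:0.25,D:0.25):0.25):0.5,A:1);"  # nested, depth 1


@pytest.fixture
def cherry_tree():
    return read_newick(CHERRY)


@pytest.fixture(scope="session")
def tree48():
    return simulate_birth_death(48, 0.8, 0.2, seed=1)


@pytest.fixture(scope="session")
def tree16():
    return simulate_birth_death(16, 1.0, 0.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
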