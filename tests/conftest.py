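import numpy as np
import pytest

import phyloisolation as pi

# small fixed trees used throughout; hand-computable scores
T2 = "(A:1,B:1);"
T3 = "((A:1,B:1):1,C:2);"
S4 = "(A:1,B:1,C:1,D:1);"
CATERPILLAR = "(((A:1,B:1):1,C:2):1,D:3);"
BALANCED4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def t2():
    return pi.parse_newick(T2)


@pytest.fixture
def t3():
    return pi.parse_newick(T3)


@pytest.fixture
def s4():
    return pi.parse_newick(S4)


@pytest.fixture
def caterpillar():
    return pi.parse_newick(CATERPILLAR)


@pytest.fixture
def balanced4():
    return pi.parse_newick(BALANCED4)


def make_trees(n_trees, n_tips, death=0.25, seed=0, birth=0.5):
    """Seeded batch of simulated birth-death trees."""
    rng = np.random.default_rng(seed)
    cfg = pi.BDConfig(n_tips=n_tips, birth=birth, death=death)
    return [pi.simulate_bd_tree(cfg, rng=rng) for _ in range(n_trees)]
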