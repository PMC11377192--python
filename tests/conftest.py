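import numpy as np
import pandas as pd
import pytest

from macroevo_paths import synthgen, treekit


@pytest.fixture
def cherry():
    return treekit.read_newick("(A:1,B:1);")


@pytest.fixture
def caterpillar():
    return treekit.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    return treekit.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def medium_tree():
    """A ~40-tip pure-birth tree reused by likelihood and rate tests."""
    tree, _ = synthgen.simulate_bd_tree(0.25, 0.0, crown_age=12.0, seed=11)
    assert tree.n_tips >= 20
    return tree


@pytest.fixture(scope="session")
def random_trees():
    """A batch of small simulated trees for oracle sweeps."""
    out = []
    for seed in range(12):
        tree, _ = synthgen.simulate_bd_tree(
            0.3, 0.05, crown_age=8.0, f=1.0, seed=100 + seed)
        out.append(tree)
    return out
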