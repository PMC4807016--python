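import numpy as np
import pytest

from pglscan.pgls import EvolutionModel
from pglscan.phylo import parse_newick
from pglscan import synthetic as syn


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_tip_geom(three_tip_tree):
    return three_tip_tree.geometry(["A", "B", "C"])


@pytest.fixture
def tree50():
    return syn.simulate_tree(50, seed=2024)


@pytest.fixture
def geom50(tree50):
    return tree50.geometry()


@pytest.fixture
def bm_pair(geom50):
    """A pair of independent Brownian traits on the 50-tip tree."""
    y = syn.simulate_trait(geom50, EvolutionModel(kind="BM"), seed=11)
    x = syn.simulate_trait(geom50, EvolutionModel(kind="BM"), seed=12)
    return y, x


@pytest.fixture
def rng():
    return np.random.default_rng(123)
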