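import dendropy
import numpy as np
import pytest

from nestevo.mk import MkModel
from nestevo.simulate import simulate_discrete_trait, simulate_yule_tree
from nestevo.trees import TreeArrays


def tree_from_newick(nwk: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=nwk, schema="newick", rooting="default-rooted")


def random_tree(rng: np.random.Generator, n_tips: int) -> dendropy.Tree:
    """Random binary rooted tree with exponential branch lengths."""
    return simulate_yule_tree(n_tips, 1.0, rng.integers(2**31))


@pytest.fixture(scope="session")
def cherry():
    return tree_from_newick("(A:1.0,B:1.0);")


@pytest.fixture(scope="session")
def four_tip_tree():
    return tree_from_newick("((A:0.3,B:0.7):0.4,(C:0.2,D:0.9):0.1);")


@pytest.fixture(scope="session")
def yule50():
    return simulate_yule_tree(50, 1.0, 4242)


@pytest.fixture(scope="session")
def simulated_dataset_200():
    """200-tip tree with an equal-rates 4-state trait simulated at q=0.2."""
    tree = simulate_yule_tree(200, 1.0, 77)
    trait = simulate_discrete_trait(tree, MkModel(k=4, rates=0.2), 0, 78)
    return tree, {t: {v} for t, v in trait.items()}


@pytest.fixture(scope="session")
def arrays50(yule50):
    return TreeArrays.from_tree(yule50)
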