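import numpy as np
import pytest

from vectree.simgen import SimConfig, simulate_tree
from vectree.tree import RootedTree


def random_tree(seed: int, n_nodes: int, max_degree: int = 3) -> RootedTree:
    return simulate_tree(
        SimConfig(
            "uniform_random", seed=seed, max_nodes=n_nodes, max_degree=max_degree
        )
    )


def permute_children(tree: RootedTree, rng: np.random.Generator) -> RootedTree:
    """Same tree with every children list independently shuffled."""
    children = []
    for u in tree.nodes():
        kids = list(tree.children[u])
        rng.shuffle(kids)
        children.append(kids)
    return RootedTree(children)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
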