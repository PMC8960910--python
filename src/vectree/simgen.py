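"""Deterministic fixtures and seeded random tree generators.

Two kinds of trees come out of this module: the small hand-built pairs used
throughout the documentation and tests (:func:`fixture`), and stochastic
phylogeny-like trees from a minimal continuous-time branching emulator
(:func:`simulate_tree`).  The emulator draws Weibull-distributed waiting
times until speciation (shape 1 recovers the memoryless exponential case;
large shapes give near-synchronized, level-structured splits) and supports
two inheritance modes at a split: *symmetric*, where both daughter lineages
draw fresh waiting times, and *asymmetric*, where one daughter inherits the
mother's clock and therefore tends to split again quickly, skewing the tree
toward long unbalanced branches.  Extinction is disabled: every lineage
survives until the target taxa count is reached.

This is an emulation of general branching-process simulators used for
phylogenetic benchmarking, not a reimplementation of any particular one; it
reproduces the qualitative contrast between the families (balanced vs
unbalanced, synchronized vs memoryless), which is what the clustering
experiments need.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .tree import RootedTree

_BRANCHING = ("symmetric", "asymmetric", "hierarchical", "flat")
_SHAPES = ("star", "path", "uniform_random")

# study defaults for the branching families: (inheritance, Weibull shape,
# Weibull scale, taxa at stop)
_FAMILY_DEFAULTS = {
    "symmetric": ("symmetric", 3.0, 0.1, 10),
    "asymmetric": ("asymmetric", 3.0, 0.1, 10),
    "hierarchical": ("asymmetric", 4.0, 0.1, 15),
    "flat": ("asymmetric", 1.0, 0.1, 15),
}


@dataclass
class SimConfig:
    """Configuration of one generator run.

    ``family`` picks the generator: the four branching families above, or
    the exact shapes ``star`` (``max_nodes`` = root degree + 1), ``path``
    (``max_nodes`` = depth + 1) and ``uniform_random`` (uniform attachment
    respecting ``max_degree``).  Branching families stop at ``n_taxa``
    leaves; shape families use ``max_nodes``.  Exactly one stopping rule
    must be set, and a seed is mandatory.
    """

    family: str
    seed: int
    n_taxa: int | None = None
    max_nodes: int | None = None
    max_degree: int = 2
    shape: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _BRANCHING + _SHAPES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.max_degree < 2:
            raise ValueError("max_degree must be >= 2")
        if self.family in _BRANCHING:
            inherit, shape, scale, taxa = _FAMILY_DEFAULTS[self.family]
            if self.n_taxa is None:
                self.n_taxa = taxa
            if self.shape is None:
                self.shape = shape
            if self.scale is None:
                self.scale = scale
            if self.max_nodes is not None:
                raise ValueError("branching families stop on n_taxa only")
            if self.n_taxa < 1:
                raise ValueError("n_taxa must be >= 1")
        else:
            if self.max_nodes is None:
                raise ValueError(f"{self.family} requires max_nodes")
            if self.n_taxa is not None:
                raise ValueError(f"{self.family} stops on max_nodes only")
            if self.max_nodes < 1:
                raise ValueError("max_nodes must be >= 1")


# -- worked-example fixtures ------------------------------------------------


def tree_from_shape(shape) -> RootedTree:
    """Build a tree from a nested-sequence shape (a leaf is an empty list)."""
    children: list[list[int]] = [[]]

    def build(node: int, sub) -> None:
        for ch in sub:
            cid = len(children)
            children.append([])
            children[node].append(cid)
            build(cid, ch)

    build(0, shape)
    return RootedTree(children)


_L = ()  # leaf


def fixture(name: str) -> tuple[RootedTree, RootedTree]:
    """Hand-built tree pairs used in the worked examples.

    ``example1``: roots of degree 2 and 3; the distance vector starts
    (1, 2, 6).  ``example2``: roots of degree 4 with look-ahead weights
    (2,3,4,5) vs (3,4,5,6); the distance vector starts (0, 4, 3).
    """
    if name == "example1":
        t1 = tree_from_shape(
            (
                ((_L, _L, _L), (_L, _L, _L)),  # A: weights (3, 3)
                ((_L, _L), (_L, _L), (_L, _L, _L)),  # B: weights (2, 2, 3)
            )
        )
        t2 = tree_from_shape(
            (
                ((_L, _L), (_L, _L), (_L, _L, _L)),  # A': weights (2, 2, 3)
                ((_L, _L), (_L, _L, _L)),  # B': weights (2, 3)
                ((_L, _L, _L), (_L, _L, _L, _L)),  # C': weights (3, 4)
            )
        )
        return t1, t2
    if name == "example2":
        t1 = tree_from_shape(
            (
                ((_L, _L, _L), (_L, _L)),  # A: weights (3, 2)
                (_L, _L, _L),  # B
                (_L, _L, _L, _L),  # C
                (_L, _L, _L, _L, _L),  # D
            )
        )
        t2 = tree_from_shape(
            (
                ((_L, _L, _L), (_L, _L), (_L, _L, _L)),  # A': weights (3, 2, 3)
                (_L, _L, _L, _L),  # B'
                (_L, _L, _L, _L, _L),  # C'
                (_L, _L, _L, _L, _L, _L),  # D'
            )
        )
        return t1, t2
    raise ValueError(f"unknown fixture {name!r}")


# -- exact shapes -----------------------------------------------------------


def star(n_leaves: int) -> RootedTree:
    """Root with ``n_leaves`` leaf children (depth 1)."""
    return RootedTree([[i for i in range(1, n_leaves + 1)]] + [[]] * n_leaves)


def path(depth: int) -> RootedTree:
    """A chain of ``depth`` edges (all out-degrees 1, one leaf)."""
    return RootedTree([[i + 1] for i in range(depth)] + [[]])


def _uniform_random(rng: np.random.Generator, n_nodes: int, max_degree: int) -> RootedTree:
    children: list[list[int]] = [[]]
    open_slots = [0]
    while len(children) < n_nodes:
        parent = open_slots[rng.integers(len(open_slots))]
        cid = len(children)
        children.append([])
        children[parent].append(cid)
        open_slots.append(cid)
        if len(children[parent]) >= max_degree:
            open_slots.remove(parent)
    return RootedTree(children)


# -- branching emulator -----------------------------------------------------


def _branching(
    rng: np.random.Generator,
    n_taxa: int,
    shape: float,
    scale: float,
    symmetric: bool,
) -> RootedTree:
    def wait() -> float:
        return scale * float(rng.weibull(shape))

    children: list[list[int]] = [[]]
    # heap of (next_split_time, node_id, birth_time); node id breaks ties
    active: list[tuple[float, int, float]] = [(wait(), 0, 0.0)]
    while len(active) < n_taxa:
        t, u, birth = heapq.heappop(active)
        a, b = len(children), len(children) + 1
        children.append([])
        children.append([])
        children[u] = [a, b]
        heapq.heappush(active, (t + wait(), a, t))
        if symmetric:
            heapq.heappush(active, (t + wait(), b, t))
        else:
            # daughter b inherits the mother's clock: her waiting time runs
            # from the mother's birth, redrawn conditioned on exceeding the
            # age already elapsed (bounded retries; immediate split in the
            # limit).  Old lineages therefore re-split fast, skewing depth.
            nxt = birth + wait()
            for _ in range(10):
                if nxt > t:
                    break
                nxt = birth + wait()
            heapq.heappush(active, (max(t, nxt), b, birth))
    return RootedTree(children)


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None) -> RootedTree:
    """One seeded, reproducible tree drawn according to ``config``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.family == "star":
        return star(config.max_nodes - 1)
    if config.family == "path":
        return path(config.max_nodes - 1)
    if config.family == "uniform_random":
        return _uniform_random(rng, config.max_nodes, config.max_degree)
    inherit = _FAMILY_DEFAULTS[config.family][0]
    return _branching(
        rng, config.n_taxa, config.shape, config.scale, inherit == "symmetric"
    )


def simulate_family(config: SimConfig, m: int) -> list[RootedTree]:
    """``m`` independent draws; per-tree streams derived from the seed."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return [
        simulate_tree(config, rng=np.random.default_rng([config.seed, i]))
        for i in range(m)
    ]


# -- exhaustive small-tree enumeration --------------------------------------


def enumerate_rooted_trees(n: int) -> list[RootedTree]:
    """All unlabeled rooted trees with exactly ``n`` nodes, one per
    isomorphism class (1, 1, 2, 4, 9, 20, ... trees for n = 1, 2, 3, ...)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    shape_memo: dict[int, list[tuple]] = {}
    forest_memo: dict[int, set[tuple]] = {}

    def shapes(k: int) -> list[tuple]:
        if k not in shape_memo:
            shape_memo[k] = [f for f in sorted(forests(k - 1))]
        return shape_memo[k]

    def forests(k: int) -> set[tuple]:
        # multisets (sorted tuples) of shapes with k total nodes
        if k in forest_memo:
            return forest_memo[k]
        if k == 0:
            out = {()}
        else:
            out = set()
            for s in range(1, k + 1):
                for t in shapes(s):
                    for rest in forests(k - s):
                        out.add(tuple(sorted(rest + (t,))))
        forest_memo[k] = out
        return out

    return [tree_from_shape(s) for s in shapes(n)]
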