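"""Rooted-tree data model and Newick ingestion.

The distance algorithm in :mod:`vectree.core` works on bare topology: leaf
labels and branch lengths are read but discarded, and sibling order carries no
meaning (it is kept only so iteration is deterministic).  Depth is counted in
edges from the root (root = level 0).
"""

from __future__ import annotations

from functools import cached_property
from typing import Iterable, Sequence

import dendropy


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class RootedTree:
    """An unlabeled rooted tree.

    Nodes are integers ``0 .. n-1`` in breadth-first order from the root
    (node 0).  The structure is immutable after construction.

    Parameters
    ----------
    children :
        ``children[u]`` is the ordered list of children of node ``u``.
        Node 0 must be the root and every node must appear as a child of
        exactly one other node (except the root).
    """

    __slots__ = ("children", "parent", "depth", "_code_cache", "__dict__")

    def __init__(self, children: Sequence[Sequence[int]]):
        n = len(children)
        self.children: tuple[tuple[int, ...], ...] = tuple(
            tuple(c) for c in children
        )
        parent: list[int | None] = [None] * n
        seen = [False] * n
        seen[0] = True
        depth = [0] * n
        order = [0]
        for u in order:
            for c in self.children[u]:
                if not (0 <= c < n) or seen[c]:
                    raise ValueError(f"node {c} is not a valid child of {u}")
                seen[c] = True
                parent[c] = u
                depth[c] = depth[u] + 1
                order.append(c)
        if not all(seen):
            raise ValueError("children lists do not describe a connected tree")
        self.parent: tuple[int | None, ...] = tuple(parent)
        self.depth: tuple[int, ...] = tuple(depth)
        self._code_cache: dict[int, str] = {}

    # -- basic queries -----------------------------------------------------

    @property
    def root(self) -> int:
        return 0

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def __len__(self) -> int:
        return len(self.children)

    def out_degree(self, u: int) -> int:
        return len(self.children[u])

    def is_leaf(self, u: int) -> bool:
        return not self.children[u]

    @cached_property
    def max_depth(self) -> int:
        return max(self.depth)

    @cached_property
    def n_leaves(self) -> int:
        return sum(1 for c in self.children if not c)

    def nodes(self) -> range:
        return range(self.n_nodes)

    def subtree_nodes(self, u: int) -> list[int]:
        """Descendants of ``u`` including ``u``, in BFS order."""
        out = [u]
        for v in out:
            out.extend(self.children[v])
        return out

    def subtree_depth(self, u: int) -> int:
        """Height of the subtree rooted at ``u`` (0 for a leaf)."""
        return max(self.depth[v] for v in self.subtree_nodes(u)) - self.depth[u]

    # -- look-ahead weights and level bookkeeping --------------------------

    def weight_vector(self, u: int) -> tuple[int, ...]:
        """One-step look-ahead weights: each child's out-degree.

        A node with children ``c1..ck`` gets ``(deg(c1), ..., deg(ck))``;
        the edge from ``u`` to each child is not counted.  Leaves get ``()``.
        """
        return tuple(len(self.children[c]) for c in self.children[u])

    def level_profile(self, u: int) -> tuple[int, ...]:
        """Number of descendants of ``u`` at each relative depth.

        ``profile[0] == 1`` (the node itself); the sum is the subtree size.
        """
        counts: list[int] = []
        frontier = [u]
        while frontier:
            counts.append(len(frontier))
            frontier = [c for v in frontier for c in self.children[v]]
        return tuple(counts)

    def canonical_code(self, u: int) -> str:
        """AHU canonical encoding of the subtree at ``u``.

        Two subtrees get equal codes iff they are isomorphic as unordered
        rooted trees; sibling order never affects the code.
        """
        cache = self._code_cache
        # iterative post-order so deep path trees do not hit recursion limits
        stack = [(u, False)]
        while stack:
            v, ready = stack.pop()
            if v in cache:
                continue
            if ready or self.is_leaf(v):
                cache[v] = "(" + "".join(
                    sorted(cache[c] for c in self.children[v])
                ) + ")"
            else:
                stack.append((v, True))
                stack.extend((c, False) for c in self.children[v])
        return cache[u]

    # -- construction and rerooting ----------------------------------------

    @classmethod
    def from_adjacency(
        cls, adjacency: dict[int, Iterable[int]], root: int
    ) -> "RootedTree":
        """Build from an undirected adjacency map by orienting away from root."""
        return cls._from_adjacency_with_map(adjacency, root)[0]

    @classmethod
    def _from_adjacency_with_map(
        cls, adjacency: dict[int, Iterable[int]], root: int
    ) -> tuple["RootedTree", dict[int, int]]:
        children: dict[int, list[int]] = {}
        relabel = {root: 0}
        order = [root]
        prev: dict[int, int | None] = {root: None}
        for u in order:
            children[relabel[u]] = []
            for v in adjacency.get(u, ()):
                if v == prev[u]:
                    continue
                prev[v] = u
                relabel[v] = len(relabel)
                children[relabel[u]].append(relabel[v])
                order.append(v)
        return cls([children[i] for i in range(len(order))]), relabel

    def _adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {u: [] for u in self.nodes()}
        for u in self.nodes():
            for c in self.children[u]:
                adj[u].append(c)
                adj[c].append(u)
        return adj

    def reroot(self, node: int) -> "RootedTree":
        """Return the same undirected topology re-oriented from ``node``."""
        return self.reroot_with_map(node)[0]

    def reroot_with_map(self, node: int) -> tuple["RootedTree", dict[int, int]]:
        """Reroot and also return the old-id -> new-id relabeling."""
        if not (0 <= node < self.n_nodes):
            raise ValueError(f"unknown node id {node}")
        if node == self.root:
            return self, {u: u for u in self.nodes()}
        return RootedTree._from_adjacency_with_map(self._adjacency(), node)


# -- Newick I/O ------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    seed = dtree.seed_node
    relabel = {id(seed): 0}
    children: list[list[int]] = [[]]
    order = [seed]
    for node in order:
        for ch in node.child_nodes():
            relabel[id(ch)] = len(children)
            children[relabel[id(node)]].append(len(children))
            children.append([])
            order.append(ch)
    return RootedTree(children)


def parse_newick(text: str) -> RootedTree:
    """Parse one Newick string into a :class:`RootedTree`.

    Labels, branch lengths and bracketed comments are accepted and discarded;
    multifurcations are preserved; the Newick root becomes the tree root.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick_file(path) -> list[RootedTree]:
    """Read all trees from a Newick file (one tree per line/statement)."""
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick in {path}: {exc}") from exc
    if not trees:
        raise NewickParseError(f"no trees found in {path}")
    return [_from_dendropy(t) for t in trees]


def write_newick(tree: RootedTree) -> str:
    """Serialize the bare topology as Newick (all leaves labeled ``x``)."""

    def render(u: int) -> str:
        if tree.is_leaf(u):
            return "x"
        return "(" + ",".join(render(c) for c in tree.children[u]) + ")"

    return render(tree.root) + ";"


# -- center finding --------------------------------------------------------


def find_center(tree: RootedTree) -> int:
    """Jordan center of the tree by iterative leaf removal.

    A tree has one or two center nodes (nodes of minimal eccentricity).  With
    two, the returned one is chosen deterministically: the center whose side
    of the center-center edge holds more nodes; ties broken by smaller
    canonical code of the tree rerooted at the candidate, then by node id.
    """
    n = tree.n_nodes
    if n == 1:
        return tree.root
    adj = {u: set(vs) for u, vs in tree._adjacency().items()}
    remaining = set(tree.nodes())
    layer = [u for u in remaining if len(adj[u]) == 1]
    while len(remaining) > 2:
        nxt = []
        for u in layer:
            remaining.discard(u)
            for v in adj[u]:
                adj[v].discard(u)
                if len(adj[v]) == 1 and v in remaining:
                    nxt.append(v)
            adj[u].clear()
        layer = nxt
    centers = sorted(remaining)
    if len(centers) == 1:
        return centers[0]
    a, b = centers
    side = {a: _side_size(tree, a, b), b: _side_size(tree, b, a)}
    key = lambda c: (-side[c], tree.reroot(c).canonical_code(0), c)
    return min(centers, key=key)


def _side_size(tree: RootedTree, keep: int, drop: int) -> int:
    """Nodes on ``keep``'s side when the keep-drop edge is removed."""
    adj = tree._adjacency()
    seen = {keep, drop}
    stack = [keep]
    count = 0
    while stack:
        u = stack.pop()
        count += 1
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return count
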