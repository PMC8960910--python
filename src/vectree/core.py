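"""Vectorial tree distance (VTD) between unlabeled rooted trees.

The distance between two rooted trees is an integer vector ``D`` indexed by
level (distance from the root).  ``D[0]`` is the difference of the root
out-degrees.  Each node carries a one-step look-ahead weight vector (its
children's out-degrees); ``D[1]`` is the minimal L1 cost of matching the two
root weight vectors after zero-padding.  Deeper entries come from recursively
aligning the subtrees paired by a minimal matching: among all minimal
matchings, the alignment is chosen to make the resulting vector
lexicographically smallest, earlier (root-proximal) levels taking precedence.
A branch matched against padding becomes a *ghost*: its whole subtree keeps
contributing its per-level descendant counts to the deeper entries.

All arithmetic in this module is exact integer arithmetic; the only
floating-point step is :func:`scalarize`.
"""

from __future__ import annotations

import itertools
import math
import sys
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tree import RootedTree

_GHOST = "*"  # group code for zero-padding slots; real AHU codes start with "("


class EnumerationCapError(RuntimeError):
    """Too many co-minimal alignments; raise the relevant cap to proceed."""


# -- elementary vector operations -----------------------------------------


def pad_pair(
    x: Sequence[int], y: Sequence[int]
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Zero-pad the shorter of two weight vectors to the common length."""
    k = max(len(x), len(y))
    return (
        tuple(x) + (0,) * (k - len(x)),
        tuple(y) + (0,) * (k - len(y)),
    )


def l1(x: Sequence[int], y: Sequence[int]) -> int:
    """L1 difference of two equal-length weight vectors."""
    if len(x) != len(y):
        raise ValueError(
            f"length mismatch ({len(x)} vs {len(y)}); call pad_pair first"
        )
    return sum(abs(a - b) for a, b in zip(x, y))


def _lex_less(a: Sequence[int], b: Sequence[int]) -> bool:
    """Lexicographic comparison with implicit trailing zeros."""
    n = max(len(a), len(b))
    for i in range(n):
        ai = a[i] if i < len(a) else 0
        bi = b[i] if i < len(b) else 0
        if ai != bi:
            return ai < bi
    return False


def _add_shifted(acc: list[int], vec: Sequence[int], mult: int) -> None:
    """acc[r+1] += mult * vec[r] — children live one level below the parent."""
    need = len(vec) + 1
    if len(acc) < need:
        acc.extend([0] * (need - len(acc)))
    for r, v in enumerate(vec):
        acc[r + 1] += mult * v


# -- matching enumeration ---------------------------------------------------

# Positions whose subtrees are isomorphic (equal canonical code) are
# interchangeable in a matching: swapping them changes neither the cost nor
# any deeper entry of the distance vector.  Padded child lists are therefore
# grouped by code and a matching is represented by a contingency matrix
# n[i][j] = number of group-i positions paired with group-j positions.  The
# number of permutations sigma in Sym(k) inducing a given matrix is
# (prod_i ci!) (prod_j dj!) / prod_ij n_ij! — this recovers the exhaustive,
# non-collapsed counts without enumerating Sym(k).


@dataclass(frozen=True)
class _Group:
    code: str
    weight: int
    count: int
    rep: int | None  # representative node id (None for padding or raw vectors)


def _group_items(
    weights: Sequence[int],
    codes: Sequence[str] | None,
    reps: Sequence[int] | None,
    n_pad: int,
) -> list[_Group]:
    if codes is None:
        codes = [f"w{w}" for w in weights]
    grouped: dict[str, _Group] = {}
    order: list[str] = []
    for i, (w, c) in enumerate(zip(weights, codes)):
        if c in grouped:
            g = grouped[c]
            grouped[c] = _Group(c, w, g.count + 1, g.rep)
        else:
            grouped[c] = _Group(c, w, 1, reps[i] if reps is not None else None)
            order.append(c)
    out = [grouped[c] for c in order]
    if n_pad:
        out.append(_Group(_GHOST, 0, n_pad, None))
    return out


def _matrix_multiplicity(
    gx: list[_Group], gy: list[_Group], mat: tuple[tuple[int, ...], ...]
) -> int:
    num = 1
    for g in gx:
        num *= math.factorial(g.count)
    for g in gy:
        num *= math.factorial(g.count)
    den = 1
    for row in mat:
        for n in row:
            den *= math.factorial(n)
    return num // den


def _enumerate_matrices(
    gx: list[_Group],
    gy: list[_Group],
    target: int | None,
    cap: int,
) -> Iterator[tuple[int, tuple[tuple[int, ...], ...]]]:
    """Yield (cost, matrix) for group matchings.

    With ``target`` set, only matrices of exactly that cost are yielded
    (search is pruned against it); with ``target=None`` every matching is
    yielded.  Raises :class:`EnumerationCapError` past ``cap`` results.
    """
    p, q = len(gx), len(gy)
    cost = [[abs(gx[i].weight - gy[j].weight) for j in range(q)] for i in range(p)]
    rem = [gy[j].count for j in range(q)]
    rows: list[tuple[int, ...]] = []
    yielded = 0

    def lower_bound(i: int) -> int:
        lb = 0
        for i2 in range(i, p):
            avail = [cost[i2][j] for j in range(q) if rem[j] > 0]
            if avail:
                lb += gx[i2].count * min(avail)
        return lb

    def distributions(i: int, prefix_cost: int) -> Iterator[tuple[int, int]]:
        # enumerate row i distributions recursively via a nested generator
        row = [0] * q

        def fill(j: int, left: int, c: int) -> Iterator[int]:
            if target is not None and c > target:
                return
            if j == q:
                if left == 0:
                    yield c
                return
            hi = min(left, rem[j])
            lo = left - sum(rem[j2] for j2 in range(j + 1, q))
            for n in range(max(0, lo), hi + 1):
                row[j] = n
                rem[j] -= n
                yield from fill(j + 1, left - n, c + n * cost[i][j])
                rem[j] += n
                row[j] = 0

        for c in fill(0, gx[i].count, prefix_cost):
            yield c, tuple(row)

    def rec(i: int, acc_cost: int) -> Iterator[tuple[int, tuple[tuple[int, ...], ...]]]:
        nonlocal yielded
        if target is not None and acc_cost + lower_bound(i) > target:
            return
        if i == p:
            if target is None or acc_cost == target:
                yielded += 1
                if yielded > cap:
                    raise EnumerationCapError(
                        f"more than {cap} co-minimal matchings; raise the "
                        "matching_cap / frontier_cap parameter"
                    )
                yield acc_cost, tuple(rows)
            return
        for c, row in distributions(i, acc_cost):
            rows.append(row)
            yield from rec(i + 1, c)
            rows.pop()

    # rebuild row tuples inside rec: distributions mutates `row`, so snapshot
    yield from rec(0, 0)


def _min_matching_value(gx: list[_Group], gy: list[_Group]) -> int:
    """Optimal matching cost via the assignment solver on expanded groups."""
    xw = [g.weight for g in gx for _ in range(g.count)]
    yw = [g.weight for g in gy for _ in range(g.count)]
    c = np.abs(np.subtract.outer(np.array(xw), np.array(yw)))
    rows, cols = linear_sum_assignment(c)
    return int(c[rows, cols].sum())


@dataclass(frozen=True)
class Pairing:
    """One (collapsed) matching: pairs of padded positions with multiplicities.

    ``pairs`` holds ``(x_rep, y_rep, count)`` triples where the reps are node
    ids when the matching was built from trees, else ``None``; a ``None`` rep
    on one side marks ghost (padding) slots.  ``multiplicity`` is the number
    of permutations of padded positions inducing this matching.
    """

    pairs: tuple[tuple[int | None, int | None, int], ...]
    cost: int
    multiplicity: int


@dataclass
class MatchingSet:
    """All minimal matchings of two zero-padded weight vectors."""

    value: int
    pairings: list[Pairing]
    n_candidates: int  # total permutations of padded positions, k!
    n_minimal: int  # permutations achieving `value` (exhaustive count)

    @property
    def n_minimal_collapsed(self) -> int:
        return len(self.pairings)


def _matching_set(
    gx: list[_Group], gy: list[_Group], cap: int
) -> MatchingSet:
    value = _min_matching_value(gx, gy)
    pairings = []
    for cost, mat in _enumerate_matrices(gx, gy, value, cap):
        pairs = tuple(
            (gx[i].rep, gy[j].rep, n)
            for i, row in enumerate(mat)
            for j, n in enumerate(row)
            if n
        )
        pairings.append(Pairing(pairs, cost, _matrix_multiplicity(gx, gy, mat)))
    k = sum(g.count for g in gx)
    return MatchingSet(
        value=value,
        pairings=pairings,
        n_candidates=math.factorial(k),
        n_minimal=sum(p.multiplicity for p in pairings),
    )


def minimal_matchings(
    x: Sequence[int],
    y: Sequence[int],
    *,
    x_codes: Sequence[str] | None = None,
    y_codes: Sequence[str] | None = None,
    cap: int = 100_000,
) -> MatchingSet:
    """Minimal-L1 matchings of two weight vectors after zero-padding.

    Without codes, positions are grouped by weight value alone; the matching
    value and the exhaustive permutation counts do not depend on the grouping.
    ``x_codes``/``y_codes`` (canonical subtree codes) refine the collapsing so
    that only genuinely interchangeable positions are merged.
    """
    xp, yp = pad_pair(x, y)
    gx = _group_items(x, x_codes, None, len(xp) - len(x))
    gy = _group_items(y, y_codes, None, len(yp) - len(y))
    return _matching_set(gx, gy, cap)


def enumerate_permutation_matchings(
    x: Sequence[int], y: Sequence[int], cap_len: int = 9
) -> tuple[int, list[tuple[int, ...]], int]:
    """Literal enumeration of every permutation of padded positions.

    Oracle-grade reference for :func:`minimal_matchings`: returns
    ``(value, minimizing_permutations, n_candidates)`` where each permutation
    maps padded-x position ``i`` to padded-y position ``perm[i]``.
    """
    xp, yp = pad_pair(x, y)
    k = len(xp)
    if k > cap_len:
        raise EnumerationCapError(
            f"padded length {k} exceeds cap_len={cap_len}"
        )
    best: int | None = None
    winners: list[tuple[int, ...]] = []
    total = 0
    for perm in itertools.permutations(range(k)):
        total += 1
        c = sum(abs(xp[i] - yp[perm[i]]) for i in range(k))
        if best is None or c < best:
            best, winners = c, [perm]
        elif c == best:
            winners.append(perm)
    return int(best), winners, total


# -- tree-vs-empty distance -------------------------------------------------


def empty_distance(tree: RootedTree, node: int) -> tuple[int, ...]:
    """Distance vector between the subtree at ``node`` and the empty tree.

    Entry ``r`` is the number of descendants of ``node`` at relative depth
    ``r + 1`` (entry 0 is the out-degree): the level profile shifted by one.
    Trailing zeros are dropped; a leaf gives ``()``.
    """
    return tree.level_profile(node)[1:]


# -- the recursive distance -------------------------------------------------


def _child_groups(
    tree: RootedTree, u: int, n_pad: int
) -> list[_Group]:
    kids = tree.children[u]
    return _group_items(
        [tree.out_degree(c) for c in kids],
        [tree.canonical_code(c) for c in kids],
        kids,
        n_pad,
    )


def vtd(
    tree1: RootedTree,
    tree2: RootedTree,
    z: int | str = "auto",
    *,
    matching_cap: int = 100_000,
) -> tuple[int, ...]:
    """Vectorial tree distance between two rooted trees.

    Returns the integer vector ``D`` with ``z + 1`` entries (levels
    ``0..z``); ``z="auto"`` uses the larger of the two tree depths.  The
    result is symmetric in its arguments and invariant under sibling
    reordering.  Raises :class:`EnumerationCapError` if a node pair has more
    than ``matching_cap`` co-minimal matchings.
    """
    if z == "auto":
        zz = max(tree1.max_depth, tree2.max_depth)
    else:
        zz = int(z)
        if zz < 0:
            raise ValueError("z must be >= 0 or 'auto'")

    memo: dict[tuple[str, str], tuple[int, ...]] = {}

    def dvec(u: int, v: int) -> tuple[int, ...]:
        key = (tree1.canonical_code(u), tree2.canonical_code(v))
        hit = memo.get(key)
        if hit is not None:
            return hit
        xs, ys = tree1.children[u], tree2.children[v]
        d0 = abs(len(xs) - len(ys))
        if not xs and not ys:
            memo[key] = (0,)
            return (0,)
        gx = _child_groups(tree1, u, max(0, len(ys) - len(xs)))
        gy = _child_groups(tree2, v, max(0, len(xs) - len(ys)))
        ms = _matching_set(gx, gy, matching_cap)
        best: list[int] | None = None
        for pairing in ms.pairings:
            acc = [d0]
            for xr, yr, n in pairing.pairs:
                if xr is None and yr is None:
                    continue
                if xr is None:
                    pv: Sequence[int] = empty_distance(tree2, yr)
                elif yr is None:
                    pv = empty_distance(tree1, xr)
                else:
                    pv = dvec(xr, yr)
                _add_shifted(acc, pv, n)
            if best is None or _lex_less(acc, best):
                best = acc
        assert best is not None and (len(best) < 2 or best[1] == ms.value)
        out = tuple(best)
        memo[key] = out
        return out

    depth = max(tree1.max_depth, tree2.max_depth)
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * depth + 1000))
    try:
        full = dvec(tree1.root, tree2.root)
    finally:
        sys.setrecursionlimit(old)
    return tuple(full[r] if r < len(full) else 0 for r in range(zz + 1))


# -- brute-force oracle -----------------------------------------------------


def vtd_bruteforce(
    tree1: RootedTree,
    tree2: RootedTree,
    z: int | str = "auto",
    *,
    max_nodes: int = 32,
) -> tuple[int, ...]:
    """Exhaustive reference implementation of the distance.

    Enumerates every level- and descendancy-preserving alignment of the two
    trees (all child bijections at every matched pair, with padding), builds
    each alignment's full per-level difference vector, and returns the
    lexicographic minimum.  No matching solver, no minimality pruning, no
    collapsing — combinatorial, guarded to small trees.
    """
    if tree1.n_nodes > max_nodes or tree2.n_nodes > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes per tree")

    def ghost_vec(tree: RootedTree, u: int) -> tuple[int, ...]:
        return empty_distance(tree, u)

    def allvecs(u: int, v: int) -> list[tuple[int, ...]]:
        xs = list(tree1.children[u])
        ys = list(tree2.children[v])
        k = max(len(xs), len(ys))
        xs += [None] * (k - len(xs))
        ys += [None] * (k - len(ys))
        d0 = abs(tree1.out_degree(u) - tree2.out_degree(v))
        if k == 0:
            return [(0,)]
        results: set[tuple[int, ...]] = set()
        for perm in itertools.permutations(range(k)):
            options: list[list[tuple[int, ...]]] = []
            for i in range(k):
                xc, yc = xs[i], ys[perm[i]]
                if xc is None and yc is None:
                    options.append([()])
                elif xc is None:
                    options.append([ghost_vec(tree2, yc)])
                elif yc is None:
                    options.append([ghost_vec(tree1, xc)])
                else:
                    options.append(allvecs(xc, yc))
            for combo in itertools.product(*options):
                acc = [d0]
                for pv in combo:
                    _add_shifted(acc, pv, 1)
                results.add(tuple(acc))
        return sorted(results)

    cands = allvecs(tree1.root, tree2.root)
    best = cands[0]
    for c in cands[1:]:
        if _lex_less(c, best):
            best = c
    if z == "auto":
        zz = max(tree1.max_depth, tree2.max_depth)
    else:
        zz = int(z)
    return tuple(best[r] if r < len(best) else 0 for r in range(zz + 1))


# -- alignment trace --------------------------------------------------------


@dataclass
class TraceNode:
    """One candidate alignment at one level of the alignment-possibility tree."""

    level: int
    parent: int | None  # index into the previous level's candidate list
    pairs: tuple[tuple[int | None, int | None, int], ...]  # active at next level
    level_value: int  # summed L1 differences at this level (ghosts included)
    cumulative: tuple[int, ...]  # distance entries 0..level along this path
    multiplicity: int  # permutations of padded positions giving this candidate
    minimal: bool = False


@dataclass
class AlignmentTrace:
    """Level-by-level record of the alignment search.

    ``levels[r]`` lists the candidate alignments considered at level ``r``;
    only minimal candidates are extended to level ``r + 1``.  The
    lexicographically best complete path reproduces :func:`vtd`.
    """

    levels: list[list[TraceNode]]
    distance: tuple[int, ...]

    def n_candidates(self, level: int, exhaustive: bool = False) -> int:
        nodes = self.levels[level]
        return sum(n.multiplicity for n in nodes) if exhaustive else len(nodes)

    def n_minimal(self, level: int, exhaustive: bool = False) -> int:
        nodes = [n for n in self.levels[level] if n.minimal]
        return sum(n.multiplicity for n in nodes) if exhaustive else len(nodes)

    def subalignments_of(self, level: int, parent_index: int,
                         exhaustive: bool = False) -> int:
        """How many level-``level`` candidates extend the given parent."""
        nodes = [n for n in self.levels[level] if n.parent == parent_index]
        return sum(n.multiplicity for n in nodes) if exhaustive else len(nodes)


def _pair_options(
    tree1: RootedTree,
    tree2: RootedTree,
    xr: int | None,
    yr: int | None,
    enumerate_all: bool,
    cap: int,
) -> list[tuple[int, tuple, int]]:
    """Matching options for one active pair: (cost, child_pairs, multiplicity).

    Ghost pairs have a single forced option: every child becomes a ghost and
    the cost is the number of grandchildren (the padded L1 against nothing).
    """
    if xr is None:
        assert yr is not None
        kids = tree2.children[yr]
        cost = sum(tree2.out_degree(c) for c in kids)
        return [(cost, tuple((None, c, 1) for c in kids), 1)]
    if yr is None:
        kids = tree1.children[xr]
        cost = sum(tree1.out_degree(c) for c in kids)
        return [(cost, tuple((c, None, 1) for c in kids), 1)]
    xs, ys = tree1.children[xr], tree2.children[yr]
    if not xs and not ys:
        return [(0, (), 1)]
    gx = _child_groups(tree1, xr, max(0, len(ys) - len(xs)))
    gy = _child_groups(tree2, yr, max(0, len(xs) - len(ys)))
    if enumerate_all:
        opts = []
        for cost, mat in _enumerate_matrices(gx, gy, None, cap):
            pairs = tuple(
                (gx[i].rep, gy[j].rep, n)
                for i, row in enumerate(mat)
                for j, n in enumerate(row)
                if n and not (gx[i].rep is None and gy[j].rep is None)
            )
            opts.append((cost, pairs, _matrix_multiplicity(gx, gy, mat)))
        return opts
    ms = _matching_set(gx, gy, cap)
    return [(p.cost, tuple(t for t in p.pairs if not (t[0] is None and t[1] is None)),
             p.multiplicity) for p in ms.pairings]


def alignment_trace(
    tree1: RootedTree,
    tree2: RootedTree,
    z: int | str = "auto",
    *,
    exhaustive: bool = False,
    frontier_cap: int = 100_000,
) -> AlignmentTrace:
    """Breadth-first record of all minimal alignments, level by level.

    With ``exhaustive=True`` the first expanded level lists *every* candidate
    matching (not only the minimal ones), mirroring a full matching table,
    and multiplicities count raw permutations rather than collapsed
    matchings.  Deeper levels always extend only minimal candidates.
    """
    zz = max(tree1.max_depth, tree2.max_depth) if z == "auto" else int(z)
    d0 = abs(tree1.out_degree(tree1.root) - tree2.out_degree(tree2.root))
    root = TraceNode(
        level=0,
        parent=None,
        pairs=(((tree1.root, tree2.root, 1)),),
        level_value=d0,
        cumulative=(d0,),
        multiplicity=1,
        minimal=True,
    )
    levels: list[list[TraceNode]] = [[root]]
    for lvl in range(1, zz + 1):
        frontier = [
            (i, n) for i, n in enumerate(levels[-1]) if n.minimal
        ]
        out: list[TraceNode] = []
        # only the first expansion shows non-minimal candidates in
        # exhaustive mode (the full matching table of the root pair)
        show_all = exhaustive and lvl == 1
        for parent_index, node in frontier:
            per_pair: list[list[tuple[int, tuple, int]]] = []
            for xr, yr, n in node.pairs:
                opts = _pair_options(tree1, tree2, xr, yr, show_all, frontier_cap)
                # a pair with count n: choose a multiset of n options
                combos: list[tuple[int, tuple, int]] = []
                for chosen in itertools.combinations_with_replacement(
                    range(len(opts)), n
                ):
                    cost = 0
                    pairs: tuple = ()
                    mult = math.factorial(n)
                    seen: dict[int, int] = {}
                    for oi in chosen:
                        c, p, m = opts[oi]
                        cost += c
                        pairs += p
                        mult *= m
                        seen[oi] = seen.get(oi, 0) + 1
                    for cnt in seen.values():
                        mult //= math.factorial(cnt)
                    combos.append((cost, pairs, mult))
                per_pair.append(combos)
            for combo in itertools.product(*per_pair):
                value = sum(c for c, _, _ in combo)
                pairs = tuple(p for _, ps, _ in combo for p in ps)
                mult = node.multiplicity
                for _, _, m in combo:
                    mult *= m
                out.append(
                    TraceNode(
                        level=lvl,
                        parent=parent_index,
                        pairs=pairs,
                        level_value=value,
                        cumulative=node.cumulative + (value,),
                        multiplicity=mult,
                    )
                )
                if len(out) > frontier_cap:
                    raise EnumerationCapError(
                        f"alignment frontier exceeded frontier_cap={frontier_cap}"
                    )
        if not out:
            break
        lo = min(n.level_value for n in out)
        for n in out:
            n.minimal = n.level_value == lo
        levels.append(out)
    # best complete path: cumulative of any minimal node at the last level
    last_min = [n for n in levels[-1] if n.minimal]
    best = last_min[0].cumulative
    for n in last_min[1:]:
        if _lex_less(n.cumulative, best):
            best = n.cumulative
    distance = tuple(best[r] if r < len(best) else 0 for r in range(zz + 1))
    return AlignmentTrace(levels=levels, distance=distance)


# -- scalarization ----------------------------------------------------------


def scalarize(
    d: Sequence[int],
    mode: str = "rms",
    lo: int | None = None,
    hi: int | None = None,
) -> float:
    """Collapse a distance vector to a scalar.

    ``rms``: root mean square over all entries of ``d``.  ``level_sum``: sum
    of entries ``lo..hi`` inclusive (levels beyond the vector count as 0).
    """
    if len(d) == 0:
        raise ValueError("empty distance vector")
    if mode == "rms":
        return float(math.sqrt(sum(v * v for v in d) / len(d)))
    if mode == "level_sum":
        if lo is None or hi is None:
            raise ValueError("level_sum requires lo and hi")
        if lo > hi:
            raise ValueError("need lo <= hi")
        return float(sum(d[r] for r in range(lo, hi + 1) if r < len(d)))
    raise ValueError(f"unknown scalarization mode {mode!r}")
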