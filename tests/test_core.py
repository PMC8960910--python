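"""Distance core: matchings, recursion, oracle agreement, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vectree.core import (
    EnumerationCapError,
    alignment_trace,
    empty_distance,
    enumerate_permutation_matchings,
    l1,
    minimal_matchings,
    pad_pair,
    scalarize,
    vtd,
    vtd_bruteforce,
)
from vectree.simgen import enumerate_rooted_trees, fixture, star, path as path_tree
from vectree.tree import parse_newick

from conftest import permute_children, random_tree

EX1 = fixture("example1")
EX2 = fixture("example2")


class TestVectorOps:
    @pytest.mark.parametrize(
        "x, y, xp, yp",
        [
            ((2, 3), (3, 2, 2), (2, 3, 0), (3, 2, 2)),
            ((), (3, 4), (0, 0), (3, 4)),
            ((1, 2), (3, 4), (1, 2), (3, 4)),
        ],
    )
    def test_pad_pair(self, x, y, xp, yp):
        assert pad_pair(x, y) == (xp, yp)

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((2, 3, 4, 5), (3, 4, 5, 6), 4),
            ((3, 2, 0), (3, 2, 3), 3),
            ((7, 1, 2), (7, 1, 2), 0),
        ],
    )
    def test_l1(self, x, y, expected):
        assert l1(x, y) == expected

    def test_l1_length_mismatch(self):
        with pytest.raises(ValueError):
            l1((1, 2), (1, 2, 3))

    @given(
        st.lists(st.integers(0, 8), max_size=5),
        st.lists(st.integers(0, 8), max_size=5),
    )
    @settings(derandomize=True, max_examples=60)
    def test_pad_preserves_entries_and_equalizes_length(self, x, y):
        xp, yp = pad_pair(x, y)
        assert len(xp) == len(yp) == max(len(x), len(y))
        assert xp[: len(x)] == tuple(x) and yp[: len(y)] == tuple(y)
        assert set(xp[len(x) :]) <= {0} and set(yp[len(y) :]) <= {0}


class TestMinimalMatchings:
    def test_worked_example_root_matching(self):
        # six mappings of (2,3,0) onto (3,2,2), two of them minimal at cost 2
        ms = minimal_matchings((2, 3), (3, 2, 2))
        assert ms.value == 2
        assert ms.n_candidates == 6
        assert ms.n_minimal == 2

    def test_identical_distinct_entries_single_minimum(self):
        ms = minimal_matchings((1, 2, 3), (1, 2, 3))
        assert ms.value == 0
        assert ms.n_minimal == 1
        assert ms.n_minimal_collapsed == 1

    def test_tied_entries_counted_exhaustively_but_collapsed(self):
        # (3,3) vs (2,3): one collapsed matching, two underlying permutations
        ms = minimal_matchings((3, 3), (2, 3))
        assert ms.value == 1
        assert ms.n_minimal == 2
        assert ms.n_minimal_collapsed == 1

    @given(
        st.lists(st.integers(0, 6), max_size=5),
        st.lists(st.integers(0, 6), max_size=5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_agrees_with_permutation_enumeration(self, x, y):
        ms = minimal_matchings(x, y)
        value, winners, total = enumerate_permutation_matchings(x, y)
        assert ms.value == value
        assert ms.n_minimal == len(winners)
        assert ms.n_candidates == total
        assert all(p.cost == value for p in ms.pairings)
        assert sum(p.multiplicity for p in ms.pairings) == len(winners)

    def test_cap_breach_raises(self):
        # distinct subtree codes defeat collapsing: 4! co-minimal matchings
        with pytest.raises(EnumerationCapError):
            minimal_matchings(
                (1, 1, 1, 1),
                (1, 1, 1, 1),
                x_codes=list("abcd"),
                y_codes=list("efgh"),
                cap=3,
            )


class TestEmptyDistance:
    def test_ghost_branches_of_worked_example(self):
        _, t2 = fixture("example1")
        b_prime, c_prime = t2.children[t2.root][1], t2.children[t2.root][2]
        assert empty_distance(t2, c_prime) == (2, 7)
        assert empty_distance(t2, b_prime) == (2, 5)

    def test_leaf_contributes_nothing(self):
        t = star(4)
        assert empty_distance(t, t.children[0][0]) == ()

    def test_matches_level_profile_shift(self):
        t = random_tree(9, 40)
        for u in (0, 5, 17):
            assert empty_distance(t, u) == t.level_profile(u)[1:]


class TestVtd:
    def test_worked_example_one(self):
        assert vtd(*EX1) == (1, 2, 6, 0)

    def test_worked_example_two(self):
        assert vtd(*EX2) == (0, 4, 3, 0)

    def test_self_distance_is_zero(self):
        for seed in range(10):
            t = random_tree(seed, 20 * (seed + 1))
            assert set(vtd(t, t)) == {0}

    def test_two_single_nodes(self):
        s = parse_newick("x;")
        assert vtd(s, s) == (0,)

    def test_z_controls_length(self):
        d = vtd(*EX1, z=6)
        assert d == (1, 2, 6, 0, 0, 0, 0)
        assert vtd(*EX1, z=1) == (1, 2)

    def test_star_vs_path(self):
        d = vtd(star(9), path_tree(9))
        assert d == (8, 1, 1, 1, 1, 1, 1, 1, 1, 0)


class TestBruteforceOracle:
    def test_worked_examples(self):
        assert vtd_bruteforce(*EX1) == (1, 2, 6, 0)
        assert vtd_bruteforce(*EX2) == (0, 4, 3, 0)

    def test_size_guard(self):
        with pytest.raises(ValueError):
            vtd_bruteforce(random_tree(0, 40), random_tree(1, 40))

    def test_exhaustive_small_tree_sweep(self):
        # every ordered pair of unlabeled rooted trees with <= 5 nodes
        trees = [t for n in range(1, 6) for t in enumerate_rooted_trees(n)]
        for t1, t2 in itertools.product(trees, repeat=2):
            assert vtd(t1, t2) == vtd_bruteforce(t1, t2)


class TestVtdProperties:
    def test_symmetry(self):
        for seed in range(30):
            t1 = random_tree(seed, 5 + 3 * seed)
            t2 = random_tree(seed + 1000, 5 + 2 * seed)
            assert vtd(t1, t2) == vtd(t2, t1)

    def test_sibling_order_invariance(self, rng):
        for seed in range(20):
            t1 = random_tree(seed, 30)
            t2 = random_tree(seed + 500, 25)
            d = vtd(t1, t2)
            assert vtd(permute_children(t1, rng), permute_children(t2, rng)) == d

    def test_level_count_lower_bound(self):
        for seed in range(30):
            t1 = random_tree(seed, 35)
            t2 = random_tree(seed + 77, 28)
            d = vtd(t1, t2)
            p1, p2 = t1.level_profile(0), t2.level_profile(0)
            for r in range(len(d)):
                c1 = p1[r + 1] if r + 1 < len(p1) else 0
                c2 = p2[r + 1] if r + 1 < len(p2) else 0
                assert d[r] >= abs(c1 - c2)

    def test_empty_tree_consistency(self):
        single = parse_newick("x;")
        for seed in range(20):
            t = random_tree(seed, 30)
            d = vtd(t, single)
            prof = t.level_profile(0)
            for r in range(len(d)):
                expect = prof[r + 1] if r + 1 < len(prof) else 0
                assert d[r] == expect


class TestAlignmentTrace:
    def test_worked_example_level_counts(self):
        tr = alignment_trace(*EX1, exhaustive=True)
        assert tr.n_candidates(1, exhaustive=True) == 6
        assert tr.n_minimal(1, exhaustive=True) == 2

    def test_each_minimal_alignment_extends_to_four(self):
        tr = alignment_trace(*EX1, exhaustive=True)
        minimal = [i for i, n in enumerate(tr.levels[1]) if n.minimal]
        assert len(minimal) == 2
        sums = {}
        for i in minimal:
            assert tr.subalignments_of(2, i, exhaustive=True) == 4
            sums[i] = {n.level_value for n in tr.levels[2] if n.parent == i}
        assert sorted(s for vals in sums.values() for s in vals) == [6, 8]

    def test_best_leaf_reproduces_vtd(self):
        for seed in range(15):
            t1 = random_tree(seed, 18)
            t2 = random_tree(seed + 31, 22)
            assert alignment_trace(t1, t2).distance == vtd(t1, t2)

    def test_identical_trees_single_zero_path(self):
        t = random_tree(4, 15)
        tr = alignment_trace(t, t)
        for lvl in tr.levels:
            minimal = [n for n in lvl if n.minimal]
            assert len(minimal) == 1
            assert minimal[0].level_value == 0

    def test_ghost_conservation(self):
        # the unmatched branch keeps feeding its per-level descendant counts:
        # conditional level-2 sums are (matched pair costs) + ghost profile
        t1, t2 = EX1
        tr = alignment_trace(t1, t2, exhaustive=True)
        b_prime, c_prime = t2.children[t2.root][1], t2.children[t2.root][2]
        ghost_of = {c_prime: empty_distance(t2, c_prime),
                    b_prime: empty_distance(t2, b_prime)}
        seen = 0
        for i, node in enumerate(tr.levels[1]):
            if not node.minimal:
                continue
            ghosts = [y for x, y, _ in node.pairs if x is None]
            assert len(ghosts) == 1
            ghost = ghosts[0]
            matched_cost = sum(
                minimal_matchings(
                    t1.weight_vector(x), t2.weight_vector(y)
                ).value
                for x, y, _ in node.pairs
                if x is not None and y is not None
            )
            expected = matched_cost + ghost_of[ghost][1]
            for sub in tr.levels[2]:
                if sub.parent == i:
                    assert sub.level_value == expected
                    seen += sub.multiplicity
        assert seen == 8  # 4 sub-alignments under each of the 2 minimal ones


class TestScalarize:
    def test_level_sum_over_window(self):
        assert scalarize((1, 2, 6, 0, 0, 0), "level_sum", 2, 5) == 6.0

    def test_rms(self):
        assert scalarize((0, 0, 0), "rms") == 0.0
        assert scalarize((3, 4), "rms") == pytest.approx(np.sqrt(12.5))

    def test_window_beyond_vector_counts_zero(self):
        assert scalarize((1, 2, 6), "level_sum", 2, 9) == 6.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            scalarize((1,), "median")
        with pytest.raises(ValueError):
            scalarize((1, 2), "level_sum")
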