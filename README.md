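# vectree

Vectorial tree distance (VTD) between unlabeled rooted trees, with a
k-means variant for clustering sets of trees — aimed at phylogenetics
workflows that need to compare or group tree *shapes* (species trees from
different clades, simulated phylogenies under different speciation regimes)
when taxon labels are unavailable, incomparable, or deliberately ignored.

## The distance

Classical tree distances (Robinson–Foulds, SPR, branch-score) compare
leaf-label partitions and need a shared taxon set.  The vectorial tree
distance instead compares bare topology, level by level from the root
outwards, and returns a *vector* rather than a scalar: entry `D(R)` says how
much the two trees differ at distance `R` from the root, so a disagreement
near the root is never conflated with one near the leaves.

Each node `O` with children `c_1..c_k` carries a one-step look-ahead weight
vector `V(O) = (n_1, ..., n_k)`, where `n_i` is the out-degree of `c_i`.
For two weight vectors (the shorter zero-padded),

    M(X, Y) = min_{σ ∈ Sym(k)} L1(σ(X), Y),

the minimal-weight matching cost.  Then, for roots `O`, `O'`:

* `D(0) = |deg(O) − deg(O')|`,
* `D(1) = M(V(O), V(O'))`,
* `D(2..z)` is the **lexicographic minimum**, over all matchings `σ`
  achieving `M`, of the entrywise sum of the child-pair distance vectors
  `D¹` (the same recursion one level down).  A child matched against
  padding becomes a *ghost branch*: its subtree contributes its per-level
  descendant counts to all deeper entries.

Earlier levels always take precedence, which makes `D` well defined even
when several matchings tie.  The recursion prunes to minimal matchings
only, collapses matchings that merely swap isomorphic subtrees, and
memoizes subtree pairs by canonical (AHU) code; an exhaustive brute-force
enumeration of every level-preserving, descendancy-preserving alignment is
included as an independent oracle and agrees with the fast path on every
small-tree sweep in the test suite.

For clustering, `D` is scalarized (root mean square over levels, or a sum
over a level window) and fed to either the **vectorial k-means** (VKM) —
whose cluster centers are representative *member trees*, re-chosen each
iteration as the member closest to its co-members — or a PAM-style
k-medoids on the same matrix.

## Worked example

The library's `fixture("example1")` pair (root look-ahead weights `(2,3)`
vs `(3,2,2)`):

```python
>>> from vectree import fixture, vtd, minimal_matchings, alignment_trace
>>> t1, t2 = fixture("example1")
>>> vtd(t1, t2)
(1, 2, 6, 0)
```

Level 0: root degrees 2 vs 3 differ by 1.  Level 1: the best matching of
`(2,3,0)` onto `(3,2,2)` costs 2, and of the 6 possible mappings exactly 2
are minimal:

```python
>>> ms = minimal_matchings(t1.weight_vector(0), t2.weight_vector(0))
>>> (ms.value, ms.n_candidates, ms.n_minimal)
(2, 6, 2)
```

Level 2: the two minimal alignments leave different branches unmatched —
one orphans a subtree with 7 grandchildren (level-2 sum `0 + 1 + 7 = 8`),
the other one with 5 (`0 + 1 + 5 = 6`); the lexicographic rule keeps the
smaller, so `D(2) = 6`:

```python
>>> tr = alignment_trace(t1, t2, exhaustive=True)
>>> sorted({n.level_value for n in tr.levels[2]})
[6, 8]
```

The same machinery drives the CLI:

```
$ vectree dist a.nwk b.nwk            # -> [1, 2, 6, 0]
$ vectree matrix *.nwk --format csv   # pairwise tensor, long format
$ vectree cluster *.nwk --k 2 --seed 1 --labels labels.tsv
$ vectree simulate --family asymmetric --seed 1 --m 30 --out fam.nwk
```

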