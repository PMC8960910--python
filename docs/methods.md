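# Methods

## The distance recursion

The vectorial tree distance of two rooted trees is the integer vector
`D(0..z)` defined by the level-wise alignment described in the README.  Two
formal readings coexist: a *global* one (among all level- and
descendancy-preserving alignments of the two trees, take the alignment
whose per-level difference vector is lexicographically minimal, earlier
levels first) and a *recursive* one (at each node pair, restrict to
matchings of the padded child lists achieving the minimal L1 cost, recurse
into the matched subtree pairs, sum the child vectors entrywise, and take
the lexicographic minimum over the tied matchings).  These agree: the
lexicographic order on integer vectors is translation-invariant, so the
minimum of a sum over independent subtree choices is the sum of the minima,
and per-level global minimality decomposes into per-pair matching
minimality.  `vtd` implements the recursive reading; `vtd_bruteforce`
implements the global one literally (every child bijection at every matched
pair, no minimality pruning) and the test suite checks exact agreement on
the complete set of rooted trees with up to 6 nodes (both argument orders)
and on 200 seeded random pairs with up to 10 nodes.

Conventions worth stating:

* **Indexing.** `D(0)` is the root-degree difference and `D(1)` the root
  matching cost; the lexicographic comparison inside the recursion starts
  at entry 2, since entries 0–1 are identical across all tied matchings.
* **Vector length.** `z="auto"` means `max(depth1, depth2)`; `D` is
  reported with `z + 1` entries, zero-extended (never silently truncated)
  when the requested `z` exceeds the trees' depth.  Explicit `z` truncates
  after the full vector is computed, so a truncated report never changes
  which alignment won.
* **Child-vector summation.** Child vectors of unequal length are
  right-padded with zeros before the entrywise sum, and enter the parent's
  vector shifted down one level.
* **Ghosts.** A branch matched against padding contributes, at every
  deeper level, the number of its descendants at that level (its level
  profile shifted by one).  This is exactly the cost of matching its
  weight vectors against nothing, applied recursively.
* **All-integer core.** Every quantity up to scalarization is an exact
  integer; ties are therefore exact, not tolerance-dependent.

## Matching enumeration

Positions whose subtrees have equal canonical (AHU) code are
interchangeable: swapping them changes neither the matching cost nor any
deeper entry.  Padded child lists are therefore grouped by code, and a
matching is a contingency matrix between x-groups and y-groups.  The
optimal cost is obtained from `scipy.optimize.linear_sum_assignment` on the
expanded cost matrix; all cost-optimal matrices are then enumerated by a
pruned depth-first search.  The number of raw permutations `σ ∈ Sym(k)`
inducing a matrix is `(∏ ci!)(∏ dj!)/∏ nij!`, which recovers exhaustive,
non-collapsed counts (the published matching-table numbers) without
enumerating `k!` permutations; a literal `itertools.permutations`
enumeration is kept for oracle tests.  Enumeration is guarded by a cap
(default 100 000 co-minimal matchings) that raises an explicit
`EnumerationCapError` naming the parameter — degenerate inputs fail loudly
rather than silently truncating.  In the worst case (many equal-weight,
pairwise non-isomorphic siblings) the number of co-minimal matchings is
genuinely factorial and no enumeration strategy avoids it; for random
bounded-degree trees ties are rare and runtime grows sub-quadratically in
node count (measured on uniform-attachment trees of 250–2000 nodes,
degree ≤ 3, three seeds per size).

## Alignment trace

`alignment_trace` runs the same search breadth-first and records, per
level, every candidate alignment (its level sum, its permutation
multiplicity, whether it was minimal); only minimal candidates are extended
to the next level.  In exhaustive mode the first expanded level lists the
full matching table of the root pair, reproducing the published candidate
counts (6 mappings, 2 minimal, each extending to 4 sub-alignments with
level-2 sums 8 and 6 on the first worked pair).  The best complete path
reproduces `vtd`'s vector, which is asserted on random pairs.

## Rooting

Phylogenetic trees arrive rooted, so the Newick root is used by default.
For unrooted or arbitrarily rooted input, `find_center` locates the Jordan
center by iterative leaf removal and `--center-root` reroots there before
comparison.  A tree has one or two centers; with two, the choice is
deterministic: the center whose side of the center–center edge holds more
nodes, ties broken by the smaller canonical code of the rerooted tree, then
by node id.  Whether to instead take the minimum distance over both center
choices is exposed to the caller simply by rerooting at each center and
comparing — the library fixes no policy beyond determinism.

## Scalarization and clustering

Two scalarizations of `D` are provided: root mean square over all levels
(the default for clustering) and a level-window sum (e.g. levels 2–5, a
useful band when comparing phylogenies whose shallow levels are near-
constant and whose deep levels are noise); level indices are 0-based.  The
pairwise tensor of `n` trees is `n × n × L` with vectors zero-padded to the
longest pair.

The vectorial k-means assigns each tree to the representative with minimal
scalarized distance, then re-chooses each cluster's representative as the
member minimizing the summed scalarized distance to its co-members;
"root-mean-square of the distance" is read per pair (scalarize each
vector, then sum over members), which matches the assignment rule.  Both
steps weakly decrease the objective (sum of member-to-representative
distances), so the iteration converges; the objective trace is recorded
and asserted non-increasing in tests.  Initialization is a seeded uniform
sample of k distinct trees; `max_iter` defaults to 100; an emptied cluster
seizes the tree farthest from its current representative.  The PAM-style
k-medoids (seeded init, best-improvement swaps) is an independent
cross-check on the same scalar matrix.  The cluster count k is always
user-supplied.  Both clusterers are scikit-learn-compatible estimators
(`fit`/`fit_predict`, `labels_`, `medoid_indices_`, `get_params`), so they
compose with sklearn model-selection tooling.

## Synthetic trees

The generator emulates a continuous-time branching (speciation) process
with Weibull-distributed waiting times, stopped at a target taxa count,
with extinction disabled.  Parameters and defaults, chosen to mirror the
published experimental conditions:

| family | inheritance | Weibull shape | scale | taxa |
|---|---|---|---|---|
| symmetric | both daughters draw fresh waits | 3 | 0.1 | 10 |
| asymmetric | one daughter inherits the mother's clock | 3 | 0.1 | 10 |
| hierarchical | asymmetric | 4 | 0.1 | 15 |
| flat | asymmetric | 1 (exponential) | 0.1 | 15 |

"Inheriting the clock" means the daughter's waiting time runs from the
mother's *birth*, redrawn up to 10 times conditioned on exceeding the age
already elapsed, splitting immediately in the limit.  With an ageing
(shape > 1) waiting-time law this makes old lineages re-split quickly, so
asymmetric trees are markedly deeper and less balanced than symmetric ones
at matched taxa — the qualitative contrast the clustering experiments rely
on — while retaining within-family topological variation.  Exact shapes
(`star`, `path`) and uniform-attachment random trees (`uniform_random`,
bounded degree) cover deterministic fixtures and scaling runs.  Seeding is
a master seed with per-tree streams derived by counter, reproducible
across platforms.

What the generator does *not* emulate: extinction, fossilization, branch
lengths (topology only), and the exact output distribution of any specific
simulator.  Tests passing on these families therefore demonstrate that the
distance separates balance- and synchrony-contrasts in topology; they do
not certify performance on any particular real clade.

## Known limitations

* Complexity is not worst-case polynomial: adversarial trees with many
  equal-weight non-isomorphic siblings explode the set of co-minimal
  matchings (capped, loud failure).
* The distance ignores labels and branch lengths by design; it cannot
  distinguish trees that are topologically isomorphic but biologically
  different, and `D = 0` means isomorphic shape, not identical phylogeny.
* Deep recursion on path-like trees requires a raised Python recursion
  limit, handled internally (saved and restored around the call).
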