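"""Clustering sets of trees by their vectorial distance.

The pairwise distances of ``n`` trees form an ``n x n x L`` integer tensor
(vectors zero-padded to a common level count ``L``).  Two clusterers operate
on a scalarized view of that tensor:

* :class:`VectorialKMeans` — a k-means variant for distance data: each
  cluster's center is a *representative member* (the tree minimizing the
  summed scalarized distance to its co-members), and assignment sends every
  tree to the representative at minimal scalarized distance.
* :class:`TreeKMedoids` — classical PAM-style k-medoids on the same scalar
  matrix, as an independent cross-check.

Both are scikit-learn-compatible estimators (``fit`` / ``fit_predict``,
``labels_`` etc.) and accept either a list of :class:`~vectree.tree.RootedTree`
or a precomputed tensor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state

from .core import vtd
from .tree import RootedTree


@dataclass
class DistanceTensor:
    """Pairwise distance vectors of a tree set: values[i, j, :] = D(i, j)."""

    values: np.ndarray  # (n, n, L) nonnegative integers

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError("tensor must have shape (n, n, L)")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_levels(self) -> int:
        return self.values.shape[2]

    def scalarize(
        self, mode: str = "rms", lo: int | None = None, hi: int | None = None
    ) -> np.ndarray:
        """Collapse to an (n, n) float matrix (see :func:`vectree.core.scalarize`)."""
        v = self.values.astype(float)
        if mode == "rms":
            return np.sqrt((v**2).mean(axis=2))
        if mode == "level_sum":
            if lo is None or hi is None:
                raise ValueError("level_sum requires lo and hi")
            return v[:, :, lo : hi + 1].sum(axis=2)
        raise ValueError(f"unknown scalarization mode {mode!r}")

    def to_long_dataframe(self):
        """Long-format table (i, j, level, value) for CSV export."""
        import pandas as pd

        n, _, L = self.values.shape
        i, j, r = np.indices((n, n, L))
        return pd.DataFrame(
            {
                "i": i.ravel(),
                "j": j.ravel(),
                "level": r.ravel(),
                "value": self.values.ravel(),
            }
        )


def pairwise_tensor(
    trees: list[RootedTree], z: int | str = "auto", **vtd_kwargs
) -> DistanceTensor:
    """Symmetric tensor of pairwise distance vectors.

    With ``z="auto"`` every pair uses its own natural depth and the level
    axis is the maximum vector length over pairs, shorter vectors
    zero-padded.
    """
    n = len(trees)
    if n < 1:
        raise ValueError("need at least one tree")
    vecs: dict[tuple[int, int], tuple[int, ...]] = {}
    for i, j in itertools.combinations(range(n), 2):
        vecs[(i, j)] = vtd(trees[i], trees[j], z, **vtd_kwargs)
    L = max((len(v) for v in vecs.values()), default=1)
    values = np.zeros((n, n, L), dtype=np.int64)
    for (i, j), v in vecs.items():
        values[i, j, : len(v)] = v
        values[j, i, : len(v)] = v
    return DistanceTensor(values)


@dataclass
class ClusterResult:
    """Outcome of a clustering run on ``n`` trees.

    ``margins[i]`` is the scalarized distance from tree ``i`` to its second
    nearest representative minus the distance to its nearest one (>= 0; small
    margins flag borderline trees).
    """

    assignments: np.ndarray  # (n,) cluster ids 0..k-1
    representatives: np.ndarray  # (k,) tree indices
    n_iterations: int
    converged: bool
    margins: np.ndarray  # (n,) floats
    objective: float
    objective_trace: list[float]


def _margins(s: np.ndarray, reps: np.ndarray) -> np.ndarray:
    d = s[:, reps]
    if len(reps) == 1:
        return np.zeros(s.shape[0])
    part = np.sort(d, axis=1)
    return part[:, 1] - part[:, 0]


def _result_from(
    s: np.ndarray, labels: np.ndarray, reps: np.ndarray,
    n_iter: int, converged: bool, trace: list[float],
) -> ClusterResult:
    obj = float(s[np.arange(len(labels)), reps[labels]].sum())
    return ClusterResult(
        assignments=labels.copy(),
        representatives=reps.copy(),
        n_iterations=n_iter,
        converged=converged,
        margins=_margins(s, reps),
        objective=obj,
        objective_trace=trace,
    )


class _ScalarMatrixClusterer(BaseEstimator, ClusterMixin):
    """Shared plumbing: tree list / tensor ingestion and scalarization."""

    def __init__(
        self,
        n_clusters: int = 2,
        z: int | str = "auto",
        scalar: str = "rms",
        levels: tuple[int, int] | None = None,
        max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.z = z
        self.scalar = scalar
        self.levels = levels
        self.max_iter = max_iter
        self.random_state = random_state

    def _scalar_matrix(self, X) -> np.ndarray:
        if isinstance(X, DistanceTensor):
            tensor = X
        elif isinstance(X, np.ndarray) and X.ndim == 3:
            tensor = DistanceTensor(X)
        elif isinstance(X, np.ndarray) and X.ndim == 2:
            return np.asarray(X, dtype=float)  # already scalarized
        else:
            tensor = pairwise_tensor(list(X), self.z)
        lo, hi = self.levels if self.levels is not None else (None, None)
        return tensor.scalarize(self.scalar, lo, hi)

    def _validate(self, s: np.ndarray) -> None:
        n = s.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters={self.n_clusters} not in 1..{n}")

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_

    def _store(self, result: ClusterResult) -> None:
        self.labels_ = result.assignments
        self.representative_indices_ = result.representatives
        self.medoid_indices_ = result.representatives  # familiar alias
        self.n_iter_ = result.n_iterations
        self.converged_ = result.converged
        self.margins_ = result.margins
        self.inertia_ = result.objective
        self.result_ = result


class VectorialKMeans(_ScalarMatrixClusterer):
    """K-means over tree distance vectors with member representatives.

    Iterates two steps until the assignment stabilizes (or ``max_iter``):
    assign each tree to the representative with minimal scalarized distance,
    then recompute each cluster's representative as the member minimizing
    the summed scalarized distance to the cluster's members.  Initial
    representatives are a seeded sample of ``n_clusters`` distinct trees.
    The objective (summed distance of trees to their representative) never
    increases between iterations.  An emptied cluster is repaired by seizing
    the tree currently farthest from its own representative.
    """

    def fit(self, X, y=None):
        s = self._scalar_matrix(X)
        self._validate(s)
        n, k = s.shape[0], self.n_clusters
        rng = check_random_state(self.random_state)
        reps = np.sort(rng.choice(n, size=k, replace=False))
        prev_labels = None
        labels = np.argmin(s[:, reps], axis=1)
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            labels = np.argmin(s[:, reps], axis=1)
            for c in range(k):
                if not np.any(labels == c):  # empty cluster: seize farthest tree
                    far = int(np.argmax(s[np.arange(n), reps[labels]]))
                    labels[far] = c
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                converged = True
                break
            for c in range(k):
                members = np.flatnonzero(labels == c)
                within = s[np.ix_(members, members)].sum(axis=1)
                reps[c] = members[int(np.argmin(within))]
            trace.append(float(s[np.arange(n), reps[labels]].sum()))
            prev_labels = labels
        self._store(_result_from(s, labels, reps, it, converged, trace))
        return self


class TreeKMedoids(_ScalarMatrixClusterer):
    """PAM-style k-medoids on the scalarized distance matrix.

    Seeded random initialization followed by greedy best-improvement swaps
    of (medoid, non-medoid) pairs until no swap lowers the total cost.
    """

    def fit(self, X, y=None):
        s = self._scalar_matrix(X)
        self._validate(s)
        n, k = s.shape[0], self.n_clusters
        rng = check_random_state(self.random_state)
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        cost = s[:, medoids].min(axis=1).sum()
        trace = [float(cost)]
        it = 0
        improved = True
        while improved and it < self.max_iter:
            it += 1
            improved = False
            best_cost, best_swap = cost, None
            for mi in range(k):
                for cand in range(n):
                    if cand in medoids:
                        continue
                    trial = medoids.copy()
                    trial[mi] = cand
                    c = s[:, trial].min(axis=1).sum()
                    if c < best_cost - 1e-12:
                        best_cost, best_swap = c, (mi, cand)
            if best_swap is not None:
                medoids[best_swap[0]] = best_swap[1]
                cost = best_cost
                trace.append(float(cost))
                improved = True
        medoids = np.sort(medoids)
        labels = np.argmin(s[:, medoids], axis=1)
        self._store(
            _result_from(s, labels, medoids, it, not improved, trace)
        )
        return self


def vkm(
    trees,
    k: int,
    z: int | str = "auto",
    scalar: str = "rms",
    levels: tuple[int, int] | None = None,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterResult:
    """Functional wrapper over :class:`VectorialKMeans`."""
    est = VectorialKMeans(
        n_clusters=k, z=z, scalar=scalar, levels=levels,
        max_iter=max_iter, random_state=seed,
    )
    est.fit(trees)
    return est.result_


def kmedoids(
    tensor,
    k: int,
    scalar: str = "rms",
    levels: tuple[int, int] | None = None,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterResult:
    """Functional wrapper over :class:`TreeKMedoids`."""
    est = TreeKMedoids(
        n_clusters=k, scalar=scalar, levels=levels,
        max_iter=max_iter, random_state=seed,
    )
    est.fit(tensor)
    return est.result_


def confusion(
    assignments, true_labels
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Row-normalized confusion matrix under the best label-cluster map.

    Returns ``(normalized, counts, mapping)`` where ``mapping`` sends each
    true class (row) to the cluster id (column) chosen to maximize the
    diagonal; rows are normalized to sum to 1.
    """
    a = np.asarray(assignments)
    t = np.asarray(true_labels)
    if a.shape != t.shape:
        raise ValueError("assignments and labels differ in length")
    classes = np.unique(t)
    clusters = np.unique(a)
    k = max(len(classes), len(clusters))
    counts = np.zeros((len(classes), len(clusters)), dtype=np.int64)
    for ci, cls in enumerate(classes):
        for ki, clu in enumerate(clusters):
            counts[ci, ki] = int(np.sum((t == cls) & (a == clu)))
    # best mapping maximizes the trace; padded square for the assignment solver
    # (phantom all-zero columns stand in for missing clusters)
    pad = np.zeros((k, k), dtype=np.int64)
    pad[: counts.shape[0], : counts.shape[1]] = counts
    rows, cols = linear_sum_assignment(-pad)
    perm = [c for _, c in sorted(zip(rows, cols))]
    counts = pad[: len(classes), perm]
    mapping = {
        cls: (clusters[perm[ci]] if perm[ci] < len(clusters) else None)
        for ci, cls in enumerate(classes)
    }
    norm = counts / counts.sum(axis=1, keepdims=True)
    return norm, counts, mapping


def clustering_accuracy(assignments, true_labels) -> float:
    """Fraction correct under the best label-cluster mapping."""
    _, counts, _ = confusion(assignments, true_labels)
    return float(np.trace(counts) / counts.sum())
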