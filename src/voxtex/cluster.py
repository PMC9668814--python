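"""Affinity-propagation clustering of subjects' positive-relevance maps.

Similarities are negative squared Euclidean distances between voxelized
maps; the shared preference is the median off-diagonal similarity, so the
number of clusters is not fixed in advance.  Message passing follows the
classic responsibility/availability updates with damping.  Cluster labels
are reindexed 1..C by descending cluster size (ties by exemplar index),
matching the size-ranked reporting convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RelevanceMap

__all__ = [
    "SimilarityMatrix",
    "ClusterAssignment",
    "similarities",
    "affinity_propagation",
    "cluster_report",
]


@dataclass
class SimilarityMatrix:
    s: np.ndarray  # (N, N); diagonal holds the preferences

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        if self.s.ndim != 2 or self.s.shape[0] != self.s.shape[1]:
            raise ValueError("similarity matrix must be square")
        off = self.s[~np.eye(len(self.s), dtype=bool)]
        if off.size and not np.isfinite(off).all():
            raise ValueError("off-diagonal similarities must be finite")

    @property
    def n(self) -> int:
        return self.s.shape[0]


@dataclass
class ClusterAssignment:
    exemplars: np.ndarray  # exemplar index per subject
    labels: np.ndarray     # 1..C, cluster 1 largest
    iterations: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0


def similarities(maps: list[RelevanceMap], preference: float | None = None) -> SimilarityMatrix:
    """s(i,k) = −‖PRᵢ − PR_k‖²; preference = median off-diagonal similarity."""
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].data.shape
    for m in maps:
        if m.data.shape != shape:
            raise ValueError("all maps must share a grid")
    X = np.stack([m.data.ravel() for m in maps]).astype(np.float64)
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    s = -np.maximum(d2, 0.0)
    np.fill_diagonal(s, 0.0)
    if preference is None:
        off = s[~np.eye(len(s), dtype=bool)]
        preference = float(np.median(off)) if off.size else 0.0
    np.fill_diagonal(s, preference)
    return SimilarityMatrix(s)


def _size_ranked_labels(exemplars: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(exemplars, return_counts=True)
    order = np.lexsort((uniq, -counts))  # size desc, exemplar index asc
    rank = {int(uniq[j]): i + 1 for i, j in enumerate(order)}
    return np.array([rank[int(e)] for e in exemplars])


def affinity_propagation(
    S: SimilarityMatrix,
    damping: float = 0.9,
    max_iter: int = 1000,
    stable_iter: int = 100,
) -> ClusterAssignment:
    """Frey–Dueck message passing with damping.

    Stops when the exemplar set is unchanged for ``stable_iter`` sweeps or
    after ``max_iter``; a run that never stabilizes returns the final state
    with ``converged=False`` and a warning.  Assignments maximize
    ``s(i, exemplar)`` over the final exemplar set; exemplars are their own
    exemplar.
    """
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must lie in [0.5, 1)")
    n = S.n
    if n == 1:
        return ClusterAssignment(
            exemplars=np.zeros(1, dtype=int),
            labels=np.ones(1, dtype=int),
            iterations=0,
            converged=True,
        )

    s = S.s.copy()
    # eps-scale deterministic jitter breaks exact ties (degenerate fixed
    # points with duplicated similarities/preferences), as in Frey–Dueck
    jitter_rng = np.random.default_rng(0)
    eps = np.finfo(np.float64).eps
    tiny = np.finfo(np.float64).tiny * 100
    s += (eps * s + tiny) * jitter_rng.standard_normal((n, n))
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    prev = None
    stable = 0
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + s
        first = np.argmax(AS, axis=1)
        max1 = AS[idx, first]
        AS[idx, first] = -np.inf
        max2 = np.max(AS, axis=1)
        AS[idx, first] = max1
        Rnew = s - max1[:, None]
        Rnew[idx, first] = s[idx, first] - max2
        R = damping * R + (1.0 - damping) * Rnew

        # availabilities
        Rp = np.maximum(R, 0.0)
        Rp[idx, idx] = R[idx, idx]
        col = Rp.sum(axis=0)
        Anew = np.minimum(0.0, col[None, :] - Rp)
        Anew[idx, idx] = col - Rp[idx, idx]
        A = damping * A + (1.0 - damping) * Anew

        ex = np.flatnonzero(np.diag(A + R) > 0)
        key = ex.tobytes()
        if prev == key and ex.size:
            stable += 1
            if stable >= stable_iter:
                converged = True
                break
        else:
            stable = 0
        prev = key

    exemplar_set = np.flatnonzero(np.diag(A + R) > 0)
    if exemplar_set.size == 0:
        exemplar_set = np.array([int(np.argmax(np.diag(A + R)))])
    if not converged:
        warnings.warn("affinity propagation did not stabilize; returning best-so-far")

    assign = exemplar_set[np.argmax(s[:, exemplar_set], axis=1)]
    assign[exemplar_set] = exemplar_set  # exemplars are self-exemplars
    # refinement: re-choose each exemplar as the member maximizing the
    # within-cluster similarity sum, then re-assign (Frey–Dueck final step)
    refined = []
    for e in exemplar_set:
        members = np.flatnonzero(assign == e)
        sums = s[np.ix_(members, members)].sum(axis=0)
        refined.append(int(members[np.argmax(sums)]))
    exemplar_set = np.unique(refined)
    assign = exemplar_set[np.argmax(s[:, exemplar_set], axis=1)]
    assign[exemplar_set] = exemplar_set
    return ClusterAssignment(
        exemplars=assign,
        labels=_size_ranked_labels(assign),
        iterations=it,
        converged=converged,
    )


def cluster_report(
    maps: list[RelevanceMap], assignment: ClusterAssignment
) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Voxel-wise mean map per cluster + a membership table.

    Clusters are keyed 1..C by descending size (the assignment's labels).
    """
    if len(maps) != len(assignment.labels):
        raise ValueError("assignment does not cover all maps")
    means: dict[int, np.ndarray] = {}
    for label in sorted(set(int(l) for l in assignment.labels)):
        members = [m.data for m, l in zip(maps, assignment.labels) if l == label]
        means[label] = np.mean(members, axis=0)
    table = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in maps],
            "cluster": assignment.labels,
            "exemplar_id": [
                maps[int(e)].subject_id or str(int(e)) for e in assignment.exemplars
            ],
        }
    )
    return means, table
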