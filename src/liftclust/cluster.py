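"""Flat and hierarchical clustering of the ROM feature table.

Implements Lloyd's K-means with restarts, Ward's agglomerative method via the
Lance-Williams recurrence on squared distances, dendrogram cutting, and the
elbow/silhouette curves used to pick the cluster count.  All algorithms are
self-contained so they can be verified against brute-force oracles and, where
available, against scipy/scikit-learn implementations in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .metrics import canonical_labels

__all__ = [
    "Partition",
    "MergeTree",
    "KSelectionCurve",
    "kmeans",
    "ward_linkage",
    "cut_tree",
    "selection_curves",
    "within_cluster_ss",
    "mean_silhouette",
]


@dataclass
class Partition:
    """A labeling of n objects into k clusters; labels are 1..k, every cluster non-empty."""

    labels: np.ndarray
    k: int
    inertia: Optional[float] = None
    centroids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if present.size != self.k:
            raise ValueError("every cluster 1..k must be non-empty")

    @property
    def n(self) -> int:
        return self.labels.size


@dataclass
class MergeTree:
    """Agglomerative merge history in linkage-matrix convention.

    ``merges`` has one row per merge: (node_a, node_b, height, merged_size),
    with leaves numbered 0..n-1 and internal nodes n..2n-2 in merge order.
    Heights are the Ward distances (non-decreasing; singleton-singleton height
    equals the Euclidean distance between the two points).
    """

    merges: np.ndarray

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.ndim != 2 or self.merges.shape[1] != 4:
            raise ValueError("merges must be an (n-1) x 4 array")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9 * max(1.0, heights.max(initial=0.0))):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1


@dataclass
class KSelectionCurve:
    k_values: np.ndarray
    wss: np.ndarray
    silhouette: np.ndarray
    elbow_k: int
    silhouette_k: int


def _squared_distances(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    return cdist(X, C, metric="sqeuclidean")


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator):
    n = X.shape[0]
    uniq = np.unique(X, axis=0)
    init_idx = rng.choice(uniq.shape[0], size=k, replace=False)
    C = uniq[np.sort(init_idx)].copy()
    labels = np.full(n, -1, dtype=np.int64)
    inertia_history = []
    while True:
        d2 = _squared_distances(X, C)
        new_labels = np.argmin(d2, axis=1)  # ties -> lowest centroid index
        # reseed empty clusters with the point farthest from its assigned centroid
        for c in range(k):
            if not np.any(new_labels == c):
                point_d2 = d2[np.arange(n), new_labels]
                far = int(np.argmax(point_d2))
                new_labels[far] = c
                C[c] = X[far]
                d2 = _squared_distances(X, C)
        inertia = float(d2[np.arange(n), new_labels].sum())
        inertia_history.append(inertia)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            C[c] = X[labels == c].mean(axis=0)
    return labels, C, inertia, inertia_history


def kmeans(X, k: int, n_restarts: int = 10, seed: int = 0) -> Partition:
    """Lloyd's algorithm, best of ``n_restarts`` by inertia, deterministic given seed.

    Initial centroids are k distinct data points; assignment ties go to the
    lowest centroid index; an emptied cluster is reseeded with the point
    farthest from its assigned centroid.  Stops when assignments no longer
    change.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    n_distinct = np.unique(X, axis=0).shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        labels, C, inertia, history = _lloyd(X, k, rng)
        if np.any(np.diff(history) > 1e-8 * max(1.0, history[0])):
            raise AssertionError("Lloyd inertia increased across iterations")
        if best is None or inertia < best[2]:
            best = (labels, C, inertia)
    labels, C, inertia = best
    canon = canonical_labels(labels + 1)
    # reorder centroids to match the canonical labels
    centroids = np.zeros_like(C)
    for old in np.unique(labels):
        new = canon[labels == old][0]
        centroids[new - 1] = C[old]
    return Partition(labels=canon, k=k, inertia=inertia, centroids=centroids)


def ward_linkage(X) -> MergeTree:
    """Ward's agglomerative clustering by the Lance-Williams recurrence.

    Works on squared inter-cluster distances d2 with the convention
    d2(E, F) = 2 nE nF / (nE + nF) * ||centroid_E - centroid_F||^2, so two
    singletons merge at exactly their Euclidean distance and each merge height
    squared equals twice the increase in total within-cluster sum of squares.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 objects")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    d2 = cdist(X, X, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    sizes = np.ones(n)
    node_ids = np.arange(n)
    active = np.ones(n, dtype=bool)
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        flat = int(np.argmin(d2))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        d2_ij = d2[i, j]
        a, b = sorted((int(node_ids[i]), int(node_ids[j])))
        new_size = sizes[i] + sizes[j]
        merges[step] = (a, b, np.sqrt(max(d2_ij, 0.0)), new_size)
        # Lance-Williams update of every other active cluster t against the merge
        others = active.copy()
        others[[i, j]] = False
        if np.any(others):
            nt = sizes[others]
            d2_new = (
                (nt + sizes[i]) * d2[others, i]
                + (nt + sizes[j]) * d2[others, j]
                - nt * d2_ij
            ) / (nt + new_size)
            d2[others, i] = d2_new
            d2[i, others] = d2_new
        sizes[i] = new_size
        node_ids[i] = n + step
        active[j] = False
        d2[j, :] = np.inf
        d2[:, j] = np.inf
    return MergeTree(merges=merges)


def cut_tree(tree: MergeTree, k: int) -> Partition:
    """Partition into k clusters by undoing the last k-1 merges.

    Labels are assigned 1..k by descending cluster size, ties by smallest
    member index, so repeated cuts are deterministic and nested.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    members = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b, _h, _s = tree.merges[step]
        new_id = n + step
        members[new_id] = members.pop(int(a)) + members.pop(int(b))
    labels = np.zeros(n, dtype=np.int64)
    clusters = sorted(members.values(), key=lambda m: (-len(m), min(m)))
    for lab, mem in enumerate(clusters, start=1):
        labels[mem] = lab
    return Partition(labels=labels, k=k)


def within_cluster_ss(X, labels) -> float:
    """Total within-cluster sum of squared Euclidean deviations from centroids."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    total = 0.0
    for u in np.unique(labels):
        G = X[labels == u]
        total += float(((G - G.mean(axis=0)) ** 2).sum())
    return total


def mean_silhouette(X, labels) -> float:
    """Mean silhouette coefficient with Euclidean distance; singletons score 0."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    s = np.zeros(n)
    masks = {u: labels == u for u in uniq}
    for i in range(n):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, masks[u]].mean() for u in uniq if u != labels[i])
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def _elbow_k(k_values: np.ndarray, wss: np.ndarray) -> int:
    """k with maximum perpendicular distance to the chord of the normalized WSS curve."""
    k_values = np.asarray(k_values, dtype=float)
    wss = np.asarray(wss, dtype=float)
    x = (k_values - k_values[0]) / max(k_values[-1] - k_values[0], 1e-12)
    span = max(wss[0] - wss[-1], 1e-12)
    y = (wss - wss[-1]) / span
    # chord from (0, y0) to (1, y_last) in normalized coordinates
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([x, y]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return int(k_values[int(np.argmax(dist))])


def selection_curves(
    X,
    k_min: int = 2,
    k_max: int = 10,
    method: str = "kmeans",
    n_restarts: int = 10,
    seed: int = 0,
) -> KSelectionCurve:
    """WSS (elbow) and mean-silhouette curves over ``k_min..k_max`` for one method."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 2 <= k_min <= k_max:
        raise ValueError("need k_max >= k_min >= 2")
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of objects")
    if method not in {"kmeans", "ward"}:
        raise ValueError("method must be 'kmeans' or 'ward'")
    tree = ward_linkage(X) if method == "ward" else None
    k_values = np.arange(k_min, k_max + 1)
    wss = np.zeros(k_values.size)
    sil = np.zeros(k_values.size)
    for idx, k in enumerate(k_values):
        if method == "ward":
            part = cut_tree(tree, int(k))
        else:
            part = kmeans(X, int(k), n_restarts=n_restarts, seed=seed + idx)
        wss[idx] = within_cluster_ss(X, part.labels)
        sil[idx] = mean_silhouette(X, part.labels)
    return KSelectionCurve(
        k_values=k_values,
        wss=wss,
        silhouette=sil,
        elbow_k=_elbow_k(k_values, wss),
        silhouette_k=int(k_values[int(np.argmax(sil))]),
    )
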