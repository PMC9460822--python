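"""Hypergraph consensus over an ensemble of K-means base clusterings.

A set of base partitions is encoded as a binary incidence matrix (objects x
hyperedges, one column per cluster per partition) and combined by one of the
three classical hypergraph consensus functions:

* CSPA -- re-cluster the object-object co-association matrix;
* HGPA -- cut the fewest hyperedges while splitting objects into near-equal
  groups;
* MCLA -- cluster the hyperedges themselves into balanced meta-clusters and
  assign each object to its strongest meta-cluster.

The balanced partitioners are self-contained (greedy multi-start with
Kernighan-Lin-style local moves, exact enumeration on tiny instances) so they
can be checked against exhaustive oracles without any external graph package.
Group sizes (HGPA) and vertex-weight sums (MCLA) are kept within +/-25% of
the ideal ``total/k``, the operational reading of "roughly equal size".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import List

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cluster import Partition, kmeans
from .metrics import canonical_labels

__all__ = [
    "BaseClusteringSet",
    "IncidenceMatrix",
    "ConsensusResult",
    "build_base_clusterings",
    "incidence_matrix",
    "cspa",
    "hgpa",
    "mcla",
    "balance_bounds",
]

BALANCE_TOLERANCE = 0.25
_EXHAUSTIVE_LIMIT = 200_000


@dataclass
class BaseClusteringSet:
    """Duplicate-free list of base partitions over the same objects."""

    partitions: List[Partition]

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ValueError("need at least one partition")
        sizes = {p.n for p in self.partitions}
        if len(sizes) != 1:
            raise ValueError("all partitions must cover the same objects")

    @property
    def r(self) -> int:
        return len(self.partitions)

    @property
    def n_objects(self) -> int:
        return self.partitions[0].n


@dataclass
class IncidenceMatrix:
    """Binary hypergraph adjacency: one row per object, one column per hyperedge."""

    entries: np.ndarray  # (v, a) in {0, 1}
    block_sizes: List[int]  # hyperedges contributed by each partition

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if self.entries.ndim != 2:
            raise ValueError("entries must be 2-D")
        if int(sum(self.block_sizes)) != self.entries.shape[1]:
            raise ValueError("block sizes must sum to the number of columns")
        start = 0
        for g in self.block_sizes:
            block = self.entries[:, start : start + g]
            if not np.all(block.sum(axis=1) == 1):
                raise ValueError("each row must have exactly one 1 per partition block")
            start += g

    @property
    def v(self) -> int:
        return self.entries.shape[0]

    @property
    def a(self) -> int:
        return self.entries.shape[1]

    @property
    def r(self) -> int:
        return len(self.block_sizes)


@dataclass
class ConsensusResult:
    partition: Partition
    method: str
    diagnostics: dict = field(default_factory=dict)


def _canonical_form(labels: np.ndarray) -> tuple:
    """Label-permutation-invariant fingerprint: relabel by first occurrence."""
    mapping: dict = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


def build_base_clusterings(
    X, k: int, runs: int = 50, seed: int = 0
) -> BaseClusteringSet:
    """Single-restart K-means runs with duplicate partitions removed.

    Duplicates are detected up to label permutation; the first occurrence is
    kept and order is preserved.  If every run collapses to one partition the
    set is legal but a warning is emitted.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    seen = set()
    partitions = []
    for run in range(runs):
        part = kmeans(X, k, n_restarts=1, seed=seed * runs + run)
        form = _canonical_form(part.labels)
        if form not in seen:
            seen.add(form)
            partitions.append(part)
    if len(partitions) == 1 and runs > 1:
        warnings.warn("all base clustering runs were identical (r = 1)", stacklevel=2)
    return BaseClusteringSet(partitions=partitions)


def incidence_matrix(base: BaseClusteringSet) -> IncidenceMatrix:
    """Concatenated one-hot blocks, one column per cluster per partition.

    Within each block, columns are ordered by each cluster's first object
    index, so the matrix is invariant to relabelings of the base partitions.
    """
    v = base.n_objects
    blocks = []
    block_sizes = []
    for part in base.partitions:
        labels = np.asarray(_canonical_form(part.labels))
        g = labels.max() + 1
        block = np.zeros((v, g), dtype=np.uint8)
        block[np.arange(v), labels] = 1
        blocks.append(block)
        block_sizes.append(int(g))
    return IncidenceMatrix(entries=np.hstack(blocks), block_sizes=block_sizes)


def balance_bounds(total: float, k: int, tolerance: float = BALANCE_TOLERANCE):
    """(lo, hi) admissible per-group weight for near-equal k-way splits."""
    ideal = total / k
    lo = max(1.0, np.floor((1.0 - tolerance) * ideal))
    hi = np.ceil((1.0 + tolerance) * ideal)
    return lo, hi


# ---------------------------------------------------------------------------
# CSPA
# ---------------------------------------------------------------------------


def cspa(incidence: IncidenceMatrix, k: int, seed: int = 0) -> ConsensusResult:
    """Co-association consensus: B = (1/r) L L^T re-clustered at k.

    B entries are the fraction of base partitions placing the pair together.
    Objects are re-clustered by average-linkage agglomerative merging on the
    dissimilarity 1 - B, cut at k clusters.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > incidence.v:
        raise ValueError("k exceeds the number of objects")
    L = incidence.entries.astype(float)
    B = (L @ L.T) / incidence.r
    dis = 1.0 - B
    np.fill_diagonal(dis, 0.0)
    condensed = squareform(dis, checks=False)
    Z = linkage(condensed, method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = canonical_labels(raw)
    part = Partition(labels=labels, k=int(labels.max()))
    return ConsensusResult(
        partition=part, method="CSPA", diagnostics={"coassociation": B}
    )


# ---------------------------------------------------------------------------
# balanced partitioning engine (shared by HGPA and MCLA)
# ---------------------------------------------------------------------------


def _repair_balance(assign, weights, k, lo, hi):
    """Move items out of over-full groups (and into under-full ones) until feasible."""
    assign = assign.copy()
    loads = np.zeros(k)
    np.add.at(loads, assign, weights)
    for _ in range(assign.size * k):
        over = np.where(loads > hi)[0]
        under = np.where(loads < lo)[0]
        if over.size == 0 and under.size == 0:
            break
        src = int(over[0]) if over.size else int(np.argmax(loads))
        dst = int(under[0]) if under.size else int(np.argmin(loads))
        if src == dst:
            break
        members = np.where(assign == src)[0]
        if members.size <= 1:
            break
        item = int(members[np.argmin(weights[members])])
        assign[item] = dst
        loads[src] -= weights[item]
        loads[dst] += weights[item]
    return assign


def _random_balanced_assignment(n, k, rng):
    perm = rng.permutation(n)
    assign = np.zeros(n, dtype=np.int64)
    for g, chunk in enumerate(np.array_split(perm, k)):
        assign[chunk] = g
    return assign


def _hyperedge_cut_count(entries: np.ndarray, assign: np.ndarray, k: int) -> int:
    """Number of hyperedges whose member objects span more than one group."""
    C = np.zeros((k, entries.shape[1]), dtype=np.int64)
    for g in range(k):
        C[g] = entries[assign == g].sum(axis=0)
    return int(((C > 0).sum(axis=0) > 1).sum())


def _hgpa_local_search(entries, assign, k, lo, hi, rng, max_passes=20):
    v = entries.shape[0]
    obj_cols = [np.flatnonzero(entries[i]) for i in range(v)]
    C = np.zeros((k, entries.shape[1]), dtype=np.int64)
    for g in range(k):
        C[g] = entries[assign == g].sum(axis=0)
    sizes = np.bincount(assign, minlength=k).astype(float)
    for _ in range(max_passes):
        improved = False
        for i in rng.permutation(v):
            g1 = int(assign[i])
            if sizes[g1] - 1 < lo:
                continue
            cols = obj_cols[i]
            nz_before = (C[:, cols] > 0).sum(axis=0)
            cut_before = (nz_before > 1).sum()
            best_delta, best_g = 0, -1
            for g2 in range(k):
                if g2 == g1 or sizes[g2] + 1 > hi:
                    continue
                c1_after = C[g1, cols] - 1
                nz_after = nz_before - (c1_after == 0) + (C[g2, cols] == 0)
                delta = int((nz_after > 1).sum() - cut_before)
                if delta < best_delta:
                    best_delta, best_g = delta, g2
            if best_g >= 0:
                C[g1, cols] -= 1
                C[best_g, cols] += 1
                sizes[g1] -= 1
                sizes[best_g] += 1
                assign[i] = best_g
                improved = True
        if not improved:
            break
    return assign, _hyperedge_cut_count(entries, assign, k)


def _exhaustive_hgpa(entries, k, lo, hi):
    v = entries.shape[0]
    best = None
    for assign in product(range(k), repeat=v):
        sizes = np.bincount(assign, minlength=k)
        if sizes.min() < lo or sizes.max() > hi:
            continue
        cut = _hyperedge_cut_count(entries, np.asarray(assign), k)
        if best is None or cut < best[0]:
            best = (cut, np.asarray(assign, dtype=np.int64))
    if best is None:
        raise ValueError("no balanced partition exists under the tolerance")
    return best[1], best[0]


def _partition_starts(incidence: IncidenceMatrix, k: int) -> List[np.ndarray]:
    """Deterministic starts induced by the base partitions themselves."""
    starts = []
    offset = 0
    for g in incidence.block_sizes[:5]:
        block = incidence.entries[:, offset : offset + g]
        offset += g
        if g > k:
            continue
        starts.append(np.argmax(block, axis=1).astype(np.int64) % k)
    return starts


def hgpa(
    incidence: IncidenceMatrix, k: int, seed: int = 0, n_starts: int = 8
) -> ConsensusResult:
    """Minimum-hyperedge-cut consensus into k near-balanced groups.

    Hyperedges and vertices are unit-weighted; a hyperedge counts as cut when
    its objects span more than one group.  Tiny instances are solved by exact
    enumeration; larger ones by multi-start greedy local search seeded both
    randomly and from the base partitions.  Deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    v = incidence.v
    if v < k:
        raise ValueError("fewer objects than groups")
    entries = incidence.entries.astype(np.int64)
    lo, hi = balance_bounds(v, k)
    if k**v <= _EXHAUSTIVE_LIMIT:
        assign, cut = _exhaustive_hgpa(entries, k, lo, hi)
    else:
        rng = np.random.default_rng(seed)
        candidates = []
        for start in _partition_starts(incidence, k):
            repaired = _repair_balance(start, np.ones(v), k, lo, hi)
            candidates.append(repaired)
        for _ in range(n_starts):
            candidates.append(_random_balanced_assignment(v, k, rng))
        best = None
        for cand in candidates:
            assign, cut = _hgpa_local_search(entries, cand.copy(), k, lo, hi, rng)
            if best is None or cut < best[1]:
                best = (assign, cut)
        assign, cut = best
    labels = canonical_labels(assign + 1)
    part = Partition(labels=labels, k=int(labels.max()))
    sizes = np.bincount(assign, minlength=k)
    return ConsensusResult(
        partition=part,
        method="HGPA",
        diagnostics={"cut": int(cut), "group_sizes": sizes.tolist()},
    )


# ---------------------------------------------------------------------------
# MCLA
# ---------------------------------------------------------------------------


def _jaccard_matrix(entries: np.ndarray) -> np.ndarray:
    inter = entries.T.astype(float) @ entries.astype(float)
    sizes = entries.sum(axis=0).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(S, 0.0)
    return S


def _weighted_cut(S: np.ndarray, assign: np.ndarray) -> float:
    same = assign[:, None] == assign[None, :]
    return float(S[~same].sum() / 2.0)


def _mcla_local_search(S, weights, assign, k, lo, hi, rng, max_passes=20):
    a = S.shape[0]
    onehot = np.zeros((k, a))
    for g in range(k):
        onehot[g, assign == g] = 1.0
    M = onehot @ S  # M[g, e] = total similarity of e to group g
    loads = np.zeros(k)
    np.add.at(loads, assign, weights)
    for _ in range(max_passes):
        improved = False
        for e in rng.permutation(a):
            g1 = int(assign[e])
            if loads[g1] - weights[e] < lo:
                continue
            internal = M[g1, e]
            best_gain, best_g = 1e-12, -1
            for g2 in range(k):
                if g2 == g1 or loads[g2] + weights[e] > hi:
                    continue
                gain = M[g2, e] - internal  # increase in within-group similarity
                if gain > best_gain:
                    best_gain, best_g = gain, g2
            if best_g >= 0:
                M[g1] -= S[e]
                M[best_g] += S[e]
                loads[g1] -= weights[e]
                loads[best_g] += weights[e]
                assign[e] = best_g
                improved = True
        if not improved:
            break
    return assign


def _exhaustive_mcla_partition(S, weights, k, lo, hi):
    a = S.shape[0]
    best = None
    for assign in product(range(k), repeat=a):
        assign = np.asarray(assign, dtype=np.int64)
        loads = np.zeros(k)
        np.add.at(loads, assign, weights)
        if loads.min() < lo or loads.max() > hi:
            continue
        cut = _weighted_cut(S, assign)
        if best is None or cut < best[0] - 1e-12:
            best = (cut, assign)
    if best is None:
        raise ValueError("no balanced meta-partition exists under the tolerance")
    return best[1]


def mcla(
    incidence: IncidenceMatrix, k: int, seed: int = 0, n_starts: int = 8
) -> ConsensusResult:
    """Meta-clustering consensus.

    The hyperedges form a meta-graph with binary-Jaccard edge weights and
    vertex weights equal to cluster sizes.  The meta-graph is partitioned into
    k weight-balanced meta-clusters (minimum weighted cut); each meta-cluster's
    hyperedges are collapsed by per-object averaging into an association
    vector, and every object goes to its argmax meta-cluster (ties to the
    lowest index).  A meta-cluster that wins no object is dropped with a
    warning and the actual cluster count is reported.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    entries = incidence.entries.astype(np.int64)
    a = incidence.a
    if a < k:
        raise ValueError("fewer hyperedges than requested meta-clusters")
    S = _jaccard_matrix(entries)
    weights = entries.sum(axis=0).astype(float)
    lo, hi = balance_bounds(weights.sum(), k)
    rng = np.random.default_rng(seed)
    if k**a <= _EXHAUSTIVE_LIMIT:
        try:
            assign = _exhaustive_mcla_partition(S, weights, k, lo, hi)
        except ValueError:
            # vertex weights too lopsided for the tolerance (e.g. one small base
            # cluster): relax to the non-empty-groups constraint only
            assign = _exhaustive_mcla_partition(S, weights, k, 1e-9, np.inf)
    else:
        candidates = []
        offset = 0
        for g in incidence.block_sizes[:3]:
            block_cols = np.arange(offset, offset + g)
            offset += g
            if g != k:
                continue
            # assign every hyperedge to its most similar cluster of this block
            sim = S[:, block_cols].copy()
            sim[block_cols, np.arange(g)] = 1.0  # a block column matches itself
            candidates.append(
                _repair_balance(np.argmax(sim, axis=1), weights, k, lo, hi)
            )
        for _ in range(n_starts):
            candidates.append(
                _repair_balance(
                    _random_balanced_assignment(a, k, rng), weights, k, lo, hi
                )
            )
        # relax the balance window when no candidate satisfies it (possible
        # with very lopsided cluster sizes); groups must still stay non-empty
        def _feasible(cand):
            loads = np.zeros(k)
            np.add.at(loads, cand, weights)
            return loads.min() >= lo and loads.max() <= hi

        if not any(_feasible(c) for c in candidates):
            lo, hi = 1e-9, np.inf
        best = None
        for cand in candidates:
            out = _mcla_local_search(S, weights, cand.copy(), k, lo, hi, rng)
            cut = _weighted_cut(S, out)
            if best is None or cut < best[0] - 1e-12:
                best = (cut, out)
        assign = best[1]

    # collapse meta-clusters into association vectors and assign objects
    assoc = np.zeros((k, incidence.v))
    meta_map = {}
    for g in range(k):
        cols = np.flatnonzero(assign == g)
        meta_map[g] = cols.tolist()
        if cols.size:
            assoc[g] = entries[:, cols].mean(axis=1)
    obj_assign = np.argmax(assoc.T, axis=1)  # ties -> lowest meta-cluster index
    occupied = np.unique(obj_assign)
    if occupied.size < k:
        warnings.warn(
            f"MCLA produced {occupied.size} non-empty clusters (requested {k})",
            stacklevel=2,
        )
    labels = canonical_labels(obj_assign + 1)
    part = Partition(labels=labels, k=int(labels.max()))
    return ConsensusResult(
        partition=part,
        method="MCLA",
        diagnostics={
            "meta_clusters": meta_map,
            "cut": _weighted_cut(S, assign),
            "n_clusters": int(occupied.size),
        },
    )
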