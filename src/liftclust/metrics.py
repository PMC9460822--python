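"""Partition-comparison utilities: contingency tables, ARI, label matching."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

__all__ = [
    "contingency_table",
    "adjusted_rand_index",
    "match_labels",
    "canonical_labels",
]


def contingency_table(labels_a, labels_b) -> np.ndarray:
    """Cross-tabulation of two labelings of the same objects."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have the same length")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand agreement; 1.0 iff the partitions coincide up to relabeling."""
    table = contingency_table(labels_a, labels_b)
    n = table.sum()
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def match_labels(pred, true) -> dict:
    """Map each predicted label to a true label by maximum overlap.

    Uses an optimal one-to-one assignment on the contingency table, which for
    well-recovered clusterings coincides with majority matching.  Returns
    ``{pred_label: true_label}``.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    up = np.unique(pred)
    ut = np.unique(true)
    table = contingency_table(pred, true)
    # pad to square so the assignment is always feasible
    size = max(up.size, ut.size)
    padded = np.zeros((size, size), dtype=np.int64)
    padded[: up.size, : ut.size] = table
    rows, cols = linear_sum_assignment(-padded)
    mapping = {}
    for r, c in zip(rows, cols):
        if r < up.size:
            mapping[int(up[r])] = int(ut[c]) if c < ut.size else -1
    return mapping


def canonical_labels(labels) -> np.ndarray:
    """Relabel clusters as 1..k ordered by descending size, ties by smallest member index."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda u: (-int(np.sum(labels == u)), int(np.argmax(labels == u))),
    )
    out = np.empty_like(labels, dtype=np.int64)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out
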