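"""External clustering-validity indices: NMI and the Rand index.

Both compare a candidate partition against a reference labeling and are
invariant to relabeling on either side. NMI uses the geometric-mean
normalization NMI = I(A;B) / sqrt(H(A) H(B)) by default (natural-log
entropies internally; the base cancels); an arithmetic-mean variant is
available. The Rand index is the fraction of item pairs on which the two
partitions agree (co-clustered in both or separated in both).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["PartitionMetrics", "contingency", "nmi", "rand_index", "partition_metrics"]


@dataclass(frozen=True)
class PartitionMetrics:
    """NMI and Rand index for one pair of labelings, plus their contingency."""

    nmi: float
    rand_index: float
    contingency: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.nmi <= 1.0 and 0.0 <= self.rand_index <= 1.0):
            raise ValueError("both indices must lie in [0, 1]")


def _as_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("labels must be a non-empty 1-D sequence")
    return arr


def contingency(labels_a, labels_b) -> np.ndarray:
    """Count matrix: entry (r, c) counts items with label r in a and c in b.

    Rows/columns follow the sorted unique labels of each side; row sums are
    the class sizes of a, column sums those of b.
    """
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    r, c = ai.max() + 1, bi.max() + 1
    table = np.zeros((r, c), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _entropy(counts: np.ndarray) -> float:
    """Natural-log entropy of a count vector."""
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(labels_a, labels_b, average_method: str = "geometric") -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    1 iff the partitions are identical up to label renaming; 0 for
    independent partitions. If one side is a single cluster (zero entropy)
    the value is defined as 1 when both sides are single clusters and 0
    otherwise.
    """
    table = contingency(labels_a, labels_b).astype(float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    h_a = _entropy(row)
    h_b = _entropy(col)
    if h_a == 0.0 or h_b == 0.0:
        both_single = table.shape[0] == 1 and table.shape[1] == 1
        logger.debug(
            "single-cluster labeling: NMI defined as %s by convention",
            1.0 if both_single else 0.0,
        )
        return 1.0 if both_single else 0.0

    nz = table > 0
    p = table[nz] / n
    outer = np.outer(row, col)[nz] / (n * n)
    mi = float((p * np.log(p / outer)).sum())
    if average_method == "geometric":
        denom = np.sqrt(h_a * h_b)
    elif average_method == "arithmetic":
        denom = 0.5 * (h_a + h_b)
    else:
        raise ValueError(f"unknown average_method {average_method!r}")
    return float(min(max(mi / denom, 0.0), 1.0))


def rand_index(labels_a, labels_b) -> float:
    """Rand index: (agreeing pairs) / (N choose 2), in [0, 1].

    A pair agrees when it is co-clustered in both partitions or separated in
    both. Symmetric; 1 iff the partitions are identical up to renaming.
    """
    table = contingency(labels_a, labels_b).astype(np.int64)
    n = int(table.sum())
    if n < 2:
        raise ValueError("the Rand index needs at least 2 items")

    def comb2(x):
        return x * (x - 1) // 2

    total = comb2(n)
    sum_ij = int(comb2(table).sum())
    sum_a = int(comb2(table.sum(axis=1)).sum())
    sum_b = int(comb2(table.sum(axis=0)).sum())
    disagree = sum_a + sum_b - 2 * sum_ij
    return float((total - disagree) / total)


def partition_metrics(labels_a, labels_b, average_method: str = "geometric") -> PartitionMetrics:
    """Bundle NMI, Rand index and the contingency table for one label pair."""
    return PartitionMetrics(
        nmi=nmi(labels_a, labels_b, average_method=average_method),
        rand_index=rand_index(labels_a, labels_b),
        contingency=contingency(labels_a, labels_b),
    )
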