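"""Hierarchical clustering of acupoints on their co-occurrence profiles.

Each acupoint is represented by the binary vector of the transactions that
contain it; acupoints are then agglomerated on a pairwise distance matrix.
Defaults are squared Euclidean distance with average (between-groups)
linkage, the historical defaults of SPSS hierarchical clustering, which is
how this analysis is conventionally run; both are configurable.  For binary
vectors the squared Euclidean distance is the number of transactions on
which two acupoints' memberships differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .frequency import item_counts
from .prescriptions import TransactionDB

METRICS = ("squared_euclidean", "jaccard")
LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class ItemProfile:
    """An acupoint and its transaction-membership vector (length N)."""

    item: str
    vector: np.ndarray

    @property
    def count(self) -> int:
        return int(self.vector.sum())


def build_profiles(db: TransactionDB, min_count: int = 1) -> list[ItemProfile]:
    """Profiles for all items with support count >= min_count.

    Ordered by descending count, ties lexicographic.  Raises if no item
    passes the threshold.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    records = [r for r in item_counts(db) if r.count >= min_count]
    if not records:
        raise ValueError(f"no item reaches min_count={min_count}")
    membership = {
        r.item: np.array(
            [1 if r.item in p.items else 0 for p in db.prescriptions], dtype=np.int8
        )
        for r in records
    }
    return [ItemProfile(r.item, membership[r.item]) for r in records]


def distance_matrix(
    profiles: Sequence[ItemProfile], metric: str = "squared_euclidean"
) -> np.ndarray:
    """Symmetric zero-diagonal pairwise distance matrix over the profiles."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    m = np.array([p.vector for p in profiles], dtype=float)
    if metric == "squared_euclidean":
        diff = m[:, None, :] != m[None, :, :]
        return diff.sum(axis=2).astype(float)
    inter = m @ m.T
    union = m.sum(axis=1)[:, None] + m.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` lists (cluster_a, cluster_b, height, new_cluster_id) with
    leaves numbered 0..n-1 and new clusters n, n+1, ...; ``linkage_matrix``
    is the equivalent scipy linkage encoding.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    leaves: tuple[str, ...]
    linkage_matrix: np.ndarray

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]


def agglomerate(
    dist: np.ndarray,
    labels: Sequence[str],
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels are inconsistent")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    merges = tuple(
        (int(row[0]), int(row[1]), float(row[2]), n + i) for i, row in enumerate(z)
    )
    return Dendrogram(merges, tuple(labels), z)


def cut(dendrogram: Dendrogram, k: int) -> dict[int, list[str]]:
    """Partition into k clusters by undoing the last k-1 merges.

    Returns cluster_id (1..k, in order of first leaf appearance) -> items.
    Cutting at k+1 always refines the cut at k.
    """
    n = len(dendrogram.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    labels = hierarchy.cut_tree(dendrogram.linkage_matrix, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    clusters: dict[int, list[str]] = {}
    for leaf, raw in zip(dendrogram.leaves, labels):
        cid = relabel.setdefault(int(raw), len(relabel) + 1)
        clusters.setdefault(cid, []).append(leaf)
    return clusters


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths = merge-height differences."""
    n = len(dendrogram.leaves)
    height = {i: 0.0 for i in range(n)}
    rendered = {i: dendrogram.leaves[i] for i in range(n)}
    node = ""
    for a, b, h, new_id in dendrogram.merges:
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node = f"({rendered[a]}:{la:g},{rendered[b]}:{lb:g})"
        rendered[new_id] = node
        height[new_id] = h
    return node + ";"


def partition_table(partition: dict[int, list[str]]) -> pd.DataFrame:
    """Report table: ``item``, ``cluster_id``."""
    rows = [
        (item, cid) for cid in sorted(partition) for item in partition[cid]
    ]
    return pd.DataFrame(rows, columns=["item", "cluster_id"])


def write_partition_tsv(partition: dict[int, list[str]], path: str | Path) -> None:
    partition_table(partition).to_csv(path, sep="\t", index=False)
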