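"""Agglomerative Ward clustering via Lance-Williams updates.

Ward's linkage merges, at every step, the pair of clusters whose fusion
least increases within-cluster dispersion.  After merging clusters i and
j, the dissimilarity from the merged cluster to any other cluster ``k``
follows the Lance-Williams recurrence

    d(k, i+j) = [(n_i + n_k) d(k,i) + (n_j + n_k) d(k,j) - n_k d(i,j)]
                / (n_i + n_j + n_k).

Two dialects exist in the field's software and differ on non-Euclidean
input: ``ward_d`` applies the recurrence to the raw dissimilarities,
``ward_d2`` applies it to squared dissimilarities and reports
square-root merge heights.  Both are provided; ties in the closest pair
are broken lexicographically on the (row, column) position so dendrograms
are reproducible across platforms.  On non-Euclidean input (Jaccard,
simple matching) height inversions are possible; they are logged, not
fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

DIALECTS = ("ward_d", "ward_d2")


class Merge(NamedTuple):
    """One agglomeration step: cluster ids merged, fusion height, new size.

    Leaves are ids ``0..n-1``; the merge recorded at step ``t`` creates
    cluster id ``n + t``.
    """

    cluster_a: int
    cluster_b: int
    height: float
    new_size: int


@dataclass
class Dendrogram:
    n_leaves: int
    merges: list[Merge]
    leaf_labels: list
    dialect: str = "ward_d2"
    n_inversions: int = 0

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError(
                f"expected {self.n_leaves - 1} merges, got {len(self.merges)}"
            )
        for m in self.merges:
            if m.height < -1e-12:
                raise ValueError(f"negative merge height {m.height}")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])


@dataclass
class ClusterAssignment:
    """Partition of labelled entities into clusters ``1..k``."""

    labels: list
    cluster_ids: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)
        if len(self.labels) != len(self.cluster_ids):
            raise ValueError("labels and cluster_ids length mismatch")
        present = np.unique(self.cluster_ids)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(
                f"cluster ids must be exactly 1..{self.k}, got {present.tolist()}"
            )

    def members(self, cluster_id: int) -> list:
        return [l for l, c in zip(self.labels, self.cluster_ids) if c == cluster_id]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_ids, minlength=self.k + 1)[1:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.labels, "cluster": self.cluster_ids})


def relabel_by_first_appearance(raw: np.ndarray, labels: list) -> ClusterAssignment:
    """Map arbitrary integer labels to 1..k in order of first appearance."""
    raw = np.asarray(raw)
    mapping: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return ClusterAssignment(list(labels), out, len(mapping))


def agglomerate_ward(dm: DistanceMatrix, dialect: str = "ward_d2") -> Dendrogram:
    """Greedy closest-pair agglomeration with the Ward update rule."""
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    n = dm.n
    if n < 2:
        raise ValueError("need at least two entities to agglomerate")

    w = dm.values.astype(float).copy()
    if dialect == "ward_d2":
        w = w**2
    np.fill_diagonal(w, np.inf)
    sizes = np.ones(n)
    ids = np.arange(n)  # current cluster id occupying each slot
    active = np.ones(n, dtype=bool)

    merges: list[Merge] = []
    prev_height = -np.inf
    n_inversions = 0
    for step in range(n - 1):
        flat = int(np.argmin(w))  # row-major first minimum = lexicographic tie-break
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        dij = w[i, j]
        height = float(np.sqrt(dij) if dialect == "ward_d2" else dij)
        if height < prev_height - 1e-12:
            n_inversions += 1
        prev_height = max(prev_height, height)

        si, sj = sizes[i], sizes[j]
        act = np.flatnonzero(active)
        act = act[(act != i) & (act != j)]
        new = ((si + sizes[act]) * w[i, act] + (sj + sizes[act]) * w[j, act]
               - sizes[act] * dij) / (si + sj + sizes[act])
        w[i, act] = new
        w[act, i] = new
        w[j, :] = np.inf
        w[:, j] = np.inf
        active[j] = False
        sizes[i] = si + sj
        merges.append(Merge(int(ids[i]), int(ids[j]), height, int(si + sj)))
        ids[i] = n + step

    if n_inversions:
        logger.warning("%d height inversion(s) in %s dendrogram (non-Euclidean input)",
                       n_inversions, dialect)
    return Dendrogram(n, merges, list(dm.labels), dialect, n_inversions)


def cut(dendro: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into ``k`` clusters by undoing the last ``k-1`` merges."""
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, int] = {i: i for i in range(n)}  # cluster id -> representative
    for t in range(n - k):
        m = dendro.merges[t]
        ra, rb = find(members[m.cluster_a]), find(members[m.cluster_b])
        parent[rb] = ra
        members[n + t] = ra
    roots = np.fromiter((find(i) for i in range(n)), dtype=int, count=n)
    return relabel_by_first_appearance(roots, dendro.leaf_labels)


def to_newick(dendro: Dendrogram, digits: int = 6) -> str:
    """Serialize as a Newick string; branch lengths are height differences.

    Leaves sit at height 0.  Height inversions would give negative branch
    lengths; those are floored at 0.
    """
    n = dendro.n_leaves
    node_height = {i: 0.0 for i in range(n)}
    rep: dict[int, str] = {
        i: str(lab).replace(",", "_").replace("(", "_").replace(")", "_")
        .replace(":", "_").replace(";", "_").replace(" ", "_")
        for i, lab in enumerate(dendro.leaf_labels)
    }
    for t, m in enumerate(dendro.merges):
        h = m.height
        parts = []
        for child in (m.cluster_a, m.cluster_b):
            bl = max(h - node_height[child], 0.0)
            parts.append(f"{rep.pop(child)}:{bl:.{digits}f}")
        new_id = n + t
        rep[new_id] = f"({parts[0]},{parts[1]})"
        node_height[new_id] = h
    (root,) = rep.values()
    return root + ";"


def merges_frame(dendro: Dendrogram) -> pd.DataFrame:
    """hclust-style merge table: negative = leaf (1-based), positive = step."""
    n = dendro.n_leaves

    def signed(cid: int) -> int:
        return -(cid + 1) if cid < n else cid - n + 1

    return pd.DataFrame(
        {
            "a": [signed(m.cluster_a) for m in dendro.merges],
            "b": [signed(m.cluster_b) for m in dendro.merges],
            "height": [m.height for m in dendro.merges],
            "size": [m.new_size for m in dendro.merges],
        }
    )
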