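"""Partition clustering and cluster-quality metrics.

Participant grouping is explored in the space of aggregated item-cluster
scores: for each participant, the number of endorsed items within each
item cluster.  Two partitioners (Lloyd k-means with k-means++ seeding,
and PAM on a dissimilarity matrix) and two scale-free quality metrics
(average silhouette width, between/total sum-of-squares ratio) are used
for model selection and validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .hierarchy import ClusterAssignment, relabel_by_first_appearance
from .preprocess import BinaryMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScoreMatrix:
    """Participants x item-cluster endorsement sums.

    Entry (p, c) counts the endorsed items of item cluster ``c`` for
    participant ``p``; bounded by the cluster's item count.
    """

    data: pd.DataFrame
    item_counts: dict[str, int]

    def __post_init__(self) -> None:
        for name, cnt in self.item_counts.items():
            col = self.data[name]
            if (col < 0).any() or (col > cnt).any():
                raise ValueError(f"scores for {name!r} outside [0, {cnt}]")

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class PartitionQuality:
    """Quality summary of one partition: silhouette + SS decomposition."""

    mean_silhouette: float
    within_ss: float
    between_ss: float
    total_ss: float
    bt_ratio: float

    def __post_init__(self) -> None:
        if self.total_ss > 0 and abs(
            self.within_ss + self.between_ss - self.total_ss
        ) > 1e-6 * self.total_ss:
            raise ValueError("within + between != total sum of squares")


def aggregate_cluster_scores(
    bm: BinaryMatrix, items: ClusterAssignment, names: list[str] | None = None
) -> ScoreMatrix:
    """Sum endorsed items per item cluster for each participant."""
    pos = {lab: i for i, lab in enumerate(items.labels)}
    missing = [c for c in bm.data.columns if c not in pos]
    if missing:
        raise ValueError(f"items absent from the cluster assignment: {missing}")
    if names is None:
        names = [f"C{c}" for c in range(1, items.k + 1)]
    x = bm.values()
    cols = {}
    counts = {}
    for c in range(1, items.k + 1):
        member_idx = [
            j for j, col in enumerate(bm.data.columns)
            if items.cluster_ids[pos[col]] == c
        ]
        cols[names[c - 1]] = x[:, member_idx].sum(axis=1)
        counts[names[c - 1]] = len(member_idx)
    df = pd.DataFrame(cols, index=bm.data.index.copy())
    return ScoreMatrix(df, counts)


def _as_array(x) -> tuple[np.ndarray, list]:
    if isinstance(x, ScoreMatrix):
        return x.values(), list(x.data.index)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, list(range(arr.shape[0]))


def ss_decomposition(x, assign: ClusterAssignment,
                     mean_silhouette: float = float("nan")) -> PartitionQuality:
    """Total/within/between sum-of-squares about centroids.

    ``bt_ratio`` is the fraction of total dispersion explained by the
    cluster centroids; a zero-variance dataset gets bt_ratio 0 with a
    warning.
    """
    arr, labels = _as_array(x)
    if arr.shape[0] != len(assign.cluster_ids):
        raise ValueError("assignment does not cover all rows")
    grand = arr.mean(axis=0)
    total = float(((arr - grand) ** 2).sum())
    within = 0.0
    for c in range(1, assign.k + 1):
        sub = arr[assign.cluster_ids == c]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    between = max(total - within, 0.0)
    if total <= 0:
        logger.warning("zero total sum of squares; bt_ratio defined as 0")
        ratio = 0.0
    else:
        ratio = between / total
    return PartitionQuality(mean_silhouette, within, between, total, ratio)


def silhouette(
    assign: ClusterAssignment, dm: DistanceMatrix
) -> tuple[np.ndarray, float]:
    """Per-entity silhouette widths s(i) = (b-a)/max(a,b) and their mean.

    ``a`` is the mean distance to the entity's own cluster (excluding
    itself), ``b`` the smallest mean distance to another cluster.
    Singleton-cluster members and entities with a = b = 0 get s = 0.
    """
    if assign.k < 2:
        raise ValueError("silhouette undefined for a single cluster")
    if list(assign.labels) != list(dm.labels):
        raise ValueError("assignment and distance-matrix labels differ")
    d = dm.values
    n = d.shape[0]
    onehot = np.zeros((n, assign.k))
    onehot[np.arange(n), assign.cluster_ids - 1] = 1.0
    sums = d @ onehot                      # (n, k) distance sums to each cluster
    sizes = assign.sizes().astype(float)
    own = assign.cluster_ids - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), own] / np.maximum(sizes[own] - 1, 1)
        mean_other = sums / sizes[None, :]
        mean_other[np.arange(n), own] = np.inf
        b = mean_other.min(axis=1)
        s = (b - a) / np.maximum(np.maximum(a, b), np.finfo(float).tiny)
    s[np.maximum(a, b) == 0] = 0.0
    s[sizes[own] == 1] = 0.0
    return s, float(s.mean())


def _kmeans_pp_init(arr: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = arr.shape[0]
    centers = np.empty((k, arr.shape[1]))
    centers[0] = arr[rng.integers(n)]
    closest = ((arr - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = closest.sum()
        if total <= 0:
            centers[c] = arr[rng.integers(n)]
            continue
        probs = closest / total
        centers[c] = arr[rng.choice(n, p=probs)]
        closest = np.minimum(closest, ((arr - centers[c]) ** 2).sum(axis=1))
    return centers


def kmeans(
    x,
    k: int,
    n_init: int = 10,
    seed: int = 0,
    standardize: bool = False,
    max_iter: int = 300,
):
    """Lloyd k-means, best of ``n_init`` k-means++ restarts by within-SS.

    Returns ``(ClusterAssignment, centroids, PartitionQuality)``; the
    quality silhouette is Euclidean in the (optionally z-scored) input
    space.  Empty clusters are re-seeded at the point farthest from its
    centroid.  Deterministic given ``seed``.
    """
    arr, labels = _as_array(x)
    n = arr.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise ValueError(f"need more rows ({n}) than clusters ({k})")
    if standardize:
        sd = arr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        arr = (arr - arr.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        centers = _kmeans_pp_init(arr, k, rng)
        assign = np.full(n, -1)
        for _it in range(max_iter):
            d2 = ((arr[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_assign = d2.argmin(axis=1)
            for c in range(k):
                mask = new_assign == c
                if mask.any():
                    centers[c] = arr[mask].mean(axis=0)
                else:  # empty cluster: re-seed at the globally farthest point
                    far = int(d2.min(axis=1).argmax())
                    logger.debug("re-seeding empty cluster %d at row %d", c, far)
                    centers[c] = arr[far]
                    new_assign[far] = c
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
        within = float(
            ((arr - centers[assign]) ** 2).sum()
        )
        if best is None or within < best[0] - 1e-12:
            best = (within, assign.copy(), centers.copy())
    within, assign_raw, centers = best

    ca = relabel_by_first_appearance(assign_raw, labels)
    order = []
    seen = set()
    for v in assign_raw:
        if v not in seen:
            seen.add(v)
            order.append(v)
    centroids = centers[order]
    if len(order) < k:
        logger.warning("k-means converged to %d non-empty clusters (k=%d)",
                       len(order), k)
    from .distances import euclidean_distances

    _, mean_sil = silhouette(ca, euclidean_distances(arr, labels)) if ca.k >= 2 else (
        None, 0.0)
    quality = ss_decomposition(arr, ca, mean_silhouette=mean_sil)
    if abs(quality.within_ss - within) > 1e-6 * max(quality.total_ss, 1.0):
        logger.debug("within-SS recomputation drift: %g vs %g",
                     quality.within_ss, within)
    return ca, centroids, quality


@dataclass
class PamResult:
    assignment: ClusterAssignment
    medoids: list
    medoid_indices: np.ndarray = field(repr=False, default=None)
    cost: float = float("nan")


def pam(dm: DistanceMatrix, k: int, seed: int = 0) -> PamResult:
    """Partitioning around medoids: greedy BUILD then best-improvement SWAP.

    Operates on the provided dissimilarity matrix; deterministic (ties go
    to the smallest index; ``seed`` is accepted for interface symmetry).
    """
    d = dm.values
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")

    # BUILD
    medoids = [int(d.sum(axis=0).argmin())]
    d_nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        cand = int(gains.argmax())
        medoids.append(cand)
        d_nearest = np.minimum(d_nearest, d[:, cand])

    medoid_arr = np.array(sorted(medoids))
    # SWAP
    for _ in range(200):
        dist_to_m = d[:, medoid_arr]               # (n, k)
        order = dist_to_m.argsort(axis=1, kind="stable")
        d1 = dist_to_m[np.arange(n), order[:, 0]]
        nearest = order[:, 0]
        d2 = dist_to_m[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        current_cost = d1.sum()
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            affected = nearest == mi
            base = np.where(affected, d2, d1)      # cost if medoid mi removed
            # candidate costs for every h at once: min(base, d[:, h])
            cand_cost = np.minimum(base[:, None], d).sum(axis=0)
            cand_cost[medoid_arr] = np.inf
            h = int(cand_cost.argmin())
            delta = current_cost - cand_cost[h]
            if delta > best_delta + 1e-12:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoid_arr[mi] = h
        medoid_arr = np.sort(medoid_arr)
    dist_to_m = d[:, medoid_arr]
    nearest = dist_to_m.argmin(axis=1)
    cost = float(dist_to_m[np.arange(n), nearest].sum())
    ca = relabel_by_first_appearance(nearest, dm.labels)
    return PamResult(ca, [dm.labels[i] for i in medoid_arr], medoid_arr, cost)
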