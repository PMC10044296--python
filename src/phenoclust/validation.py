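"""Resampling nulls, stability checks and descriptive summaries.

Two distinct checks guard the item-cluster solution.  A random-assignment
null rebuilds the aggregated score dataset after shuffling items into
clusters of the same sizes and re-runs k-means, asking whether the
dendrogram-derived solution explains more variance (between/total SS)
than random item groupings.  A participant bootstrap re-runs the item
clustering on resampled cohorts and records how often pairs of items
land in the same cluster.  Partition agreement is quantified with the
adjusted Rand index; cluster-score dispersion uses the median absolute
deviation normalized by the cluster's item count; score correlations are
Spearman.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .distances import jaccard_distances
from .hierarchy import ClusterAssignment, agglomerate_ward, cut
from .partition import ScoreMatrix, aggregate_cluster_scores, kmeans
from .preprocess import BinaryMatrix

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    statistic_name: str
    draws: list[float]
    observed: float
    empirical_p: float

    def __post_init__(self) -> None:
        b = len(self.draws)
        expected = (1 + sum(1 for d in self.draws if d >= self.observed)) / (1 + b)
        if abs(self.empirical_p - expected) > 1e-12:
            raise ValueError("empirical_p inconsistent with draws")

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.draws, q))


def _random_sized_assignment(
    labels: list, sizes: np.ndarray, rng: np.random.Generator
) -> ClusterAssignment:
    perm = rng.permutation(len(labels))
    raw = np.empty(len(labels), dtype=int)
    start = 0
    for c, size in enumerate(sizes, start=1):
        raw[perm[start:start + size]] = c
        start += size
    from .hierarchy import relabel_by_first_appearance

    return relabel_by_first_appearance(raw, labels)


def random_assignment_null(
    bm: BinaryMatrix,
    observed_assignment: ClusterAssignment,
    k_p: int,
    B: int = 199,
    seed: int = 0,
    size_profile: bool = True,
    kmeans_n_init: int = 5,
) -> NullDistribution:
    """Between/total-SS null from random item-to-cluster assignment.

    Each draw shuffles the items into ``k_i`` clusters (matching the
    observed cluster sizes by default, so the null isolates membership
    rather than size; uniform multinomial with ``size_profile=False``),
    aggregates scores, runs k-means at ``k_p`` and records bt_ratio.
    The observed statistic is computed identically from the dendrogram
    solution.  ``empirical_p = (1 + #{draws >= observed}) / (1 + B)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    k_i = observed_assignment.k
    sizes = observed_assignment.sizes()
    labels = list(observed_assignment.labels)

    def bt_of(assign: ClusterAssignment, s: int) -> float:
        scores = aggregate_cluster_scores(bm, assign)
        _, _, q = kmeans(scores, k_p, n_init=kmeans_n_init, seed=s)
        return q.bt_ratio

    observed = bt_of(observed_assignment, int(rng.integers(2**31)))
    draws = []
    for _ in range(B):
        if size_profile:
            rand_assign = _random_sized_assignment(labels, sizes, rng)
        else:
            raw = rng.integers(1, k_i + 1, size=len(labels))
            while len(np.unique(raw)) < k_i:  # keep all k_i clusters non-empty
                raw = rng.integers(1, k_i + 1, size=len(labels))
            from .hierarchy import relabel_by_first_appearance

            rand_assign = relabel_by_first_appearance(raw, labels)
        draws.append(bt_of(rand_assign, int(rng.integers(2**31))))
    p = (1 + sum(1 for d in draws if d >= observed)) / (1 + B)
    return NullDistribution("bt_ratio", draws, observed, p)


def bootstrap_item_stability(
    bm: BinaryMatrix,
    k_i: int,
    B: int = 50,
    seed: int = 0,
    dialect: str = "ward_d2",
) -> pd.DataFrame:
    """Item co-clustering frequencies over participant bootstrap resamples.

    For each resample the Jaccard distances, Ward dendrogram and k_i-cut
    are recomputed; entry (i, j) is the fraction of resamples (in which
    both items survived variance screening) where i and j share a
    cluster.  Diagonal is 1.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    items = list(bm.data.columns)
    p = len(items)
    together = np.zeros((p, p))
    both_present = np.zeros((p, p))
    x = bm.values()
    for _ in range(B):
        idx = rng.integers(0, x.shape[0], size=x.shape[0])
        sub = x[idx]
        keep = np.flatnonzero(sub.std(axis=0) > 0)
        if len(keep) < p:
            dropped = [items[i] for i in range(p) if i not in set(keep)]
            logger.warning("dropping zero-variance item(s) for this draw: %s",
                           dropped)
        if len(keep) < max(k_i + 1, 2):
            continue
        sub_bm = BinaryMatrix(
            pd.DataFrame(sub[:, keep], columns=[items[i] for i in keep])
        )
        dendro = agglomerate_ward(jaccard_distances(sub_bm, "items"), dialect)
        assign = cut(dendro, min(k_i, len(keep)))
        ids = np.asarray(assign.cluster_ids)
        same = ids[:, None] == ids[None, :]
        together[np.ix_(keep, keep)] += same
        both_present[np.ix_(keep, keep)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(both_present > 0, together / both_present, np.nan)
    np.fill_diagonal(freq, 1.0)
    return pd.DataFrame(freq, index=items, columns=items)


def adjusted_rand(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Chance-corrected agreement between two partitions of the same entities.

    Computed from the contingency table; 1 for identical partitions,
    expectation ~0 for independent ones.  The degenerate all-singletons
    vs all-one-cluster comparison returns 0 by convention.
    """
    if set(a.labels) != set(b.labels):
        raise ValueError("partitions are over different entity sets")
    order = {lab: i for i, lab in enumerate(a.labels)}
    b_ids = np.empty(len(b.labels), dtype=int)
    for lab, cid in zip(b.labels, b.cluster_ids):
        b_ids[order[lab]] = cid
    a_ids = np.asarray(a.cluster_ids)
    n = len(a_ids)
    contingency = np.zeros((a.k, b.k))
    np.add.at(contingency, (a_ids - 1, b_ids - 1), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if abs(max_index - expected) < 1e-12:
        return 0.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class ClusterDispersion:
    """Per-cluster MAD of participant scores, normalized by item count."""

    normalized_mad: dict[str, float]


def normalized_mad(
    scores: ScoreMatrix, consistency_constant: bool = False
) -> ClusterDispersion:
    """median(|x - median(x)|) / items-in-cluster per score column.

    The raw (descriptive) MAD is the default; the 1.4826 normal
    consistency constant can be switched on.
    """
    out = {}
    c = 1.4826 if consistency_constant else 1.0
    for name, cnt in scores.item_counts.items():
        col = scores.data[name].to_numpy(dtype=float)
        mad = float(np.median(np.abs(col - np.median(col))))
        out[name] = c * mad / cnt
    return ClusterDispersion(out)


def spearman_matrix(
    scores: ScoreMatrix, groups: ClusterAssignment | None = None
) -> dict:
    """Spearman correlations between score columns, overall and per group.

    Ties get average ranks.  Zero-variance columns produce NaN entries
    with a warning.  Returns ``{"overall": DataFrame, "by_group": {...}}``.
    """

    def corr(df: pd.DataFrame) -> pd.DataFrame:
        if len(df) < 3:
            raise ValueError("need at least 3 participants per stratum")
        arr = df.to_numpy(dtype=float)
        if (arr.std(axis=0) == 0).any():
            logger.warning("zero-variance score column; NaN correlations")
        rho = spearmanr(arr).statistic
        if np.isscalar(rho):  # two columns: spearmanr returns a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
        rho = np.asarray(rho, dtype=float)
        np.fill_diagonal(rho, 1.0)
        return pd.DataFrame(rho, index=df.columns, columns=df.columns)

    result = {"overall": corr(scores.data), "by_group": {}}
    if groups is not None:
        if list(groups.labels) != list(scores.data.index):
            raise ValueError("group labels do not match score rows")
        for g in range(1, groups.k + 1):
            sub = scores.data.iloc[np.flatnonzero(groups.cluster_ids == g)]
            result["by_group"][g] = corr(sub)
    return result
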