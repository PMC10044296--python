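"""Three-step choice of the number of item and participant clusters.

Step 1 scans an elbow curve over k = 2..20 for the item and participant
dendrograms independently.  Step 2 builds, for every combination of
k_i = 3..10 item clusters and k_p = 3..10 participant clusters, the
aggregated item-cluster score dataset and records average silhouette
widths.  Step 3 narrows to a region of interest (default 3..5 x 3..5),
computes silhouette and between/total-SS quality for hierarchical cuts,
k-means and PAM in every cell, and picks the cell with the best mean
rank across metrics and methods (ties toward smaller k_i, then smaller
k_p).  The elbow step is intrinsically visual; the knee is formalized as
the maximum discrete second difference, and the full curves, grids and
rank tables are kept in the result so a human can audit or override.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import (DistanceMatrix, euclidean_distances, jaccard_distances,
                        simple_matching_distances)
from .hierarchy import ClusterAssignment, Dendrogram, agglomerate_ward, cut
from .partition import (aggregate_cluster_scores, kmeans, pam, silhouette,
                        ss_decomposition)
from .preprocess import BinaryMatrix, screen_items

logger = logging.getLogger(__name__)


@dataclass
class ElbowCurve:
    ks: list[int]
    values: list[float]
    knee_k: int
    flat: bool = False

    def to_dict(self) -> dict:
        return {"k": self.ks, "value": self.values, "knee_k": self.knee_k,
                "flat": self.flat}


def _within_dissimilarity(dm: DistanceMatrix, assign: ClusterAssignment) -> float:
    """Sum over clusters of mean-scaled within-cluster dissimilarity.

    For squared Euclidean input this equals the within-cluster SS
    (sum of pairwise squared distances / cluster size); for general
    dissimilarities it is the analogous cohesion functional.
    """
    total = 0.0
    for c in range(1, assign.k + 1):
        idx = np.flatnonzero(assign.cluster_ids == c)
        if len(idx) > 1:
            sub = dm.values[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def knee_point(ks: list[int], values: list[float]) -> tuple[int, bool]:
    """Knee of a decreasing cohesion curve: max discrete second difference.

    Returns ``(knee_k, flat)``; ``flat`` flags a curve whose second
    differences are nearly uniform (no pronounced knee).
    """
    if len(ks) < 3:
        raise ValueError("need at least three curve points")
    v = np.asarray(values, dtype=float)
    d2 = v[:-2] - 2 * v[1:-1] + v[2:]
    knee_idx = int(d2.argmax()) + 1
    scale = max(abs(v[0] - v[-1]), np.finfo(float).tiny)
    flat = bool(d2.max() - d2.min() < 0.05 * scale)
    return ks[knee_idx], flat


def elbow_scan(dendro: Dendrogram, data, k_range=range(2, 21)) -> ElbowCurve:
    """Cohesion profile over dendrogram cuts, with a second-difference knee.

    ``data`` is either a numeric matrix (within-SS of the k-cut) or a
    :class:`DistanceMatrix` (within-cluster dissimilarity).  The knee is
    argmax of f(k-1) - 2 f(k) + f(k+1) over interior k; a flat curve is
    flagged so the (visual) judgment can be overridden.
    """
    ks = [k for k in k_range if 1 <= k <= dendro.n_leaves]
    if len(ks) < 3:
        raise ValueError("k_range must contain at least three usable values")
    values = []
    for k in ks:
        assign = cut(dendro, k)
        if isinstance(data, DistanceMatrix):
            values.append(_within_dissimilarity(data, assign))
        else:
            values.append(ss_decomposition(data, assign).within_ss)
    knee_k, flat = knee_point(ks, values)
    if flat:
        logger.warning("elbow curve has no pronounced knee (flat second differences)")
    return ElbowCurve(ks, [float(x) for x in values], knee_k, flat)


@dataclass
class SelectionInputs:
    """Distance matrices and dendrograms shared by the selection steps."""

    bm: BinaryMatrix
    item_dm: DistanceMatrix
    part_dm: DistanceMatrix
    item_dendro: Dendrogram
    part_dendro: Dendrogram


def prepare_inputs(
    bm: BinaryMatrix, dialect: str = "ward_d2", min_endorsement: int = 1
) -> SelectionInputs:
    bm = screen_items(bm, min_endorsement)
    item_dm = jaccard_distances(bm, axis="items")
    part_dm = simple_matching_distances(bm, axis="participants")
    item_dendro = agglomerate_ward(item_dm, dialect)
    part_dendro = agglomerate_ward(part_dm, dialect)
    return SelectionInputs(bm, item_dm, part_dm, item_dendro, part_dendro)


def silhouette_grid(
    inputs: SelectionInputs,
    ki_range=range(3, 11),
    kp_range=range(3, 11),
    seed: int = 0,
    kmeans_n_init: int = 5,
) -> dict[str, pd.DataFrame]:
    """Average silhouette width over the (k_i, k_p) exploration window.

    Per cell, participants are partitioned two ways: the participant
    dendrogram cut (silhouette on the simple-matching distances, the
    space that clustering was built in) and k-means on the aggregated
    scores (Euclidean silhouette on the score space).  Degenerate cells
    are NaN.
    """
    ki_list, kp_list = list(ki_range), list(kp_range)
    grids = {m: pd.DataFrame(np.nan, index=ki_list, columns=kp_list)
             for m in ("hca", "kmeans")}
    for m in grids.values():
        m.index.name, m.columns.name = "k_i", "k_p"

    hca_sil: dict[int, float] = {}
    for kp in kp_list:
        try:
            part_assign = cut(inputs.part_dendro, kp)
            _, hca_sil[kp] = silhouette(part_assign, inputs.part_dm)
        except ValueError as exc:
            logger.warning("degenerate HCA cell k_p=%d: %s", kp, exc)

    for ki in ki_list:
        item_assign = cut(inputs.item_dendro, ki)
        scores = aggregate_cluster_scores(inputs.bm, item_assign)
        for kp in kp_list:
            if kp in hca_sil:
                grids["hca"].loc[ki, kp] = hca_sil[kp]
            try:
                _, _, q = kmeans(scores, kp, n_init=kmeans_n_init,
                                 seed=seed + 977 * ki + kp)
                grids["kmeans"].loc[ki, kp] = q.mean_silhouette
            except ValueError as exc:
                logger.warning("degenerate k-means cell (%d, %d): %s", ki, kp, exc)
    return grids


def quality_grid(
    inputs: SelectionInputs,
    ki_range=range(3, 6),
    kp_range=range(3, 6),
    seed: int = 0,
    standardize: bool = False,
    kmeans_n_init: int = 10,
    include_pam: bool = True,
) -> pd.DataFrame:
    """Full quality table over the region of interest.

    Rows are (k_i, k_p) cells; columns are (method, metric) pairs with
    method in {hca, kmeans, pam} and metric in {silhouette, bt_ratio}.
    Silhouettes follow the per-method space convention of
    :func:`silhouette_grid`; bt_ratio is always computed on the score
    matrix under the method's participant partition.
    """
    methods = ["hca", "kmeans"] + (["pam"] if include_pam else [])
    cells = [(ki, kp) for ki in ki_range for kp in kp_range]
    cols = pd.MultiIndex.from_product([methods, ["silhouette", "bt_ratio"]],
                                      names=["method", "metric"])
    grid = pd.DataFrame(np.nan, index=pd.MultiIndex.from_tuples(
        cells, names=["k_i", "k_p"]), columns=cols)

    part_cuts: dict[int, ClusterAssignment] = {}
    part_sil: dict[int, float] = {}
    for kp in sorted({kp for _, kp in cells}):
        part_cuts[kp] = cut(inputs.part_dendro, kp)
        _, part_sil[kp] = silhouette(part_cuts[kp], inputs.part_dm)

    for ki in sorted({ki for ki, _ in cells}):
        item_assign = cut(inputs.item_dendro, ki)
        scores = aggregate_cluster_scores(inputs.bm, item_assign)
        arr = scores.values()
        if standardize:
            sd = arr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            arr = (arr - arr.mean(axis=0)) / sd
        score_dm = euclidean_distances(arr, scores.participant_ids)
        for kp in sorted({kp2 for ki2, kp2 in cells if ki2 == ki}):
            hq = ss_decomposition(arr, part_cuts[kp])
            grid.loc[(ki, kp), ("hca", "silhouette")] = part_sil[kp]
            grid.loc[(ki, kp), ("hca", "bt_ratio")] = hq.bt_ratio
            try:
                ca, _, q = kmeans(arr, kp, n_init=kmeans_n_init,
                                  seed=seed + 7919 * ki + kp)
                grid.loc[(ki, kp), ("kmeans", "silhouette")] = q.mean_silhouette
                grid.loc[(ki, kp), ("kmeans", "bt_ratio")] = q.bt_ratio
            except ValueError as exc:
                logger.warning("degenerate k-means cell (%d, %d): %s", ki, kp, exc)
            if include_pam:
                try:
                    pr = pam(score_dm, kp, seed=seed)
                    _, psil = silhouette(pr.assignment, score_dm)
                    pq = ss_decomposition(arr, pr.assignment)
                    grid.loc[(ki, kp), ("pam", "silhouette")] = psil
                    grid.loc[(ki, kp), ("pam", "bt_ratio")] = pq.bt_ratio
                except ValueError as exc:
                    logger.warning("degenerate PAM cell (%d, %d): %s", ki, kp, exc)
    return grid


@dataclass
class SelectionResult:
    k_i: int
    k_p: int
    region: tuple[list[int], list[int]]
    grid: pd.DataFrame
    ranks: pd.DataFrame
    elbow_items: ElbowCurve | None = None
    elbow_participants: ElbowCurve | None = None
    silhouette_grids: dict[str, pd.DataFrame] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": "1",
            "k_i": self.k_i,
            "k_p": self.k_p,
            "region": {"k_i": self.region[0], "k_p": self.region[1]},
            "grid": {
                f"{m}.{metric}": {
                    f"{ki}x{kp}": (None if np.isnan(v) else float(v))
                    for (ki, kp), v in self.grid[(m, metric)].items()
                }
                for m, metric in self.grid.columns
            },
            "mean_rank": {f"{ki}x{kp}": float(v)
                          for (ki, kp), v in self.ranks["mean_rank"].items()},
            "elbow_items": self.elbow_items.to_dict() if self.elbow_items else None,
            "elbow_participants": (self.elbow_participants.to_dict()
                                   if self.elbow_participants else None),
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def rank_select(
    grid: pd.DataFrame,
    methods: tuple[str, ...] = ("hca", "kmeans"),
    metrics: tuple[str, ...] = ("silhouette", "bt_ratio"),
) -> SelectionResult:
    """Pick the (k_i, k_p) cell with the lowest mean rank.

    Each (method, metric) column is ranked across cells (rank 1 = best,
    both metrics maximize; average ranks on ties); the winner minimizes
    the mean rank over the selected columns, ties broken toward smaller
    k_i then smaller k_p.  NaN cells are excluded from ranking with a
    warning.  PAM columns, if present, are reported but not ranked by
    default (k-means is the paper-grade partitioner in this step).
    """
    use_cols = [(m, s) for m in methods for s in metrics if (m, s) in grid.columns]
    if not use_cols:
        raise ValueError("no rankable columns in grid")
    warnings: list[str] = []
    ranks = pd.DataFrame(index=grid.index)
    for col in use_cols:
        series = grid[col]
        if series.isna().any():
            warnings.append(f"NaN cells excluded from ranking in {col}")
            logger.warning("NaN cells excluded from ranking in %s", col)
        ranks[f"{col[0]}.{col[1]}"] = series.rank(ascending=False, method="average")
    ranks["mean_rank"] = ranks.mean(axis=1, skipna=True)
    best_rank = ranks["mean_rank"].min()
    tied = [idx for idx in ranks.index
            if ranks.loc[idx, "mean_rank"] <= best_rank + 1e-12]
    k_i, k_p = sorted(tied)[0]
    region = (sorted({ki for ki, _ in grid.index}),
              sorted({kp for _, kp in grid.index}))
    return SelectionResult(int(k_i), int(k_p), region, grid, ranks,
                           warnings=warnings)


def select_cluster_numbers(
    bm: BinaryMatrix,
    seed: int = 0,
    dialect: str = "ward_d2",
    elbow_range=range(2, 21),
    ki_range=range(3, 11),
    kp_range=range(3, 11),
    region_ki=range(3, 6),
    region_kp=range(3, 6),
    standardize: bool = False,
    kmeans_n_init: int = 10,
    include_pam: bool = True,
) -> SelectionResult:
    """Run the full three-step selection and return the audited result."""
    inputs = prepare_inputs(bm, dialect)
    elbow_items = elbow_scan(inputs.item_dendro, inputs.item_dm, elbow_range)
    elbow_parts = elbow_scan(inputs.part_dendro, inputs.part_dm, elbow_range)
    sil_grids = silhouette_grid(inputs, ki_range, kp_range, seed=seed)
    grid = quality_grid(inputs, region_ki, region_kp, seed=seed,
                        standardize=standardize, kmeans_n_init=kmeans_n_init,
                        include_pam=include_pam)
    result = rank_select(grid)
    result.elbow_items = elbow_items
    result.elbow_participants = elbow_parts
    result.silhouette_grids = sil_grids
    if inputs.item_dendro.n_inversions or inputs.part_dendro.n_inversions:
        result.warnings.append(
            f"dendrogram height inversions: items={inputs.item_dendro.n_inversions}, "
            f"participants={inputs.part_dendro.n_inversions}"
        )
    return result
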