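"""Binary dissimilarity matrices.

Two complementary treatments of 0/0 pairs drive the two clustering
tiers.  For items, joint absence of two symptoms says nothing about
their affinity, so co-occurrence is scored asymmetrically with the
Jaccard distance (b+c)/(a+b+c).  For participants, agreeing on the
absence of a symptom is as informative as agreeing on its presence, so
rows are compared with the simple matching distance (b+c)/(a+b+c+d),
i.e. the normalized Hamming distance.  Here a,b,c,d count the (1,1),
(1,0), (0,1), (0,0) coordinate pairs of the two binary vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .preprocess import BinaryMatrix

logger = logging.getLogger(__name__)

_METRICS = ("jaccard", "simple_matching", "euclidean")


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with entity labels."""

    labels: list
    values: np.ndarray
    metric_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if n == 0:
            raise ValueError("empty distance matrix")
        if np.isnan(self.values).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(self.values)).max() > 1e-12:
            raise ValueError("nonzero diagonal")
        if self.metric_tag not in _METRICS:
            raise ValueError(f"metric_tag must be one of {_METRICS}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _binary_vectors(bm: BinaryMatrix, axis: str) -> tuple[np.ndarray, list]:
    x = bm.values()
    if axis == "items":
        return x.T.astype(np.float64), list(bm.data.columns)
    if axis == "participants":
        return x.astype(np.float64), list(bm.data.index)
    raise ValueError(f"axis must be 'items' or 'participants', got {axis!r}")


def jaccard_distances(bm: BinaryMatrix, axis: str = "items") -> DistanceMatrix:
    """Pairwise Jaccard distances (b+c)/(a+b+c) between rows of one margin.

    A pair of all-zero vectors has an empty union; the distance is
    defined as 0 (identical absence) with a warning, since such entities
    should be screened out upstream.
    """
    v, labels = _binary_vectors(bm, axis)
    if v.shape[0] < 2:
        raise ValueError("need at least two entities for a distance matrix")
    a = v @ v.T                      # co-endorsement counts
    s = v.sum(axis=1)
    union = s[:, None] + s[None, :] - a
    degenerate = union <= 0
    if degenerate.sum() > len(labels):  # off-diagonal all-zero pairs
        logger.warning("Jaccard distance on all-zero vector pair(s) defined as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(degenerate, 0.0, (union - a) / np.where(degenerate, 1.0, union))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float jitter
    return DistanceMatrix(labels, d, "jaccard")


def simple_matching_distances(
    bm: BinaryMatrix, axis: str = "participants"
) -> DistanceMatrix:
    """Pairwise simple matching distances: disagreement count / vector length."""
    v, labels = _binary_vectors(bm, axis)
    if v.shape[0] < 2:
        raise ValueError("need at least two entities for a distance matrix")
    p = v.shape[1]
    a = v @ v.T
    s = v.sum(axis=1)
    d = (s[:, None] + s[None, :] - 2.0 * a) / p
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels, d, "simple_matching")


def euclidean_distances(x, labels=None) -> DistanceMatrix:
    """Euclidean distance matrix for numeric rows (e.g. cluster-score space)."""
    arr = np.asarray(getattr(x, "to_numpy", lambda: x)(), dtype=float)
    if labels is None:
        labels = list(getattr(x, "index", range(arr.shape[0])))
    return DistanceMatrix(labels, squareform(pdist(arr)), "euclidean")
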