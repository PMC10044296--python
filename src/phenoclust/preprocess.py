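"""Response tables, missing-value imputation, and dichotomization.

Raw questionnaire responses are ordinal (0-3 Likert codes) with sporadic
missingness (~1.5% of cells in population cohorts of this kind).  The
pipeline imputes each missing cell as the mode of ``m`` stochastic draws
from the empirical response distribution of that item among the
participant's nearest neighbours, then dichotomizes: 0 stays 0 ("no
complaints"), any of 1-3 becomes 1 ("symptom endorsed").  All downstream
clustering operates on the resulting 0/1 endorsement matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ImputationError, SchemaError
from .instruments import ItemDescriptor, item_ids

logger = logging.getLogger(__name__)

NA_TOKENS = ("", "NA", ".")
ORDINAL_CODES = (0, 1, 2, 3)


@dataclass
class ResponseMatrix:
    """Participants x items ordinal response table.

    ``data`` is a float DataFrame indexed by participant id with one
    column per registered item; missing cells are NaN, observed cells are
    codes in {0,1,2,3}.
    """

    data: pd.DataFrame
    items: list[ItemDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.items and list(self.data.columns) != item_ids(self.items):
            raise SchemaError("column order does not match the item registry")
        vals = self.data.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if observed.size and not np.isin(observed, ORDINAL_CODES).all():
            bad = observed[~np.isin(observed, ORDINAL_CODES)][0]
            raise ValueError(f"response code {bad!r} outside {{0,1,2,3}}")
        if self.data.index.has_duplicates:
            raise SchemaError("duplicate participant ids")

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def is_complete(self) -> bool:
        return not self.data.isna().any().any()

    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())


@dataclass
class BinaryMatrix:
    """Participants x items 0/1 endorsement table (complete, no missing)."""

    data: pd.DataFrame
    items: list[ItemDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.items and list(self.data.columns) != item_ids(self.items):
            raise SchemaError("column order does not match the item registry")
        vals = self.data.to_numpy()
        if np.isnan(vals.astype(float)).any():
            raise ValueError("BinaryMatrix cannot contain missing cells")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryMatrix values must be 0 or 1")
        self.data = self.data.astype(np.int8)

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)


def read_responses(
    path,
    registry: list[ItemDescriptor],
    id_column: str = "pid",
    sep: str | None = None,
) -> ResponseMatrix:
    """Read a delimited response table into a :class:`ResponseMatrix`.

    The file needs a header row with ``id_column`` plus one column per
    registered item (extra columns are ignored); blank cells and the
    tokens ``NA`` / ``.`` are treated as missing.  The delimiter is
    sniffed unless ``sep`` is given.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        na_values=list(NA_TOKENS),
        keep_default_na=False,
        dtype=str,
    )
    if id_column not in df.columns:
        raise SchemaError(f"missing participant-id column {id_column!r}")
    wanted = item_ids(registry)
    absent = [c for c in wanted if c not in df.columns]
    if absent:
        raise SchemaError(f"missing registered item column(s): {absent}")
    df = df.set_index(id_column)[wanted]
    out = pd.DataFrame(index=df.index.copy(), columns=wanted, dtype=float)
    for col in wanted:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            row = raw.index[bad][0]
            raise ValueError(
                f"non-numeric value {raw[bad].iloc[0]!r} at row {row!r}, column {col!r}"
            )
        oob = num.notna() & ~num.isin(ORDINAL_CODES)
        if oob.any():
            row = num.index[oob][0]
            raise ValueError(
                f"value {num[oob].iloc[0]:g} outside {{0,1,2,3}} at row {row!r}, "
                f"column {col!r}"
            )
        out[col] = num
    return ResponseMatrix(out, list(registry))


def _mode_smallest(draws: np.ndarray) -> int:
    # np.bincount + argmax returns the smallest code on ties, which is the
    # documented tie-break (conservative toward non-endorsement).
    return int(np.bincount(draws.astype(int), minlength=4).argmax())


def impute_mode_of_m(
    rm: ResponseMatrix,
    m: int = 5,
    seed: int = 0,
    n_donors: int = 10,
) -> ResponseMatrix:
    """Fill missing cells with the mode of ``m`` stochastic draws.

    For each missing cell, draws come from the observed ordinal values of
    that item among the participant's ``n_donors`` nearest neighbours
    (Hamming distance on the binary-coded items observed in both rows);
    if no neighbour information exists the item's marginal distribution is
    used.  The per-cell mode of the ``m`` draws is imputed, ties broken
    toward the smaller code.  Deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    vals = rm.data.to_numpy(dtype=float).copy()
    n, p = vals.shape
    missing = np.isnan(vals)
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        col = rm.data.columns[int(np.flatnonzero(fully_missing)[0])]
        raise ImputationError(f"item column {col!r} is fully missing; cannot impute")
    if not missing.any():
        return ResponseMatrix(rm.data.copy(), list(rm.items))

    rng = np.random.default_rng(seed)
    observed = ~missing
    binary = np.where(observed, (vals >= 1).astype(float), np.nan)
    filled = vals.copy()
    for i in np.flatnonzero(missing.any(axis=1)):
        shared = observed[i] & observed  # (n, p) columns observed in both rows
        n_shared = shared.sum(axis=1)
        mismatch = shared & (binary != binary[i])
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(n_shared > 0, mismatch.sum(axis=1) / n_shared, np.inf)
        dist[i] = np.inf
        order = np.argsort(dist, kind="stable")
        for j in np.flatnonzero(missing[i]):
            donors = order[observed[order, j] & np.isfinite(dist[order])][:n_donors]
            pool = vals[donors, j] if donors.size else vals[observed[:, j], j]
            draws = rng.choice(pool, size=m, replace=True)
            filled[i, j] = _mode_smallest(draws)
    out = pd.DataFrame(filled, index=rm.data.index.copy(), columns=rm.data.columns)
    return ResponseMatrix(out, list(rm.items))


def binarize(rm: ResponseMatrix) -> BinaryMatrix:
    """Dichotomize a complete ordinal table: 0 -> 0, codes 1-3 -> 1."""
    if not rm.is_complete():
        raise ValueError(
            f"{rm.n_missing()} missing cell(s); run impute_mode_of_m before binarize"
        )
    binary = (rm.data.to_numpy(dtype=float) >= 1).astype(np.int8)
    out = pd.DataFrame(binary, index=rm.data.index.copy(), columns=rm.data.columns)
    return BinaryMatrix(out, list(rm.items))


def screen_items(bm: BinaryMatrix, min_endorsement: int = 1) -> BinaryMatrix:
    """Drop items endorsed by fewer than ``min_endorsement`` participants.

    All-zero items carry no co-occurrence information and make the
    asymmetric (Jaccard) item distance degenerate; they are screened out
    before item clustering.
    """
    counts = bm.data.sum(axis=0)
    keep = counts >= min_endorsement
    if keep.all():
        return bm
    dropped = list(counts.index[~keep])
    logger.warning("screening out %d item(s) below min endorsement: %s",
                   len(dropped), dropped)
    kept_ids = set(counts.index[keep])
    items = [d for d in bm.items if d.item_id in kept_ids] if bm.items else []
    return BinaryMatrix(bm.data.loc[:, keep].copy(), items)
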