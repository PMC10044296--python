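"""Gaussian finite mixtures with structured covariances and BIC selection.

For the diagnosed subsample, aggregated symptom-cluster scores are
approximately continuous and multimodal, so participants are grouped by
EM-fitted Gaussian mixtures.  Six covariance structures are supported in
the usual volume/shape code scheme on diagonal and full matrices:

======  =============================  ==========================
code    covariance                     free covariance parameters
======  =============================  ==========================
EII     shared spherical               1
VII     per-component spherical        k
EEI     shared diagonal                d
VVI     per-component diagonal         k d
EEE     shared full                    d (d + 1) / 2
VVV     per-component full             k d (d + 1) / 2
======  =============================  ==========================

Model choice maximizes BIC in the form ``2 loglik - n_params ln(n)``
(the convention of the model-based clustering literature this analysis
follows, where the "best" BIC is the largest); many texts minimize the
negated form, so the sign convention is stated here once and used
consistently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRUCTURES = ("EII", "VII", "EEI", "VVI", "EEE", "VVV")
_EIG_FLOOR = 1e-6


def n_covariance_params(structure: str, k: int, d: int) -> int:
    return {
        "EII": 1,
        "VII": k,
        "EEI": d,
        "VVI": k * d,
        "EEE": d * (d + 1) // 2,
        "VVV": k * d * (d + 1) // 2,
    }[structure]


def n_free_params(structure: str, k: int, d: int) -> int:
    """Mixture weights (k-1) + means (k d) + covariance parameters."""
    return (k - 1) + k * d + n_covariance_params(structure, k, d)


@dataclass
class GmmModel:
    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray  # (k, d, d)
    structure: str
    loglik: float
    n_params: int
    converged: bool = True
    n_iter: int = 0
    loglik_path: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if self.n_params != n_free_params(self.structure, self.k,
                                          self.means.shape[1]):
            raise ValueError("n_params inconsistent with structure")

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def bic(self, n: int) -> float:
        return 2.0 * self.loglik - self.n_params * np.log(n)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "structure": self.structure,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "converged": self.converged,
        }


def _floor_spd(cov: np.ndarray) -> np.ndarray:
    """Eigenvalue floor keeping the matrix symmetric positive definite."""
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, _EIG_FLOOR)
    return (vecs * vals) @ vecs.T


def _log_gaussian(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _m_step_cov(
    x: np.ndarray, resp: np.ndarray, means: np.ndarray, structure: str
) -> np.ndarray:
    n, d = x.shape
    k = means.shape[0]
    nk = resp.sum(axis=0)
    covs = np.empty((k, d, d))
    if structure in ("VVV", "EEE"):
        scatters = np.empty((k, d, d))
        for c in range(k):
            diff = x - means[c]
            scatters[c] = (resp[:, c][:, None] * diff).T @ diff
        if structure == "VVV":
            for c in range(k):
                covs[c] = _floor_spd(scatters[c] / nk[c])
        else:
            shared = _floor_spd(scatters.sum(axis=0) / n)
            covs[:] = shared
    else:
        # diagonal families: per-component weighted variances
        var = np.empty((k, d))
        for c in range(k):
            diff = x - means[c]
            var[c] = (resp[:, c][:, None] * diff**2).sum(axis=0) / nk[c]
        if structure == "VVI":
            diag = var
        elif structure == "EEI":
            diag = np.tile((var * nk[:, None]).sum(axis=0) / n, (k, 1))
        elif structure == "VII":
            diag = np.tile(var.mean(axis=1)[:, None], (1, d))
        elif structure == "EII":
            lam = float((var * nk[:, None]).sum() / (n * d))
            diag = np.full((k, d), lam)
        else:  # pragma: no cover
            raise ValueError(structure)
        diag = np.maximum(diag, _EIG_FLOOR)
        for c in range(k):
            covs[c] = np.diag(diag[c])
    return covs


def _init_means(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    from .partition import _kmeans_pp_init

    return _kmeans_pp_init(x, k, rng)


def fit_em(
    x,
    k: int,
    structure: str = "VVV",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 10,
) -> GmmModel:
    """Fit a k-component Gaussian mixture by EM, best of ``n_init`` restarts.

    Each restart initializes component means by k-means++ over the data,
    covariances at the pooled (structured) estimate, and weights uniform.
    Convergence is a relative log-likelihood change below ``tol``.
    Non-convergence is reported on the model, not raised; a restart whose
    E-step degenerates is abandoned and retried, with an error only if
    every restart fails.
    """
    x = np.asarray(getattr(x, "to_numpy", lambda: x)(), dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if structure not in STRUCTURES:
        raise ValueError(f"structure must be one of {STRUCTURES}")
    if n <= k * d:
        raise ValueError(f"need n > k*d ({k * d}), got n={n}")

    rng = np.random.default_rng(seed)
    best: GmmModel | None = None
    failures = 0
    for _ in range(n_init):
        try:
            model = _fit_once(x, k, structure, rng, tol, max_iter)
        except np.linalg.LinAlgError:
            failures += 1
            continue
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise RuntimeError(
            f"all {n_init} EM restarts failed for k={k}, structure={structure}"
        )
    if failures:
        logger.debug("%d/%d EM restarts failed", failures, n_init)
    return best


def _fit_once(x, k, structure, rng, tol, max_iter) -> GmmModel:
    n, d = x.shape
    means = _init_means(x, k, rng)
    resp = np.full((n, k), 1.0 / k)
    # initial hard assignment to nearest seed, then one M-step
    d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    hard = d2.argmin(axis=1)
    resp = np.full((n, k), 1e-6)
    resp[np.arange(n), hard] = 1.0
    resp /= resp.sum(axis=1, keepdims=True)

    loglik_path: list[float] = []
    prev = -np.inf
    converged = False
    weights = np.full(k, 1.0 / k)
    covs = None
    for it in range(max_iter):
        nk = resp.sum(axis=0)
        if (nk < 1e-8).any():
            raise np.linalg.LinAlgError("empty component")
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        covs = _m_step_cov(x, resp, means, structure)

        logp = np.empty((n, k))
        for c in range(k):
            logp[:, c] = np.log(weights[c]) + _log_gaussian(x, means[c], covs[c])
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        loglik = float(lse.sum())
        loglik_path.append(loglik)
        resp = np.exp(logp - lse[:, None])
        if it > 0 and abs(loglik - prev) <= tol * (abs(prev) + 1e-12):
            converged = True
            break
        prev = loglik
    return GmmModel(
        k=k, weights=weights, means=means, covariances=covs,
        structure=structure, loglik=loglik_path[-1],
        n_params=n_free_params(structure, k, d), converged=converged,
        n_iter=len(loglik_path), loglik_path=loglik_path,
    )


@dataclass
class BICTable:
    table: pd.DataFrame  # columns: k, structure, loglik, n_params, bic, converged
    best: tuple[int, str]
    models: dict[tuple[int, str], GmmModel] = field(repr=False, default_factory=dict)

    @property
    def best_model(self) -> GmmModel:
        return self.models[self.best]


def select_by_bic(
    x,
    k_range=range(1, 10),
    structures: tuple[str, ...] = STRUCTURES,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> BICTable:
    """Fit every (k, structure) combination and pick the max-BIC model.

    Only converged fits compete for ``best``; exact BIC ties go to the
    model with fewer free parameters.  Raises if nothing converges.
    """
    x_arr = np.asarray(getattr(x, "to_numpy", lambda: x)(), dtype=float)
    if x_arr.ndim == 1:
        x_arr = x_arr[:, None]
    n = x_arr.shape[0]
    rows = []
    models: dict[tuple[int, str], GmmModel] = {}
    rng = np.random.default_rng(seed)
    for structure in structures:
        for k in k_range:
            sub_seed = int(rng.integers(2**31))
            try:
                model = fit_em(x_arr, k, structure, seed=sub_seed, tol=tol,
                               max_iter=max_iter, n_init=n_init)
            except (RuntimeError, ValueError) as exc:
                logger.warning("fit failed for k=%d %s: %s", k, structure, exc)
                continue
            models[(k, structure)] = model
            rows.append(
                {"k": k, "structure": structure, "loglik": model.loglik,
                 "n_params": model.n_params, "bic": model.bic(n),
                 "converged": model.converged}
            )
    if not rows:
        raise RuntimeError("no (k, structure) fit succeeded")
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no fit converged")
    best_row = ok.sort_values(
        ["bic", "n_params"], ascending=[False, True], kind="stable"
    ).iloc[0]
    best = (int(best_row["k"]), str(best_row["structure"]))
    return BICTable(table, best, models)


def classify(model: GmmModel, x) -> tuple[np.ndarray, np.ndarray]:
    """Posterior responsibilities and hard (argmax) component labels (1-based)."""
    x = np.asarray(getattr(x, "to_numpy", lambda: x)(), dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != model.d:
        raise ValueError(f"data has {x.shape[1]} columns, model expects {model.d}")
    logp = np.empty((x.shape[0], model.k))
    for c in range(model.k):
        logp[:, c] = np.log(model.weights[c]) + _log_gaussian(
            x, model.means[c], model.covariances[c]
        )
    m = logp.max(axis=1, keepdims=True)
    resp = np.exp(logp - m)
    resp /= resp.sum(axis=1, keepdims=True)
    return resp, resp.argmax(axis=1) + 1


def crosstab(hard_labels: np.ndarray, external: pd.Series | np.ndarray) -> pd.DataFrame:
    """Cluster x external-label contingency table (e.g. against diagnosis)."""
    return pd.crosstab(
        pd.Series(hard_labels, name="cluster"),
        pd.Series(np.asarray(external), name="label"),
    )


def undersample_majority(labels, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subsample (majority classes thinned).

    Draws without replacement from each over-represented class down to
    the minority count; deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    m = counts.min()
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        keep.append(np.sort(rng.choice(idx, size=m, replace=False)))
    return np.sort(np.concatenate(keep))
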