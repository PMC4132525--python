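"""Household SEP scores: Mokken sum score and polychoric-PCA index.

The Mokken score is the unweighted sum of the retained dichotomous
items — the quantity the monotone homogeneity model licenses for
ordering households.  The contrasting index is the first principal
component of the tetrachoric (2x2 polychoric) correlation matrix of
the items, scored with Filmer-Pritchett standardisation
(centre each item by its popularity p_i, scale by the Bernoulli SD
sqrt(p_i (1 - p_i))).

Quintile boundaries follow the empirical CDF: the boundary for
quintile q is the smallest score s with CDF(s) >= q/5, and households
sharing a score always share a quintile — with discrete sum scores the
five groups are therefore only approximately equal in size.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import owens_t

from .exceptions import ConfigurationError, DegenerateDataError
from .scalability import ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WealthIndex",
    "PCAResult",
    "TetrachoricEstimate",
    "mokken_score",
    "quintile_assign",
    "tetrachoric_rho",
    "polychoric_matrix",
    "pca_first_component",
    "pca_scores",
]

_RHO_CLIP = 1.0 - 1e-6


@dataclass(frozen=True)
class WealthIndex:
    """Per-household SEP score and quintile under one method."""

    method: str  # "mokken_sum" or "pca"
    score: np.ndarray
    quintile: np.ndarray
    items: tuple[str, ...]

    def to_frame(self, household_ids=None) -> pd.DataFrame:
        ids = household_ids if household_ids is not None else range(len(self.score))
        return pd.DataFrame(
            {
                "household_id": list(ids),
                "method": self.method,
                "score": self.score,
                "quintile": self.quintile,
            }
        )


@dataclass(frozen=True)
class PCAResult:
    loadings: np.ndarray  # first component, sign-normalised (sum > 0)
    eigenvalues: np.ndarray  # descending
    variance_proportions: np.ndarray

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_proportions": self.variance_proportions.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class TetrachoricEstimate:
    rho: float
    thresholds: tuple[float, float]
    converged: bool
    loglik: float
    clipped: bool = False
    corrected: bool = False  # +0.5 continuity correction applied


def mokken_score(matrix: ResponseMatrix, items) -> WealthIndex:
    """Unweighted sum score over the given items, with quintiles."""
    items = list(items)
    if not items:
        raise ConfigurationError("item set must be non-empty")
    scores = matrix.values[:, items].sum(axis=1).astype(float)
    return WealthIndex(
        method="mokken_sum",
        score=scores,
        quintile=quintile_assign(scores),
        items=tuple(matrix.item_labels[i] for i in items),
    )


def quintile_assign(scores) -> np.ndarray:
    """Quintile labels 1 (poorest) to 5 with tie-respecting boundaries.

    The boundary for quintile q is the smallest score whose empirical
    CDF reaches q/5; a household falls in quintile 1 + (number of
    boundaries strictly below its score).  Requires n >= 5 and at
    least two distinct scores.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 5:
        raise DegenerateDataError("quintile assignment needs at least 5 households")
    values, counts = np.unique(scores, return_counts=True)
    if len(values) < 2:
        raise DegenerateDataError("constant scores: quintiles undefined")
    cum = counts.cumsum()
    bounds = []
    for q in range(1, 5):
        # CDF(s) >= q/5  <=>  5 * cum >= q * n (exact integer arithmetic)
        idx = int(np.searchsorted(5 * cum, q * n, side="left"))
        bounds.append(values[idx])
    labels = 1 + np.searchsorted(np.asarray(bounds), scores, side="left")
    return labels.astype(np.int64)


# ---------------------------------------------------------------------------
# tetrachoric correlation


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal, via Owen's T."""
    rho = float(np.clip(rho, -_RHO_CLIP, _RHO_CLIP))
    if abs(h) < 1e-12 and abs(k) < 1e-12:
        return 0.25 + np.arcsin(rho) / (2.0 * np.pi)
    # nudge exact zeros so the Owen's T decomposition is well defined
    if abs(h) < 1e-12:
        h = 1e-12
    if abs(k) < 1e-12:
        k = 1e-12
    denom = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    beta = 0.5 if h * k < 0 else 0.0
    return float(
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - owens_t(h, ah)
        - owens_t(k, ak)
        - beta
    )


def _cell_probs(tau_i: float, tau_j: float, rho: float) -> np.ndarray:
    """2x2 cell probabilities (order n00, n01, n10, n11) under the
    bivariate-normal model with X=1 iff latent > tau."""
    p00 = _bvn_cdf(tau_i, tau_j, rho)
    ci = stats.norm.cdf(tau_i)
    cj = stats.norm.cdf(tau_j)
    probs = np.array([p00, ci - p00, cj - p00, 1.0 - ci - cj + p00])
    return np.clip(probs, 1e-300, 1.0)


def tetrachoric_rho(table, config: dict | None = None) -> TetrachoricEstimate:
    """Two-step ML tetrachoric correlation from a 2x2 count table.

    ``table[a, b]`` counts households with X_i = a, X_j = b.  Thresholds
    come from the inverse-normal of the margins; rho then maximises the
    multinomial likelihood under bivariate-normal orthant probabilities.
    A zero cell triggers a +0.5 continuity correction on all four cells
    (logged); a zero margin is an error.
    """
    del config  # reserved for future tolerances
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ConfigurationError("table must be a nonnegative 2x2 count array")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero margin: tetrachoric rho undefined")
    corrected = False
    if (table == 0).any():
        logger.info("tetrachoric: zero cell, +0.5 continuity correction applied")
        table = table + 0.5
        corrected = True
    n = table.sum()
    # X=1 iff latent > tau, so P(X=0) = Phi(tau)
    tau_i = stats.norm.ppf(table[0, :].sum() / n)
    tau_j = stats.norm.ppf(table[:, 0].sum() / n)
    counts = np.array([table[0, 0], table[0, 1], table[1, 0], table[1, 1]])

    def nll(rho: float) -> float:
        return -float(counts @ np.log(_cell_probs(tau_i, tau_j, rho)))

    res = optimize.minimize_scalar(
        nll, bounds=(-_RHO_CLIP, _RHO_CLIP), method="bounded",
        options={"xatol": 1e-10},
    )
    rho = float(res.x)
    clipped = abs(rho) >= _RHO_CLIP - 1e-9
    if clipped:
        logger.info("tetrachoric: rho clipped at +/-%.6f", _RHO_CLIP)
    if not res.success:
        logger.warning("tetrachoric: optimiser did not converge, best point kept")
    return TetrachoricEstimate(
        rho=rho,
        thresholds=(float(tau_i), float(tau_j)),
        converged=bool(res.success),
        loglik=-float(res.fun),
        clipped=clipped,
        corrected=corrected,
    )


def polychoric_matrix(matrix: ResponseMatrix) -> np.ndarray:
    """Pairwise tetrachoric correlation matrix of all items.

    Symmetric with unit diagonal.  If the pairwise-assembled matrix is
    not positive semi-definite it is repaired by clipping eigenvalues
    at 1e-8 and rescaling to unit diagonal (logged).
    """
    X = matrix.values.astype(np.int64)
    n, k = matrix.n, matrix.k
    s = X.sum(axis=0)
    J = X.T @ X
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            n11 = int(J[i, j])
            n10 = int(s[i]) - n11
            n01 = int(s[j]) - n11
            n00 = n - n11 - n10 - n01
            est = tetrachoric_rho([[n00, n01], [n10, n11]])
            R[i, j] = R[j, i] = est.rho
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < 1e-8:
        logger.info(
            "polychoric matrix not PSD (min eigenvalue %.3g); repairing", eigvals.min()
        )
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 1e-8, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
    return R


def pca_first_component(corr: np.ndarray) -> PCAResult:
    """Eigendecomposition of a correlation matrix; first component kept.

    Variance proportion of component m is eigenvalue_m / k (the trace
    of a correlation matrix).  First-component loadings are sign-flipped
    so their sum is positive ("higher = wealthier").
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ConfigurationError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ConfigurationError("correlation matrix must be symmetric")
    k = corr.shape[0]
    w, V = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    loadings = V[:, 0].copy()
    ssum = loadings.sum()
    if ssum < 0:
        loadings = -loadings
    elif ssum == 0:  # pragma: no cover - measure-zero tie
        logger.warning("first-component loading sum is 0; sign left as computed")
    return PCAResult(
        loadings=loadings,
        eigenvalues=w,
        variance_proportions=w / k,
    )


def pca_scores(matrix: ResponseMatrix, pca: PCAResult) -> WealthIndex:
    """First-component index with Filmer-Pritchett standardisation:
    score_h = sum_i loading_i * (x_hi - p_i) / sqrt(p_i (1 - p_i))."""
    if len(pca.loadings) != matrix.k:
        raise ConfigurationError("loadings length does not match item count")
    p = matrix.popularity
    Z = (matrix.values - p) / np.sqrt(p * (1.0 - p))
    scores = Z @ pca.loadings
    return WealthIndex(
        method="pca",
        score=scores,
        quintile=quintile_assign(scores),
        items=matrix.item_labels,
    )
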