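"""Loevinger scalability coefficients for dichotomous item banks.

The central quantities of Mokken scale analysis.  For a pair of binary
items, designate the less popular item the "harder" one.  A Guttman
error is a household owning the harder item while lacking the easier
one.  With ``F_ij`` the observed number of such errors and ``E_ij`` the
number expected were the two items independent,

    H_ij = 1 - F_ij / E_ij

which equals ``cov(X_i, X_j) / (p_h (1 - p_e))`` with population
(1/n) covariances.  Item coefficients ``H_i`` and the scale coefficient
``H`` are one minus the corresponding ratios of summed errors.  ``H``
computed on the transposed response matrix (households as items)
summarises how accurately the item ordering holds across households.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseMatrix",
    "ItemStats",
    "PairScalability",
    "ScalabilityReport",
    "item_popularity",
    "compute_scalability",
    "se_item_H",
    "transposed_H",
    "strength_label",
]


def strength_label(h: float) -> str:
    """Conventional interpretation bands for H coefficients.

    Below .3 an item/scale is considered unscalable; .3-.4 weak,
    .4-.5 medium, above .5 strong.
    """
    if h < 0.3:
        return "unscalable"
    if h < 0.4:
        return "weak"
    if h < 0.5:
        return "medium"
    return "strong"


@dataclass(frozen=True)
class ResponseMatrix:
    """Complete-case households x binary items response matrix.

    Invariants enforced at construction: entries in {0, 1} with no
    missing values, at least 2 households and 2 items, and every item
    popularity strictly inside (0, 1) — constant items carry no ordering
    information and make H undefined, so they are rejected here rather
    than downstream.
    """

    values: np.ndarray
    item_labels: tuple[str, ...] = ()
    household_ids: tuple = ()

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise DegenerateDataError("response matrix must be 2-dimensional")
        if np.isnan(arr.astype(float)).any():
            raise DegenerateDataError("response matrix contains missing values")
        uniq = np.unique(arr)
        if not np.isin(uniq, [0, 1]).all():
            raise DegenerateDataError(
                f"response matrix entries must be 0/1, found {uniq[:5]}"
            )
        arr = arr.astype(np.int8)
        n, k = arr.shape
        if n < 2 or k < 2:
            raise DegenerateDataError(
                f"need at least 2 households and 2 items, got {n} x {k}"
            )
        labels = tuple(self.item_labels) or tuple(f"item_{i}" for i in range(k))
        if len(labels) != k:
            raise DegenerateDataError("item_labels length does not match columns")
        ids = tuple(self.household_ids) or tuple(range(n))
        if len(ids) != n:
            raise DegenerateDataError("household_ids length does not match rows")
        p = arr.mean(axis=0)
        const = np.where((p == 0.0) | (p == 1.0))[0]
        if const.size:
            names = [labels[i] for i in const]
            raise DegenerateDataError(
                f"constant item(s) rejected (popularity 0 or 1): {names}"
            )
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "item_labels", labels)
        object.__setattr__(self, "household_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def popularity(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def subset(self, items: Sequence[int]) -> "ResponseMatrix":
        """New matrix restricted to the given item indices (order kept)."""
        items = list(items)
        return ResponseMatrix(
            self.values[:, items],
            tuple(self.item_labels[i] for i in items),
            self.household_ids,
        )

    def label_indices(self, labels: Sequence[str]) -> list[int]:
        lut = {lab: i for i, lab in enumerate(self.item_labels)}
        return [lut[lab] for lab in labels]


@dataclass(frozen=True)
class ItemStats:
    """Item popularities and the popularity rank order.

    ``rank_by_popularity`` lists item indices from most to least popular;
    equal popularities rank by original column index.
    """

    popularity: np.ndarray
    rank_by_popularity: np.ndarray


@dataclass(frozen=True)
class PairScalability:
    i: int
    j: int
    F_ij: int
    E_ij: float
    H_ij: float


@dataclass
class ScalabilityReport:
    item_labels: tuple[str, ...]
    pair_table: list[PairScalability]
    Hij: np.ndarray
    item_H: np.ndarray
    item_H_se: np.ndarray | None
    scale_H: float
    transposed_H: float
    item_strength: tuple[str, ...] = ()
    scale_strength: str = ""
    popularity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def item_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "item": list(self.item_labels),
                "proportion": self.popularity,
                "H_i": self.item_H,
                "strength": list(self.item_strength),
            }
        )
        if self.item_H_se is not None:
            df["H_i_se"] = self.item_H_se
        return df

    def pair_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "item_i": self.item_labels[p.i],
                    "item_j": self.item_labels[p.j],
                    "F_ij": p.F_ij,
                    "E_ij": p.E_ij,
                    "H_ij": p.H_ij,
                }
                for p in self.pair_table
            ]
        )

    def to_dict(self) -> dict:
        d = {
            "scale_H": float(self.scale_H),
            "transposed_H": float(self.transposed_H)
            if np.isfinite(self.transposed_H)
            else None,
            "scale_strength": self.scale_strength,
            "items": self.item_frame().to_dict(orient="records"),
            "pairs": self.pair_frame().to_dict(orient="records"),
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# internal kernels operating on raw 0/1 arrays


def _pairwise_FE(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed (F) and independence-expected (E) Guttman error counts.

    Returns symmetric k x k arrays; diagonal is meaningless and set to 0.
    Harder item of a pair = lower popularity, ties to the lower index.
    """
    X = X.astype(np.int64, copy=False)
    n, k = X.shape
    s = X.sum(axis=0)
    J = X.T @ X
    idx = np.arange(k)
    # row item is the harder one of the pair?
    row_harder = (s[:, None] < s[None, :]) | (
        (s[:, None] == s[None, :]) & (idx[:, None] < idx[None, :])
    )
    F = np.where(row_harder, s[:, None] - J, s[None, :] - J).astype(np.float64)
    E = np.where(
        row_harder,
        s[:, None] * (n - s[None, :]),
        s[None, :] * (n - s[:, None]),
    ) / float(n)
    np.fill_diagonal(F, 0.0)
    np.fill_diagonal(E, 0.0)
    return F, E


def _item_H_from_FE(F: np.ndarray, E: np.ndarray) -> np.ndarray:
    return 1.0 - F.sum(axis=1) / E.sum(axis=1)


def _scale_H_from_FE(F: np.ndarray, E: np.ndarray) -> float:
    iu = np.triu_indices(F.shape[0], k=1)
    return float(1.0 - F[iu].sum() / E[iu].sum())


def _scale_H_raw(X: np.ndarray) -> float:
    F, E = _pairwise_FE(X)
    return _scale_H_from_FE(F, E)


# ---------------------------------------------------------------------------
# public operations


def item_popularity(matrix: ResponseMatrix) -> ItemStats:
    """Item popularities (column means) and descending popularity rank."""
    p = matrix.popularity
    rank = np.lexsort((np.arange(matrix.k), -p))
    return ItemStats(popularity=p, rank_by_popularity=rank)


def compute_scalability(
    matrix: ResponseMatrix,
    n_boot: int = 0,
    seed: int | None = None,
    include_transpose: bool = True,
) -> ScalabilityReport:
    """Full scalability report: H_ij, H_i (+bootstrap SE), H and H^T.

    ``n_boot > 0`` adds bootstrap standard errors for the H_i (see
    :func:`se_item_H`).  ``include_transpose=False`` skips H^T, which is
    quadratic in the number of households.
    """
    X = matrix.values
    F, E = _pairwise_FE(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        Hij = 1.0 - F / E
    np.fill_diagonal(Hij, 1.0)
    item_H = _item_H_from_FE(F, E)
    scale_H = _scale_H_from_FE(F, E)
    pairs = [
        PairScalability(i, j, int(F[i, j]), float(E[i, j]), float(Hij[i, j]))
        for i in range(matrix.k)
        for j in range(i + 1, matrix.k)
    ]
    se = None
    if n_boot:
        se = se_item_H(matrix, n_boot=n_boot, seed=0 if seed is None else seed)
    ht = float("nan")
    if include_transpose:
        try:
            ht = transposed_H(matrix)
        except DegenerateDataError as exc:  # pragma: no cover - unusual data
            logger.warning("transposed H unavailable: %s", exc)
    return ScalabilityReport(
        item_labels=matrix.item_labels,
        pair_table=pairs,
        Hij=Hij,
        item_H=item_H,
        item_H_se=se,
        scale_H=scale_H,
        transposed_H=ht,
        item_strength=tuple(strength_label(h) for h in item_H),
        scale_strength=strength_label(scale_H),
        popularity=matrix.popularity,
    )


def se_item_H(
    matrix: ResponseMatrix, n_boot: int = 1000, seed: int = 0
) -> np.ndarray:
    """Nonparametric bootstrap standard errors of the item H_i.

    Households are resampled with replacement; replicates in which any
    item becomes constant (H_i undefined) are dropped and logged.  More
    than 10% dropped replicates triggers a warning; zero usable
    replicates raises :class:`DegenerateDataError`.
    """
    if n_boot < 200:
        raise DegenerateDataError("n_boot must be at least 200 for stable SEs")
    X = matrix.values
    n = matrix.n
    rng = np.random.default_rng(seed)
    reps = []
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        sb = Xb.sum(axis=0)
        if ((sb == 0) | (sb == n)).any():
            dropped += 1
            continue
        F, E = _pairwise_FE(Xb)
        reps.append(_item_H_from_FE(F, E))
    if not reps:
        raise DegenerateDataError(
            "all bootstrap replicates degenerate; cannot estimate SEs"
        )
    if dropped:
        logger.info("bootstrap: dropped %d/%d degenerate replicates", dropped, n_boot)
    if dropped > 0.1 * n_boot:
        logger.warning(
            "bootstrap: %.1f%% of replicates dropped; SEs may be unreliable",
            100.0 * dropped / n_boot,
        )
    return np.std(np.vstack(reps), axis=0, ddof=1)


def transposed_H(matrix: ResponseMatrix) -> float:
    """Scale H of the transposed matrix (households as "items").

    Households with constant response vectors (all 0 or all 1) carry no
    ordering information as pseudo-items and are dropped with a log
    message, mirroring the constant-item rule.
    """
    Xt = matrix.values.T  # k x n: rows = items, columns = households
    col_sums = Xt.sum(axis=0)
    keep = (col_sums > 0) & (col_sums < matrix.k)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "transposed_H: dropped %d constant household row(s)", n_dropped
        )
    if keep.sum() < 2:
        raise DegenerateDataError(
            "fewer than 2 non-constant households; H^T undefined"
        )
    return _scale_H_raw(Xt[:, keep])
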