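"""Automated item selection procedure (AISP) for Mokken scales.

Sequential bottom-up partitioning of an item pool.  A scale is seeded
with the pair maximising H_ij among pairs whose H_ij is significantly
positive and at least the threshold c; items are then added one at a
time, each required to have a significantly positive H_ij with every
current member and an item coefficient H_i (within the enlarged scale)
of at least c, choosing the addition that maximises the scale H.  When
no item qualifies the scale is closed and a new one seeded from the
remainder; items never placed are unscalable.

Positivity of H_ij is tested by a seeded bootstrap percentile test
(reject when the alpha-quantile of bootstrap H_ij exceeds zero) —
resampling households for a single pair is equivalent to a multinomial
draw over the four response patterns, which is how it is implemented.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateDataError
from .scalability import (
    ResponseMatrix,
    ScalabilityReport,
    compute_scalability,
    _pairwise_FE,
)

logger = logging.getLogger(__name__)

__all__ = ["SelectionConfig", "ScalePartition", "significance_positive_Hij", "aisp"]


@dataclass(frozen=True)
class SelectionConfig:
    """AISP tuning: scalability lower bound ``c`` (conventional default
    .3), one-sided level ``alpha`` for the H_ij > 0 test, bootstrap
    replicate count and seed."""

    c: float = 0.3
    alpha: float = 0.05
    n_boot: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.c < 1.0:
            raise ConfigurationError("c must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_boot < 100:
            raise ConfigurationError("n_boot must be at least 100")


@dataclass
class ScalePartition:
    """AISP output: ordered scales, unscalable items, per-scale
    scalability reports and the full decision trail."""

    item_labels: tuple[str, ...]
    scales: list[list[int]]
    unscalable: list[int]
    reports: list[ScalabilityReport]
    selection_log: list[dict]

    def __post_init__(self):
        assigned = [i for s in self.scales for i in s] + list(self.unscalable)
        if sorted(assigned) != list(range(len(self.item_labels))):
            raise DegenerateDataError("scales + unscalable must partition the pool")
        for s in self.scales:
            if len(s) < 2:
                raise DegenerateDataError("every scale must contain >= 2 items")

    def scale_of(self, item: int) -> int | None:
        """1-based scale id of an item, None if unscalable."""
        for sid, s in enumerate(self.scales, start=1):
            if item in s:
                return sid
        return None

    def to_dict(self) -> dict:
        return {
            "scales": [
                {
                    "id": sid,
                    "items": [self.item_labels[i] for i in s],
                    "scale_H": self.reports[sid - 1].scale_H,
                }
                for sid, s in enumerate(self.scales, start=1)
            ],
            "unscalable": [self.item_labels[i] for i in self.unscalable],
            "selection_log": self.selection_log,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def item_table(self, popularity: np.ndarray, se: np.ndarray | None = None
                   ) -> pd.DataFrame:
        """Survey-report style table: label, proportion, scale id, H_i."""
        rows = []
        for i, lab in enumerate(self.item_labels):
            sid = self.scale_of(i)
            h_i = None
            if sid is not None:
                rep = self.reports[sid - 1]
                pos = self.scales[sid - 1].index(i)
                h_i = float(rep.item_H[pos])
            rows.append(
                {
                    "item": lab,
                    "proportion": float(popularity[i]),
                    "scale": sid if sid is not None else "-",
                    "H_i": h_i,
                }
            )
        df = pd.DataFrame(rows)
        if se is not None:
            df["H_i_se"] = se
        return df


def _pair_rng(config: SelectionConfig, i: int, j: int) -> np.random.Generator:
    lo, hi = (i, j) if i < j else (j, i)
    return np.random.default_rng(np.random.SeedSequence((config.seed, lo, hi)))


def _bootstrap_Hij(
    counts: np.ndarray, n: int, i: int, j: int, config: SelectionConfig
) -> np.ndarray:
    """Bootstrap replicates of H_ij from the pair's 2x2 pattern counts
    (order: n00, n01, n10, n11).  Degenerate replicates are dropped."""
    rng = _pair_rng(config, i, j)
    boots = rng.multinomial(n, counts / counts.sum(), size=config.n_boot)
    n01, n10, n11 = boots[:, 1], boots[:, 2], boots[:, 3]
    s_i = n10 + n11
    s_j = n01 + n11
    valid = (s_i > 0) & (s_i < n) & (s_j > 0) & (s_j < n)
    p_i, p_j, p_ij = s_i / n, s_j / n, n11 / n
    cov = p_ij - p_i * p_j
    # harder item: lower popularity, tie to lower index
    i_harder = (p_i < p_j) | ((p_i == p_j) & (i < j))
    denom = np.where(i_harder, p_i * (1.0 - p_j), p_j * (1.0 - p_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        H = cov / denom
    return H[valid]


def significance_positive_Hij(
    matrix: ResponseMatrix, i: int, j: int, config: SelectionConfig
) -> tuple[bool, float]:
    """One-sided bootstrap percentile test of H_ij > 0.

    Returns (significant, p_value) where the p-value is the bootstrap
    fraction of replicates with H_ij <= 0.  An entirely degenerate
    bootstrap is treated as non-significant and logged.
    """
    xi = matrix.values[:, i].astype(np.int64)
    xj = matrix.values[:, j].astype(np.int64)
    n11 = int((xi & xj).sum())
    n10 = int(xi.sum()) - n11
    n01 = int(xj.sum()) - n11
    n00 = matrix.n - n11 - n10 - n01
    counts = np.array([n00, n01, n10, n11], dtype=float)
    H = _bootstrap_Hij(counts, matrix.n, i, j, config)
    if H.size == 0:
        logger.info("pair (%d, %d): degenerate bootstrap, treated as ns", i, j)
        return False, 1.0
    p_value = float(np.mean(H <= 0.0))
    significant = bool(np.quantile(H, config.alpha) > 0.0)
    return significant, p_value


def _subset_H(F: np.ndarray, E: np.ndarray, members: list[int]) -> float:
    idx = np.ix_(members, members)
    iu = np.triu_indices(len(members), k=1)
    return float(1.0 - F[idx][iu].sum() / E[idx][iu].sum())


def _item_H_in_subset(
    F: np.ndarray, E: np.ndarray, item: int, others: list[int]
) -> float:
    return float(1.0 - F[item, others].sum() / E[item, others].sum())


def aisp(matrix: ResponseMatrix, config: SelectionConfig | None = None) -> ScalePartition:
    """Partition the item pool into zero or more Mokken scales.

    Deterministic given the matrix and config (bootstrap seeds are
    derived per item pair from ``config.seed``).  If no pair is both
    significantly positive and above c, all items are unscalable.
    """
    config = config or SelectionConfig()
    k = matrix.k
    if k < 2:
        raise DegenerateDataError("need at least 2 items")
    F, E = _pairwise_FE(matrix.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        Hij = 1.0 - F / E
    np.fill_diagonal(Hij, 1.0)

    sig = np.zeros((k, k), dtype=bool)
    pvals = np.ones((k, k))
    n_tests = 0
    for i in range(k):
        for j in range(i + 1, k):
            s, p = significance_positive_Hij(matrix, i, j, config)
            sig[i, j] = sig[j, i] = s
            pvals[i, j] = pvals[j, i] = p
            n_tests += 1
    logger.info("AISP: %d pairwise positivity tests (no multiplicity correction)",
                n_tests)

    unassigned = set(range(k))
    scales: list[list[int]] = []
    log: list[dict] = []

    while True:
        # (1) seed: best significant pair with H_ij >= c
        best_pair, best_h = None, -np.inf
        for i in sorted(unassigned):
            for j in sorted(unassigned):
                if j <= i:
                    continue
                if sig[i, j] and Hij[i, j] >= config.c:
                    if Hij[i, j] > best_h:
                        best_h, best_pair = Hij[i, j], (i, j)
        if best_pair is None:
            break
        scale = list(best_pair)
        log.append(
            {
                "action": "seed",
                "scale": len(scales) + 1,
                "items": [matrix.item_labels[x] for x in best_pair],
                "H_ij": float(best_h),
            }
        )
        # (2) grow
        while True:
            best = None  # (H_new, H_i, -index, item)
            for x in sorted(unassigned - set(scale)):
                if not all(sig[x, s] for s in scale):
                    continue
                h_x = _item_H_in_subset(F, E, x, scale)
                if h_x < config.c:
                    continue
                h_new = _subset_H(F, E, scale + [x])
                key = (h_new, h_x, -x)
                if best is None or key > best[0]:
                    best = (key, x, h_new, h_x)
            if best is None:
                break
            _, x, h_new, h_x = best
            scale.append(x)
            log.append(
                {
                    "action": "add",
                    "scale": len(scales) + 1,
                    "item": matrix.item_labels[x],
                    "H_i": float(h_x),
                    "scale_H": float(h_new),
                }
            )
        log.append(
            {
                "action": "close",
                "scale": len(scales) + 1,
                "items": [matrix.item_labels[x] for x in scale],
                "scale_H": float(_subset_H(F, E, scale)),
            }
        )
        scales.append(scale)
        unassigned -= set(scale)
        if len(unassigned) < 2:
            break

    unscalable = sorted(unassigned)
    for x in unscalable:
        log.append({"action": "unscalable", "item": matrix.item_labels[x]})
    reports = [compute_scalability(matrix.subset(s), include_transpose=False)
               for s in scales]
    return ScalePartition(
        item_labels=matrix.item_labels,
        scales=scales,
        unscalable=unscalable,
        reports=reports,
        selection_log=log,
    )
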