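"""Restscore checks of the Mokken model assumptions.

Monotonicity (the MMH): for each item, households are grouped by their
rest score — the sum over the other scale items — and the item's
ownership proportion must not decrease across increasing rest-score
groups.  Non-intersection / invariant item ordering (the DMM): for
every item pair, grouped on the rest score excluding both, the overall
harder item must nowhere be more popular than the easier one.

A *violation* is a reversal larger than ``minvi``; it is *critical*
when additionally statistically significant at ``alpha`` (two-proportion
z-test for monotonicity; an exact one-sided sign test on the pair's
discordant households within the group for IIO).  Iterative removal
drops the item with the most critical violations and re-checks, the
standard remedy when invariant item ordering fails.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError
from .scalability import ResponseMatrix, _pairwise_FE, _item_H_from_FE

logger = logging.getLogger(__name__)

__all__ = [
    "CheckConfig",
    "RestscoreTable",
    "ItemViolations",
    "ViolationReport",
    "restscore_groups",
    "check_monotonicity",
    "check_iio_restscore",
    "iterative_iio_removal",
]


@dataclass(frozen=True)
class CheckConfig:
    """Tuning constants for the restscore checks.

    ``minvi`` is the minimum reversal magnitude to count as a violation
    (default .03, the widely used restscore convention); ``minsize`` is
    the minimum rest-score group size — when None it defaults to n/10
    for n >= 500 and n/5 otherwise, never below 50; ``alpha`` is the
    significance level that upgrades a violation to critical.
    """

    minvi: float = 0.03
    minsize: int | None = None
    alpha: float = 0.05

    def __post_init__(self):
        if self.minvi < 0:
            raise ConfigurationError("minvi must be >= 0")
        if self.minsize is not None and self.minsize < 2:
            raise ConfigurationError("minsize must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")

    def resolve_minsize(self, n: int) -> int:
        if self.minsize is not None:
            return self.minsize
        return max(50, n // 10 if n >= 500 else n // 5)


@dataclass(frozen=True)
class RestscoreTable:
    """Rest-score grouping: per-household group assignment plus the
    rest-score range and size of each group (ordered by rest score)."""

    assignment: np.ndarray  # group index per household
    bounds: tuple[tuple[int, int], ...]  # (low, high) rest score per group
    sizes: tuple[int, ...]

    @property
    def n_groups(self) -> int:
        return len(self.sizes)


@dataclass
class ItemViolations:
    item: int
    label: str
    comparisons: int = 0
    violations: int = 0
    critical: int = 0
    max_violation: float = 0.0
    z_stats: list = field(default_factory=list)


@dataclass
class ViolationReport:
    check: str
    items: list[ItemViolations]
    worst_offender: int | None

    def by_item(self) -> dict[int, ItemViolations]:
        return {iv.item: iv for iv in self.items}

    def total_critical(self) -> int:
        # IIO tallies count each pair's violations on both items
        return sum(iv.critical for iv in self.items)

    def to_dict(self) -> dict:
        return {
            "check": self.check,
            "worst_offender": None
            if self.worst_offender is None
            else next(
                iv.label for iv in self.items if iv.item == self.worst_offender
            ),
            "items": [
                {
                    "item": iv.label,
                    "comparisons": iv.comparisons,
                    "violations": iv.violations,
                    "critical": iv.critical,
                    "max_violation": iv.max_violation,
                }
                for iv in self.items
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def restscore_groups(
    matrix: ResponseMatrix,
    excluded_items: set[int] | list[int],
    config: CheckConfig | None = None,
    scale_items: list[int] | None = None,
) -> RestscoreTable:
    """Group households by rest score over ``scale_items`` minus
    ``excluded_items``.

    Adjacent rest-score values are merged left to right (low to high)
    until each group reaches ``minsize``; an undersized final remainder
    is merged into the last closed group.  If n < 2*minsize a single
    group results, with a warning.
    """
    config = config or CheckConfig()
    excluded = set(excluded_items)
    scale = list(scale_items) if scale_items is not None else list(range(matrix.k))
    rest_items = [i for i in scale if i not in excluded]
    if len(rest_items) < 1:
        raise DegenerateDataError("no items left to form a rest score")
    R = matrix.values[:, rest_items].sum(axis=1).astype(np.int64)
    n = matrix.n
    minsize = config.resolve_minsize(n)
    if n < 2 * minsize:
        logger.warning(
            "restscore_groups: n=%d < 2*minsize=%d; using a single group",
            n,
            2 * minsize,
        )
        return RestscoreTable(
            assignment=np.zeros(n, dtype=np.int64),
            bounds=((int(R.min()), int(R.max())),),
            sizes=(n,),
        )
    values, counts = np.unique(R, return_counts=True)
    groups: list[list[int]] = []  # list of value-index lists
    current: list[int] = []
    total = 0
    for vi, c in enumerate(counts):
        current.append(vi)
        total += int(c)
        if total >= minsize:
            groups.append(current)
            current, total = [], 0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    value_to_group = np.empty(len(values), dtype=np.int64)
    bounds = []
    sizes = []
    for g, vis in enumerate(groups):
        value_to_group[vis] = g
        bounds.append((int(values[vis[0]]), int(values[vis[-1]])))
        sizes.append(int(counts[vis].sum()))
    assignment = value_to_group[np.searchsorted(values, R)]
    return RestscoreTable(assignment, tuple(bounds), tuple(sizes))


def _group_prop(assignment: np.ndarray, n_groups: int, x: np.ndarray,
                sizes: np.ndarray) -> np.ndarray:
    return np.bincount(assignment, weights=x, minlength=n_groups) / sizes


def _worst(items: list[ItemViolations]) -> int | None:
    if not any(iv.violations for iv in items):
        return None
    return max(items, key=lambda iv: (iv.critical, iv.max_violation, -iv.item)).item


def check_monotonicity(
    matrix: ResponseMatrix,
    scale_items: list[int],
    config: CheckConfig | None = None,
) -> ViolationReport:
    """Restscore monotonicity check for every item of a scale.

    For item i, compares its ownership proportion across all ordered
    pairs of rest-score groups (rest score excludes i); a drop larger
    than ``minvi`` is a violation, critical when the one-sided
    two-proportion z-test is significant at ``alpha``.
    """
    config = config or CheckConfig()
    scale = list(scale_items)
    if len(scale) < 3:
        raise DegenerateDataError("monotonicity check needs a scale of >= 3 items")
    out = []
    for i in scale:
        table = restscore_groups(matrix, {i}, config, scale)
        sizes = np.asarray(table.sizes, dtype=float)
        props = _group_prop(table.assignment, table.n_groups,
                            matrix.values[:, i].astype(float), sizes)
        iv = ItemViolations(item=i, label=matrix.item_labels[i])
        for g1 in range(table.n_groups):
            for g2 in range(g1 + 1, table.n_groups):
                iv.comparisons += 1
                diff = props[g1] - props[g2]
                if diff > config.minvi:
                    iv.violations += 1
                    iv.max_violation = max(iv.max_violation, float(diff))
                    pool = (props[g1] * sizes[g1] + props[g2] * sizes[g2]) / (
                        sizes[g1] + sizes[g2]
                    )
                    se = np.sqrt(
                        pool * (1 - pool) * (1 / sizes[g1] + 1 / sizes[g2])
                    )
                    z = diff / se if se > 0 else np.inf
                    p = stats.norm.sf(z)
                    iv.z_stats.append(float(z))
                    if p < config.alpha:
                        iv.critical += 1
        out.append(iv)
    return ViolationReport("monotonicity", out, _worst(out))


def check_iio_restscore(
    matrix: ResponseMatrix,
    scale_items: list[int],
    config: CheckConfig | None = None,
) -> ViolationReport:
    """Restscore check of non-intersection (invariant item ordering).

    For each pair with overall p_i < p_j (ties to the lower index), in
    every rest-score group (rest excludes both items) the harder item i
    must not exceed the easier item j by more than ``minvi``.  A
    reversal is critical when an exact one-sided sign test on the
    group's discordant households is significant at ``alpha``.  Tallies
    aggregate over all pairs containing an item.
    """
    config = config or CheckConfig()
    scale = list(scale_items)
    if len(scale) < 3:
        raise DegenerateDataError("IIO check needs a scale of >= 3 items")
    p = matrix.popularity
    tall = {i: ItemViolations(item=i, label=matrix.item_labels[i]) for i in scale}
    for a_pos in range(len(scale)):
        for b_pos in range(a_pos + 1, len(scale)):
            a, b = scale[a_pos], scale[b_pos]
            # i = harder (less popular) item of the pair
            if p[a] < p[b] or (p[a] == p[b] and a < b):
                i, j = a, b
            else:
                i, j = b, a
            table = restscore_groups(matrix, {i, j}, config, scale)
            sizes = np.asarray(table.sizes, dtype=float)
            xi = matrix.values[:, i].astype(float)
            xj = matrix.values[:, j].astype(float)
            prop_i = _group_prop(table.assignment, table.n_groups, xi, sizes)
            prop_j = _group_prop(table.assignment, table.n_groups, xj, sizes)
            for g in range(table.n_groups):
                tall[i].comparisons += 1
                tall[j].comparisons += 1
                diff = prop_i[g] - prop_j[g]
                if diff > config.minvi:
                    in_g = table.assignment == g
                    n10 = int(((xi == 1) & (xj == 0) & in_g).sum())
                    n01 = int(((xi == 0) & (xj == 1) & in_g).sum())
                    pval = stats.binom.sf(n10 - 1, n10 + n01, 0.5) if n10 + n01 else 1.0
                    for t in (tall[i], tall[j]):
                        t.violations += 1
                        t.max_violation = max(t.max_violation, float(diff))
                        t.z_stats.append(float(pval))
                        if pval < config.alpha:
                            t.critical += 1
    out = [tall[i] for i in scale]
    return ViolationReport("iio", out, _worst(out))


def iterative_iio_removal(
    matrix: ResponseMatrix,
    scale_items: list[int],
    config: CheckConfig | None = None,
) -> tuple[list[int], list[dict]]:
    """Repeatedly remove the worst IIO offender until no critical
    violations remain.

    The worst offender has the most critical violations; ties break by
    larger maximum violation, then lower within-scale H_i, then lower
    item index.  Stops with a warning if the scale would shrink below 3
    items.  Returns (retained item indices, removal log).
    """
    config = config or CheckConfig()
    current = list(scale_items)
    removal_log: list[dict] = []
    while len(current) >= 3:
        report = check_iio_restscore(matrix, current, config)
        by_item = report.by_item()
        if not any(iv.critical for iv in by_item.values()):
            break
        F, E = _pairwise_FE(matrix.values[:, current])
        item_H = _item_H_from_FE(F, E)
        h_of = {item: float(item_H[pos]) for pos, item in enumerate(current)}
        worst = max(
            current,
            key=lambda it: (
                by_item[it].critical,
                by_item[it].max_violation,
                -h_of[it],
                -it,
            ),
        )
        entry = {
            "removed": matrix.item_labels[worst],
            "critical": by_item[worst].critical,
            "max_violation": by_item[worst].max_violation,
            "H_i": h_of[worst],
            "tally": {
                matrix.item_labels[it]: by_item[it].critical for it in current
            },
        }
        logger.info("IIO removal: %s", entry)
        removal_log.append(entry)
        current.remove(worst)
        if len(current) < 3:
            logger.warning("IIO removal stopped: scale shrank below 3 items")
            break
    return current, removal_log
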