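"""Reliability and cross-method comparison of SEP indices.

Cronbach's alpha of a (weighted) item sum, with a 95% confidence
interval by the Feldt F-distribution method, and the three-way
comparison of the Mokken score, the polychoric-PCA scores and log
household expenditure: Pearson correlations between continuous scores,
Spearman correlations between quintile labels (average ranks for the
heavy ties), and per-quintile expenditure summaries backing
boxplot-style displays.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError
from .scalability import ResponseMatrix
from .wealth_index import WealthIndex

logger = logging.getLogger(__name__)

__all__ = ["ReliabilityResult", "ComparisonReport", "weighted_alpha", "compare_indices"]


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    ci_low: float
    ci_high: float
    weights: np.ndarray
    n: int
    k: int
    ci_method: str = "feldt"

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "k": self.k,
            "ci_method": self.ci_method,
        }


@dataclass
class ComparisonReport:
    pearson: dict[str, float]
    spearman: dict[str, float]
    quintile_summaries: dict[str, pd.DataFrame]
    n: int
    log_base: str = "natural"

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "spearman": self.spearman,
            "quintile_summaries": {
                name: df.to_dict(orient="records")
                for name, df in self.quintile_summaries.items()
            },
            "n": self.n,
            "log_base": self.log_base,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def weighted_alpha(
    matrix: ResponseMatrix, weights, level: float = 0.95
) -> ReliabilityResult:
    """Cronbach's alpha of the weighted item sum, with a Feldt CI.

    With y_i = w_i x_i, alpha = k/(k-1) * (1 - sum var(y_i)/var(sum y_i)),
    sample variances with n-1 denominator.  Alpha is invariant to a
    common positive rescaling of the weights.  The Feldt interval uses
    (1 - alpha) ~ scaled F with (n-1, (n-1)(k-1)) degrees of freedom.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != matrix.k:
        raise ConfigurationError("weights length does not match item count")
    if not np.isfinite(w).all():
        raise ConfigurationError("weights must be finite")
    Y = matrix.values * w
    item_vars = Y.var(axis=0, ddof=1)
    total_var = Y.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("weighted total score has zero variance")
    k = matrix.k
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    n = matrix.n
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    gamma = 1.0 - level
    ci_low = 1.0 - (1.0 - alpha) * stats.f.ppf(1.0 - gamma / 2.0, df1, df2)
    ci_high = 1.0 - (1.0 - alpha) * stats.f.ppf(gamma / 2.0, df1, df2)
    return ReliabilityResult(
        alpha=float(alpha),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        weights=w,
        n=n,
        k=k,
    )


def _quintile_summary(quintiles: np.ndarray, logexp: np.ndarray) -> pd.DataFrame:
    rows = []
    for q in range(1, 6):
        vals = logexp[quintiles == q]
        rows.append(
            {
                "quintile": q,
                "n": int(len(vals)),
                "q1": float(np.percentile(vals, 25)) if len(vals) else float("nan"),
                "median": float(np.median(vals)) if len(vals) else float("nan"),
                "q3": float(np.percentile(vals, 75)) if len(vals) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def compare_indices(
    mokken: WealthIndex,
    pca_full: WealthIndex,
    pca_reduced: WealthIndex,
    expenditure,
) -> ComparisonReport:
    """Three-way comparison of SEP measures against log expenditure.

    Expenditure is natural-log transformed (long-tailed, as is typical
    of expenditure data).  Entries that are missing (NaN) are excluded
    pairwise from the expenditure comparisons only.  Returns Pearson r
    between continuous scores, Spearman r between quintile labels, and
    per-quintile log-expenditure summaries for each index.
    """
    indices = {
        "mokken": mokken,
        "pca_full": pca_full,
        "pca_reduced": pca_reduced,
    }
    lengths = {len(ix.score) for ix in indices.values()}
    expenditure = np.asarray(expenditure, dtype=float)
    if lengths != {len(expenditure)}:
        raise ConfigurationError("all score and expenditure vectors must align")
    valid = np.isfinite(expenditure)
    if (expenditure[valid] <= 0).any():
        raise ConfigurationError("expenditure must be strictly positive")
    logexp = np.full_like(expenditure, np.nan)
    logexp[valid] = np.log(expenditure[valid])

    for name, ix in indices.items():
        if np.std(ix.score) == 0:
            raise DegenerateDataError(f"index '{name}' has zero score variance")

    pearson: dict[str, float] = {}
    spearman: dict[str, float] = {}
    names = list(indices)
    for a_pos in range(len(names)):
        for b_pos in range(a_pos + 1, len(names)):
            a, b = names[a_pos], names[b_pos]
            pearson[f"{a}_vs_{b}"] = float(
                stats.pearsonr(indices[a].score, indices[b].score)[0]
            )
            spearman[f"{a}_vs_{b}_quintiles"] = float(
                stats.spearmanr(indices[a].quintile, indices[b].quintile)[0]
            )
    for name, ix in indices.items():
        pearson[f"{name}_vs_log_expenditure"] = float(
            stats.pearsonr(ix.score[valid], logexp[valid])[0]
        )
        spearman[f"{name}_quintiles_vs_log_expenditure"] = float(
            stats.spearmanr(ix.quintile[valid], logexp[valid])[0]
        )
    summaries = {
        name: _quintile_summary(ix.quintile[valid], logexp[valid])
        for name, ix in indices.items()
    }
    return ComparisonReport(
        pearson=pearson,
        spearman=spearman,
        quintile_summaries=summaries,
        n=int(valid.sum()),
    )
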