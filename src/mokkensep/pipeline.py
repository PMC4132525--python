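"""End-to-end orchestration: simulate/load -> scale -> check -> score -> compare.

One seeded, idempotent run reproduces the whole analysis sequence:
scalability coefficients on the full pool, AISP partitioning,
monotonicity and IIO checks with iterative removal on the first scale,
the Mokken sum score, polychoric PCA indices on the full and reduced
pools, weighted reliabilities, and the comparison against log
household expenditure.  All tuning constants live in one config so a
replication on real survey data is a config change, not a code change.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import ComparisonReport, ReliabilityResult, compare_indices, weighted_alpha
from .exceptions import ConfigurationError, DegenerateDataError, PipelineError
from .item_selection import ScalePartition, SelectionConfig, aisp
from .model_checks import CheckConfig, ViolationReport, check_monotonicity, \
    check_iio_restscore, iterative_iio_removal
from .scalability import ResponseMatrix, ScalabilityReport, compute_scalability
from .synthetic_data import SurveyConfig, default_survey_config, simulate_survey
from .wealth_index import PCAResult, WealthIndex, mokken_score, pca_first_component, \
    pca_scores, polychoric_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "read_households", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from one YAML file.

    Either ``input_path`` (a comma-separated household table) or a
    ``synthetic`` block must be given.  ``dichotomise`` maps numeric
    column names to thresholds: value >= threshold becomes 1.
    """

    input_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    item_columns: list[str] | None = None
    expenditure_column: str = "expenditure"
    dichotomise: dict[str, float] = field(default_factory=dict)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    checks: CheckConfig = field(default_factory=CheckConfig)
    n_boot_se: int = 1000
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.input_path is None and not self.synthetic:
            self.synthetic = {"n": 3810}
        for col, thr in self.dichotomise.items():
            if not np.isfinite(thr):
                raise ConfigurationError(f"non-finite threshold for column '{col}'")
        if self.item_columns is not None and not self.item_columns:
            raise ConfigurationError("item_columns must be non-empty when given")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sel = d.pop("selection", {})
        chk = d.pop("checks", {})
        cfg = cls(**d)
        if isinstance(sel, dict):
            cfg.selection = SelectionConfig(**sel)
        if isinstance(chk, dict):
            cfg.checks = CheckConfig(**chk)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All stage outputs of one pipeline run plus provenance."""

    scalability: ScalabilityReport
    partition: ScalePartition
    monotonicity: ViolationReport | None
    iio: ViolationReport | None
    removal_log: list[dict]
    mokken_items: list[str]
    indices: dict[str, WealthIndex]
    pca: dict[str, PCAResult]
    reliability: dict[str, ReliabilityResult]
    comparison: ComparisonReport | None
    exclusion_log: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "exclusion_log": self.exclusion_log,
            "scalability": self.scalability.to_dict(),
            "partition": self.partition.to_dict(),
            "monotonicity": self.monotonicity.to_dict() if self.monotonicity else None,
            "iio": self.iio.to_dict() if self.iio else None,
            "removal_log": self.removal_log,
            "mokken_items": self.mokken_items,
            "pca": {name: p.to_dict() for name, p in self.pca.items()},
            "reliability": {
                name: r.to_dict() for name, r in self.reliability.items()
            },
            "comparison": self.comparison.to_dict() if self.comparison else None,
            "quintile_counts": {
                name: pd.Series(ix.quintile).value_counts().sort_index().to_dict()
                for name, ix in self.indices.items()
            },
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)
        self.scalability.item_frame().to_csv(out / "scalability_items.csv", index=False)
        self.scalability.pair_frame().to_csv(out / "scalability_pairs.csv", index=False)
        frames = [
            ix.to_frame().assign(method=name) for name, ix in self.indices.items()
        ]
        if frames:
            pd.concat(frames).to_csv(out / "scores.csv", index=False)


def read_households(
    path, config: PipelineConfig
) -> tuple[ResponseMatrix, np.ndarray, dict]:
    """Read a delimited household table; complete-case on the items.

    Numeric columns listed in ``config.dichotomise`` are thresholded to
    0/1 first.  Rows with any missing item value are excluded (counted
    in the exclusion log); rows with missing or non-positive
    expenditure are retained for scaling but flagged NaN for the
    expenditure comparisons.
    """
    df = pd.read_csv(path)
    item_cols = config.item_columns
    if item_cols is None:
        drop = {config.expenditure_column, "theta"}
        item_cols = [c for c in df.columns if c not in drop]
    missing_cols = [c for c in item_cols if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(f"unknown item column(s): {missing_cols}")
    items = df[item_cols].apply(pd.to_numeric, errors="coerce")
    for col, thr in config.dichotomise.items():
        if col not in items.columns:
            raise ConfigurationError(f"dichotomise column '{col}' not an item column")
        vals = items[col]
        items[col] = (vals >= thr).astype(float).where(vals.notna())
    bad = [
        c for c in item_cols
        if not items[c].dropna().isin([0.0, 1.0]).all()
    ]
    if bad:
        raise ConfigurationError(
            f"non-binary item column(s) without a dichotomisation rule: {bad}"
        )
    complete = items.notna().all(axis=1)
    n_in = len(df)
    n_used = int(complete.sum())
    if n_used == 0:
        raise DegenerateDataError("all rows excluded by complete-case filtering")
    exclusion_log = {
        "rows_in": n_in,
        "rows_used": n_used,
        "rows_excluded": n_in - n_used,
        "exclusion_rate": (n_in - n_used) / n_in,
    }
    matrix = ResponseMatrix(
        items[complete].to_numpy(), tuple(item_cols),
        tuple(df.index[complete].tolist()),
    )
    if config.expenditure_column in df.columns:
        exp_raw = pd.to_numeric(
            df.loc[complete, config.expenditure_column], errors="coerce"
        ).to_numpy(dtype=float)
        invalid = ~np.isfinite(exp_raw) | (exp_raw <= 0)
        exclusion_log["expenditure_missing_or_nonpositive"] = int(invalid.sum())
        exp_raw[invalid] = np.nan
        expenditure = exp_raw
    else:
        expenditure = np.full(n_used, np.nan)
        exclusion_log["expenditure_missing_or_nonpositive"] = n_used
    return matrix, expenditure, exclusion_log


def _build_survey_config(config: PipelineConfig) -> SurveyConfig:
    syn = dict(config.synthetic)
    n = int(syn.get("n", 3810))
    seed = int(syn.get("seed", config.seed))
    return default_survey_config(n_households=n, seed=seed)


def run_full_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis sequence; deterministic given the config."""

    completed: dict[str, object] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            err = exc if isinstance(exc, PipelineError) else PipelineError(name, str(exc))
            if config.out_dir:
                out = Path(config.out_dir)
                out.mkdir(parents=True, exist_ok=True)
                with open(out / "report.json", "w") as fh:
                    json.dump(
                        {
                            "failed_stage": err.stage,
                            "error": str(err),
                            "completed_stages": sorted(completed),
                        },
                        fh,
                        indent=2,
                    )
            raise err from exc
        completed[name] = result
        return result

    # --- data -------------------------------------------------------------
    if config.input_path is not None:
        matrix, expenditure, exclusion_log = stage(
            "read", read_households, config.input_path, config
        )
    else:
        survey = _build_survey_config(config)
        data = stage("simulate", simulate_survey, survey)
        matrix, expenditure = data.responses, data.expenditure
        exclusion_log = {
            "rows_in": matrix.n,
            "rows_used": matrix.n,
            "rows_excluded": 0,
            "exclusion_rate": 0.0,
        }

    # --- scalability on the full pool ------------------------------------
    scal = stage(
        "scalability",
        compute_scalability,
        matrix,
        n_boot=config.n_boot_se,
        seed=config.seed,
    )

    # --- AISP -------------------------------------------------------------
    sel = dataclasses.replace(config.selection, seed=config.seed)
    partition = stage("aisp", aisp, matrix, sel)

    # --- model checks on scale 1 ------------------------------------------
    monotonicity = iio = None
    removal_log: list[dict] = []
    if partition.scales:
        scale1 = partition.scales[0]
        if len(scale1) >= 3:
            monotonicity = stage(
                "monotonicity", check_monotonicity, matrix, scale1, config.checks
            )
            iio = stage(
                "iio", check_iio_restscore, matrix, scale1, config.checks
            )
            retained, removal_log = stage(
                "iio_removal", iterative_iio_removal, matrix, scale1, config.checks
            )
        else:
            retained = list(scale1)
    else:
        raise PipelineError("aisp", "no scale could be formed from the item pool")
    mokken_items = retained

    # --- indices ----------------------------------------------------------
    mokken = stage("mokken_score", mokken_score, matrix, mokken_items)

    full_corr = stage("polychoric_full", polychoric_matrix, matrix)
    pca_full = stage("pca_full", pca_first_component, full_corr)
    idx_full = stage("pca_scores_full", pca_scores, matrix, pca_full)

    reduced = matrix.subset(mokken_items)
    red_corr = stage("polychoric_reduced", polychoric_matrix, reduced)
    pca_red = stage("pca_reduced", pca_first_component, red_corr)
    idx_red = stage("pca_scores_reduced", pca_scores, reduced, pca_red)

    # --- reliability -------------------------------------------------------
    reliability = {
        "unit_full_pool": stage(
            "alpha", weighted_alpha, matrix, np.ones(matrix.k)
        ),
        "pca_weighted_full_pool": stage(
            "alpha", weighted_alpha, matrix, pca_full.loadings
        ),
        "unit_mokken_scale": stage(
            "alpha", weighted_alpha, reduced, np.ones(reduced.k)
        ),
        "pca_weighted_reduced_pool": stage(
            "alpha", weighted_alpha, reduced, pca_red.loadings
        ),
    }

    # --- comparison --------------------------------------------------------
    comparison = None
    if np.isfinite(expenditure).any():
        comparison = stage(
            "comparison", compare_indices, mokken, idx_full, idx_red, expenditure
        )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
    }
    report = RunReport(
        scalability=scal,
        partition=partition,
        monotonicity=monotonicity,
        iio=iio,
        removal_log=removal_log,
        mokken_items=[matrix.item_labels[i] for i in mokken_items],
        indices={"mokken": mokken, "pca_full": idx_full, "pca_reduced": idx_red},
        pca={"full": pca_full, "reduced": pca_red},
        reliability=reliability,
        comparison=comparison,
        exclusion_log=exclusion_log,
        provenance=provenance,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
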