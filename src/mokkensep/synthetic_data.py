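"""Synthetic household asset-ownership surveys with known latent structure.

Households carry a standard-normal latent socioeconomic position (SEP)
trait theta.  Ownership of asset i is Bernoulli with a two-parameter
logistic (2PL) response function,

    P(X_i = 1 | theta) = logistic(a_i (theta - b_i)),

a_i > 0 the discrimination and b_i the difficulty ("hardness") of the
item.  Equal discriminations give non-intersecting response curves,
i.e. invariant item ordering holds by construction — the clean
negative control for the model checks.  Household expenditure is
log-normal with a trait loading: log E = mu + lambda * theta + sigma * eps.

Besides the core simulator the module provides deterministic Guttman
data, two violation injectors (a non-monotone item and a crossing
high-discrimination item), and a 17-item survey emulating the shape of
a national asset module: 12 items on the dominant trait with
popularities from ~90% down to ~0.3%, a correlated two-item secondary
cluster, and 3 weakly-related noise items.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import ConfigurationError
from .scalability import ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LatentConfig",
    "SurveyConfig",
    "SyntheticDataset",
    "simulate_responses",
    "responses_given_theta",
    "make_guttman",
    "inject_nonmonotone_item",
    "inject_intersecting_item",
    "marginal_popularity",
    "difficulty_for_popularity",
    "simulate_survey",
    "default_survey_config",
    "write_household_table",
]


@dataclass(frozen=True)
class LatentConfig:
    """Generating configuration for a single-trait 2PL dataset.

    ``item_params`` is a list of (a_i, b_i) tuples; ``expenditure_params``
    is (mu, lam, sigma) on the log scale, where ``lam`` is the loading of
    log-expenditure on the SEP trait.
    """

    n_households: int
    item_params: tuple[tuple[float, float], ...]
    expenditure_params: tuple[float, float, float] = (7.0, 0.75, 1.0)
    seed: int = 0
    item_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_households < 1:
            raise ConfigurationError("n_households must be positive")
        if not self.item_params:
            raise ConfigurationError("item_params must be non-empty")
        for a, b in self.item_params:
            if a <= 0:
                raise ConfigurationError(f"discrimination a={a} must be > 0")
        mu, lam, sigma = self.expenditure_params
        if lam < 0:
            raise ConfigurationError("expenditure loading lambda must be >= 0")
        if sigma <= 0:
            raise ConfigurationError("expenditure noise sigma must be > 0")
        labels = tuple(self.item_labels) or tuple(
            f"item_{i}" for i in range(len(self.item_params))
        )
        if len(labels) != len(self.item_params):
            raise ConfigurationError("item_labels length mismatch")
        object.__setattr__(self, "item_params", tuple(map(tuple, self.item_params)))
        object.__setattr__(self, "item_labels", labels)


@dataclass(frozen=True)
class SurveyConfig:
    """Multi-block survey: a main trait block, a correlated secondary
    block, and weakly-discriminating noise items."""

    n_households: int
    main_items: tuple[tuple[str, float, float], ...]  # (label, a, b)
    secondary_items: tuple[tuple[str, float, float], ...]
    secondary_trait_corr: float
    noise_items: tuple[tuple[str, float, float], ...]
    expenditure_params: tuple[float, float, float]
    seed: int


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated responses plus the ground truth that produced them."""

    responses: ResponseMatrix
    theta: np.ndarray
    expenditure: np.ndarray
    generating_config: object

    def __post_init__(self):
        n = self.responses.n
        if len(self.theta) != n or len(self.expenditure) != n:
            raise ConfigurationError("theta/expenditure length mismatch")
        if (np.asarray(self.expenditure) <= 0).any():
            raise ConfigurationError("expenditure must be strictly positive")


def responses_given_theta(
    theta: np.ndarray,
    item_params: Sequence[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli 2PL responses for fixed latent trait values."""
    theta = np.asarray(theta, dtype=float)
    a = np.array([p[0] for p in item_params])
    b = np.array([p[1] for p in item_params])
    probs = expit(a[None, :] * (theta[:, None] - b[None, :]))
    return (rng.random(probs.shape) < probs).astype(np.int8)


def simulate_responses(config: LatentConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset from a :class:`LatentConfig`.

    theta ~ N(0,1); responses 2PL; expenditure log-normal with trait
    loading.  Bit-reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    theta = rng.standard_normal(config.n_households)
    X = responses_given_theta(theta, config.item_params, rng)
    mu, lam, sigma = config.expenditure_params
    expenditure = np.exp(mu + lam * theta + sigma * rng.standard_normal(len(theta)))
    matrix = ResponseMatrix(X, config.item_labels)
    return SyntheticDataset(matrix, theta, expenditure, config)


def make_guttman(theta: np.ndarray, difficulties: np.ndarray) -> ResponseMatrix:
    """Deterministic Guttman responses: entry (h, i) = 1 iff theta_h > b_i.

    The result contains zero Guttman errors for every item pair, so all
    H coefficients equal 1 downstream.  Difficulties must be distinct.
    A degenerate outcome (an item owned by everyone or no one) is
    rejected by the ResponseMatrix popularity check.
    """
    theta = np.asarray(theta, dtype=float)
    difficulties = np.asarray(difficulties, dtype=float)
    if len(np.unique(difficulties)) != len(difficulties):
        raise ConfigurationError("difficulties must be distinct")
    return ResponseMatrix((theta[:, None] > difficulties[None, :]).astype(np.int8))


def _append_item(
    data: SyntheticDataset, column: np.ndarray, label: str
) -> SyntheticDataset:
    X = np.column_stack([data.responses.values, column.astype(np.int8)])
    labels = data.responses.item_labels + (label,)
    matrix = ResponseMatrix(X, labels, data.responses.household_ids)
    return SyntheticDataset(matrix, data.theta, data.expenditure, data.generating_config)


def inject_nonmonotone_item(
    data: SyntheticDataset, peak: float, width: float, seed: int
) -> SyntheticDataset:
    """Append an item with a unimodal (non-monotone) response curve.

    Ownership probability is a Gaussian bump in theta centred at
    ``peak`` with the given ``width``, scaled to a maximum of 0.9 —
    e.g. an asset common among middle-SEP households but rare at both
    extremes.  Original items are untouched.
    """
    if width <= 0:
        raise ConfigurationError("width must be > 0")
    rng = np.random.default_rng(seed)
    probs = 0.9 * np.exp(-((data.theta - peak) ** 2) / (2.0 * width**2))
    col = (rng.random(len(probs)) < probs).astype(np.int8)
    return _append_item(data, col, "nonmonotone_item")


def inject_intersecting_item(
    data: SyntheticDataset, a_new: float, b_new: float, seed: int
) -> SyntheticDataset:
    """Append a monotone 2PL item whose response curve crosses the others.

    Requires a discrimination strongly different (>= 3x in either
    direction) from every existing item's, so the crossing is real
    rather than sampling noise.
    """
    cfg = data.generating_config
    base_a = _base_discriminations(cfg)
    if base_a is not None:
        ratio_ok = all(a_new >= 3.0 * a or a_new <= a / 3.0 for a in base_a)
        if not ratio_ok:
            raise ConfigurationError(
                "a_new must differ from every base discrimination by >= 3x"
            )
    rng = np.random.default_rng(seed)
    probs = expit(a_new * (data.theta - b_new))
    col = (rng.random(len(probs)) < probs).astype(np.int8)
    return _append_item(data, col, "intersecting_item")


def _base_discriminations(cfg) -> list[float] | None:
    if isinstance(cfg, LatentConfig):
        return [a for a, _ in cfg.item_params]
    if isinstance(cfg, SurveyConfig):
        return [a for _, a, _ in cfg.main_items + cfg.secondary_items + cfg.noise_items]
    return None


# ---------------------------------------------------------------------------
# marginal popularity and calibrated difficulties

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def marginal_popularity(a: float, b: float) -> float:
    """Population item popularity: integral of the 2PL response curve
    over the standard-normal trait distribution (Gauss-Hermite)."""
    return float(np.sum(_GH_WEIGHTS * expit(a * (_GH_NODES - b))))


def difficulty_for_popularity(p: float, a: float) -> float:
    """Difficulty b such that the marginal popularity equals ``p``."""
    if not 0.0 < p < 1.0:
        raise ConfigurationError("target popularity must be in (0, 1)")
    return brentq(lambda b: marginal_popularity(a, b) - p, -15.0, 15.0, xtol=1e-10)


# ---------------------------------------------------------------------------
# default 17-item survey fixture

# Target popularities shaped like a national household asset module:
# a dominant wealth dimension spanning near-universal utilities down to
# sub-1% luxury goods, a small secondary cluster (e.g. agrarian assets)
# on a correlated trait, and items nearly unrelated to wealth.
_MAIN_TARGETS = [
    ("clock", 0.905),
    ("electricity", 0.904),
    ("television", 0.785),
    ("motorbike", 0.498),
    ("video_player", 0.316),
    ("landline_phone", 0.167),
    ("refrigerator", 0.153),
    ("magazine_subscription", 0.075),
    ("washing_machine", 0.053),
    ("computer", 0.050),
    ("mobile_phone", 0.043),
    ("dishwasher", 0.0034),
]
_SECONDARY_TARGETS = [("bucket", 0.846), ("agricultural_machine", 0.081)]
_NOISE_TARGETS = [("bicycle", 0.840), ("second_house", 0.047), ("car", 0.037)]


def default_survey_config(
    n_households: int = 3810, seed: int = 0
) -> SurveyConfig:
    """The default 17-item survey: 12 main-trait items (a=2), a
    secondary pair on a trait correlated 0.4 with the main one, and 3
    noise items with near-flat response curves (a=0.3)."""
    a_main, a_sec, a_noise = 2.0, 2.0, 0.3
    main = tuple(
        (lab, a_main, difficulty_for_popularity(p, a_main)) for lab, p in _MAIN_TARGETS
    )
    sec = tuple(
        (lab, a_sec, difficulty_for_popularity(p, a_sec)) for lab, p in _SECONDARY_TARGETS
    )
    noise = tuple(
        (lab, a_noise, difficulty_for_popularity(p, a_noise)) for lab, p in _NOISE_TARGETS
    )
    # lambda/sigma give corr(log expenditure, theta) = 0.75/1.25 = 0.6
    return SurveyConfig(
        n_households=n_households,
        main_items=main,
        secondary_items=sec,
        secondary_trait_corr=0.4,
        noise_items=noise,
        expenditure_params=(7.0, 0.75, 1.0),
        seed=seed,
    )


def simulate_survey(config: SurveyConfig) -> SyntheticDataset:
    """Generate the multi-block survey dataset from a SurveyConfig."""
    rng = np.random.default_rng(config.seed)
    n = config.n_households
    theta = rng.standard_normal(n)
    rho = config.secondary_trait_corr
    theta2 = rho * theta + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    cols, labels = [], []
    for block, trait in (
        (config.main_items, theta),
        (config.secondary_items, theta2),
        (config.noise_items, theta),
    ):
        if block:
            params = [(a, b) for _, a, b in block]
            cols.append(responses_given_theta(trait, params, rng))
            labels.extend(lab for lab, _, _ in block)
    X = np.hstack(cols)
    mu, lam, sigma = config.expenditure_params
    expenditure = np.exp(mu + lam * theta + sigma * rng.standard_normal(n))
    matrix = ResponseMatrix(X, tuple(labels))
    return SyntheticDataset(matrix, theta, expenditure, config)


def write_household_table(
    data: SyntheticDataset, path, include_theta: bool = False
) -> None:
    """Write the household table as comma-separated text: one row per
    household, item columns, an ``expenditure`` column, and optionally
    the true ``theta`` for test fixtures."""
    df = pd.DataFrame(
        data.responses.values, columns=list(data.responses.item_labels)
    )
    df["expenditure"] = data.expenditure
    if include_theta:
        df["theta"] = data.theta
    df.to_csv(path, index=False)
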