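import numpy as np
import pytest

from mokkensep import (
    LatentConfig,
    ResponseMatrix,
    default_survey_config,
    make_guttman,
    simulate_responses,
    simulate_survey,
)


def rasch_like_config(k=11, a=2.0, n=5000, seed=1, span=2.5):
    """Equal-discrimination 2PL bank: non-intersecting response curves,
    so invariant item ordering holds by construction."""
    bs = np.linspace(-span, span, k)
    return LatentConfig(
        n_households=n,
        item_params=tuple((a, float(b)) for b in bs),
        seed=seed,
    )


@pytest.fixture(scope="session")
def rasch_dataset():
    return simulate_responses(rasch_like_config())


@pytest.fixture(scope="session")
def survey_dataset():
    """Default 17-item survey fixture at the full study size."""
    return simulate_survey(default_survey_config(n_households=3810, seed=1))


@pytest.fixture
def guttman_matrix():
    rng = np.random.default_rng(42)
    theta = rng.standard_normal(200)
    difficulties = np.quantile(theta, [0.15, 0.35, 0.55, 0.75, 0.9])
    return make_guttman(theta, difficulties)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_valid_matrix(rng, n_max=50, k_max=5):
    """Random binary matrix with no constant item, by rejection."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        k = int(rng.integers(2, k_max + 1))
        p = rng.uniform(0.15, 0.85, size=k)
        X = (rng.random((n, k)) < p).astype(np.int8)
        col_ok = ((X.sum(0) > 0) & (X.sum(0) < n)).all()
        if col_ok:
            return ResponseMatrix(X)
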