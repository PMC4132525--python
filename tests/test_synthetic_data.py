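"""Generator calibration and the controlled violation injectors."""

import numpy as np
import pytest
from scipy import stats

import oracles
from conftest import rasch_like_config
from mokkensep import (
    ConfigurationError,
    DegenerateDataError,
    LatentConfig,
    default_survey_config,
    inject_intersecting_item,
    inject_nonmonotone_item,
    make_guttman,
    simulate_responses,
    simulate_survey,
)
from mokkensep.synthetic_data import (
    difficulty_for_popularity,
    marginal_popularity,
    write_household_table,
)
from mokkensep.scalability import compute_scalability


class TestLatentConfig:
    def test_rejects_bad_params(self):
        with pytest.raises(ConfigurationError):
            LatentConfig(10, ((0.0, 0.0),))
        with pytest.raises(ConfigurationError):
            LatentConfig(10, ((1.0, 0.0),), expenditure_params=(0.0, 0.5, 0.0))
        with pytest.raises(ConfigurationError):
            LatentConfig(10, ())


class TestSimulateResponses:
    def test_reproducible_from_seed(self):
        cfg = rasch_like_config(k=5, n=500, seed=11)
        d1, d2 = simulate_responses(cfg), simulate_responses(cfg)
        np.testing.assert_array_equal(d1.responses.values, d2.responses.values)
        np.testing.assert_array_equal(d1.theta, d2.theta)
        np.testing.assert_array_equal(d1.expenditure, d2.expenditure)

    def test_infinite_discrimination_is_guttman(self):
        cfg = LatentConfig(
            400, tuple((1e6, b) for b in (-1.0, 0.0, 1.0)), seed=5
        )
        d = simulate_responses(cfg)
        expected = (d.theta[:, None] > np.array([-1.0, 0.0, 1.0])).astype(int)
        np.testing.assert_array_equal(d.responses.values, expected)

    def test_popularities_match_quadrature_oracle(self):
        """Empirical popularity within 3 Monte-Carlo SEs of the
        quadrature value of the marginal response probability, and
        strictly decreasing in difficulty."""
        cfg = rasch_like_config(k=11, a=2.0, n=5000, seed=1)
        d = simulate_responses(cfg)
        p_hat = d.responses.popularity
        for i, (a, b) in enumerate(cfg.item_params):
            p_true = oracles.quad_popularity(a, b)
            se = np.sqrt(p_true * (1 - p_true) / cfg.n_households)
            assert abs(p_hat[i] - p_true) < 3 * se
        assert np.all(np.diff(p_hat) < 0)

    def test_degenerate_theta_popularity_half(self):
        # logistic symmetry: at theta = b the response probability is 1/2
        n = 100_000
        rng = np.random.default_rng(0)
        from mokkensep.synthetic_data import responses_given_theta

        X = responses_given_theta(np.zeros(n), [(1.0, 0.0)], rng)
        assert abs(X.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_expenditure_trait_correlation(self):
        d = simulate_responses(rasch_like_config(k=5, n=20_000, seed=3))
        r = stats.pearsonr(np.log(d.expenditure), d.theta)[0]
        assert r == pytest.approx(0.6, abs=0.02)

    def test_sum_score_recovers_theta(self):
        d = simulate_responses(rasch_like_config(k=11, a=2.0, n=5000, seed=1))
        rho = stats.spearmanr(d.responses.values.sum(1), d.theta)[0]
        assert rho >= 0.8


class TestMakeGuttman:
    def test_direct_evaluation(self):
        m = make_guttman(np.array([-1.0, 0.0, 1.0]), np.array([-0.5, 0.5]))
        np.testing.assert_array_equal(m.values, [[0, 0], [1, 0], [1, 1]])

    def test_scale_H_is_one(self, guttman_matrix):
        assert compute_scalability(guttman_matrix).scale_H == 1.0

    def test_all_zero_flagged_degenerate(self):
        with pytest.raises(DegenerateDataError, match="constant"):
            make_guttman(np.array([-3.0, -2.5, -2.0]), np.array([0.0, 1.0]))

    def test_duplicate_difficulties_rejected(self):
        with pytest.raises(ConfigurationError):
            make_guttman(np.array([0.0, 1.0]), np.array([0.5, 0.5]))


@pytest.fixture(scope="module")
def base():
    return simulate_responses(rasch_like_config(k=11, a=2.0, n=5000, seed=1))


class TestInjectors:
    def test_nonmonotone_peaks_in_middle_tercile(self, base):
        d = inject_nonmonotone_item(base, peak=0.0, width=0.5, seed=2)
        col = d.responses.values[:, -1]
        terciles = np.quantile(d.theta, [1 / 3, 2 / 3])
        low = col[d.theta < terciles[0]].mean()
        mid = col[(d.theta >= terciles[0]) & (d.theta < terciles[1])].mean()
        high = col[d.theta >= terciles[1]].mean()
        assert mid > low and mid > high
        # original items untouched
        np.testing.assert_array_equal(
            d.responses.values[:, :-1], base.responses.values
        )

    def test_nonmonotone_flat_limit(self, base):
        d = inject_nonmonotone_item(base, peak=0.0, width=1e6, seed=2)
        col = d.responses.values[:, -1]
        lo = col[d.theta < 0].mean()
        hi = col[d.theta >= 0].mean()
        assert abs(lo - hi) < 0.05  # flat response curve, noise only

    def test_intersecting_requires_strong_contrast(self, base):
        with pytest.raises(ConfigurationError):
            inject_intersecting_item(base, a_new=2.0, b_new=0.0, seed=3)

    def test_crossing_point_in_range(self, base):
        # a_new(theta - b_new) = a(theta - b) crosses inside [-3, 3]
        d = inject_intersecting_item(base, a_new=6.0, b_new=0.0, seed=3)
        assert d.responses.k == base.responses.k + 1
        a, b = 2.0, 0.5  # an original item
        theta_cross = (6.0 * 0.0 - a * b) / (6.0 - a)
        assert -3 < theta_cross < 3


class TestSurvey:
    def test_difficulty_calibration_roundtrip(self):
        for p in (0.005, 0.1, 0.5, 0.9):
            b = difficulty_for_popularity(p, a=2.0)
            assert marginal_popularity(2.0, b) == pytest.approx(p, abs=1e-8)
            assert oracles.quad_popularity(2.0, b) == pytest.approx(p, abs=1e-6)

    def test_survey_shape_and_popularity_span(self, survey_dataset):
        m = survey_dataset.responses
        assert m.k == 17
        assert m.n == 3810
        p = m.popularity
        assert p.min() < 0.01 and p.max() > 0.85

    def test_survey_reproducible(self):
        cfg = default_survey_config(500, seed=8)
        d1, d2 = simulate_survey(cfg), simulate_survey(cfg)
        np.testing.assert_array_equal(d1.responses.values, d2.responses.values)
        np.testing.assert_array_equal(d1.expenditure, d2.expenditure)

    def test_rare_item_constant_at_small_n_rejected(self):
        # the sub-1% luxury item is all-zero in a tiny sample and the
        # response-matrix invariant must catch it
        with pytest.raises(DegenerateDataError, match="constant"):
            simulate_survey(default_survey_config(200, seed=4))

    def test_writer_round_trips(self, tmp_path):
        import pandas as pd

        d = simulate_responses(rasch_like_config(k=5, n=60, seed=2, span=1.0))
        path = tmp_path / "households.csv"
        write_household_table(d, path, include_theta=True)
        df = pd.read_csv(path)
        assert list(df.columns[:5]) == list(d.responses.item_labels)
        assert {"expenditure", "theta"} <= set(df.columns)
        np.testing.assert_array_equal(
            df[list(d.responses.item_labels)].to_numpy(), d.responses.values
        )
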