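"""Loevinger H coefficients against brute-force and sampling oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import random_valid_matrix, rasch_like_config
from mokkensep import (
    DegenerateDataError,
    ResponseMatrix,
    compute_scalability,
    item_popularity,
    se_item_H,
    simulate_responses,
    strength_label,
    transposed_H,
)


class TestResponseMatrix:
    def test_rejects_constant_item(self):
        X = np.array([[1, 1], [1, 0], [1, 1]])
        with pytest.raises(DegenerateDataError, match="constant"):
            ResponseMatrix(X)

    def test_rejects_non_binary(self):
        with pytest.raises(DegenerateDataError):
            ResponseMatrix(np.array([[0, 2], [1, 0]]))

    def test_rejects_missing(self):
        with pytest.raises(DegenerateDataError):
            ResponseMatrix(np.array([[0.0, np.nan], [1.0, 0.0]]))

    def test_subset_keeps_labels(self):
        X = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]])
        m = ResponseMatrix(X, ("a", "b", "c"))
        sub = m.subset([2, 0])
        assert sub.item_labels == ("c", "a")
        assert np.array_equal(sub.values[:, 1], X[:, 0])


class TestItemPopularity:
    def test_direct_count(self):
        m = ResponseMatrix(np.array([[1, 0], [1, 1], [0, 0], [0, 1]]))
        stats = item_popularity(m)
        assert stats.popularity[0] == pytest.approx(0.5)

    def test_tie_rank_by_column_index(self):
        # both items at p = 0.5: rank order falls back to column index
        m = ResponseMatrix(np.array([[1, 0], [0, 1], [1, 0], [0, 1]]))
        assert list(item_popularity(m).rank_by_popularity) == [0, 1]


class TestPairCoefficients:
    def test_hand_counted_pair(self):
        # patterns (1,1) x2, (1,0) x4, (0,1) x1, (0,0) x3:
        # p_A = .6, p_B = .3 -> B harder, F = 1, E = 10 * .3 * .4 = 1.2
        rows = [(1, 1)] * 2 + [(1, 0)] * 4 + [(0, 1)] * 1 + [(0, 0)] * 3
        m = ResponseMatrix(np.array(rows))
        rep = compute_scalability(m)
        pair = rep.pair_table[0]
        assert pair.F_ij == 1
        assert pair.E_ij == pytest.approx(1.2)
        assert pair.H_ij == pytest.approx(1 - 1 / 1.2)

    def test_exact_independence_gives_zero(self):
        rows = [(1, 1)] * 25 + [(1, 0)] * 25 + [(0, 1)] * 25 + [(0, 0)] * 25
        rep = compute_scalability(ResponseMatrix(np.array(rows)))
        assert rep.pair_table[0].H_ij == pytest.approx(0.0, abs=1e-12)
        assert rep.scale_H == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_and_covariance_forms(self, rng):
        for _ in range(50):
            m = random_valid_matrix(rng)
            rep = compute_scalability(m, include_transpose=False)
            for pair in rep.pair_table:
                bf = oracles.brute_force_pair_H(m.values, pair.i, pair.j)
                cv = oracles.covariance_form_pair_H(m.values, pair.i, pair.j)
                assert pair.H_ij == pytest.approx(bf, abs=1e-12)
                assert pair.H_ij == pytest.approx(cv, abs=1e-12)
            assert rep.scale_H == pytest.approx(
                oracles.brute_force_scale_H(m.values), abs=1e-12
            )
            for i in range(m.k):
                assert rep.item_H[i] == pytest.approx(
                    oracles.brute_force_item_H(m.values, i), abs=1e-12
                )

    def test_item_H_bounded_by_pair_extremes(self, rng):
        # H_i is a ratio of sums, hence lies between the extreme H_ij
        for _ in range(25):
            m = random_valid_matrix(rng)
            rep = compute_scalability(m, include_transpose=False)
            for i in range(m.k):
                hij = [p.H_ij for p in rep.pair_table if i in (p.i, p.j)]
                assert min(hij) - 1e-12 <= rep.item_H[i] <= max(hij) + 1e-12

    def test_guttman_limit_all_ones(self, guttman_matrix):
        rep = compute_scalability(guttman_matrix)
        assert all(p.H_ij == 1.0 for p in rep.pair_table)
        assert np.all(rep.item_H == 1.0)
        assert rep.scale_H == 1.0
        assert rep.transposed_H == 1.0

    def test_row_permutation_invariance(self, rng):
        m = random_valid_matrix(rng)
        perm = rng.permutation(m.n)
        rep1 = compute_scalability(m, include_transpose=False)
        rep2 = compute_scalability(
            ResponseMatrix(m.values[perm]), include_transpose=False
        )
        assert rep1.scale_H == pytest.approx(rep2.scale_H, abs=1e-14)
        np.testing.assert_allclose(rep1.item_H, rep2.item_H, atol=1e-14)

    def test_monotone_convergence_to_guttman(self):
        # raising discrimination drives the data toward a Guttman
        # pattern, so H must climb toward 1
        hs = []
        for a in (0.5, 2.0, 8.0, 64.0):
            cfg = rasch_like_config(k=5, a=a, n=4000, seed=9, span=1.5)
            data = simulate_responses(cfg)
            hs.append(compute_scalability(data.responses,
                                          include_transpose=False).scale_H)
        assert hs == sorted(hs)
        assert hs[-1] > 0.95


class TestStrengthLabels:
    @pytest.mark.parametrize(
        "h,label",
        [(0.2, "unscalable"), (0.35, "weak"), (0.45, "medium"), (0.55, "strong")],
    )
    def test_cutoffs(self, h, label):
        assert strength_label(h) == label


class TestTransposedH:
    def test_equals_scale_H_of_transpose(self, rng):
        for _ in range(30):
            m = random_valid_matrix(rng)
            Xt = m.values.T
            keep = (Xt.sum(0) > 0) & (Xt.sum(0) < m.k)
            if keep.sum() < 2:
                continue
            assert transposed_H(m) == pytest.approx(
                oracles.brute_force_scale_H(Xt[:, keep]), abs=1e-12
            )

    def test_constant_household_dropped(self, caplog):
        X = np.array([[1, 1, 1], [1, 0, 1], [0, 1, 0], [0, 0, 1], [1, 1, 0]])
        m = ResponseMatrix(X)
        with caplog.at_level("INFO", logger="mokkensep.scalability"):
            ht = transposed_H(m)
        assert "dropped 1" in caplog.text
        keep = [1, 2, 3, 4]
        assert ht == pytest.approx(oracles.brute_force_scale_H(X.T[:, keep]), abs=1e-12)


class TestBootstrapSE:
    def test_identical_rows_degenerate(self):
        X = np.tile(np.array([[1, 0, 1]]), (20, 1))
        with pytest.raises(DegenerateDataError):
            ResponseMatrix(X)  # constant items already rejected upstream

    def test_se_matches_repeated_sampling_oracle(self):
        """Bootstrap SE of each H_i vs the SD of H_i over independently
        regenerated datasets from the same generating process.  The
        bootstrap SE is averaged over several datasets so the check
        targets the estimator, not one realisation's noise."""
        ses = []
        for s in range(10):
            cfg = rasch_like_config(k=11, a=2.0, n=3810, seed=7 + s)
            data = simulate_responses(cfg)
            ses.append(se_item_H(data.responses, n_boot=300, seed=7 + s))
        se = np.mean(np.vstack(ses), axis=0)
        hs = []
        for s in range(500):
            d = simulate_responses(
                rasch_like_config(k=11, a=2.0, n=3810, seed=10_000 + s)
            )
            hs.append(
                compute_scalability(d.responses, include_transpose=False).item_H
            )
        true_sd = np.std(np.vstack(hs), axis=0, ddof=1)
        assert np.all(np.abs(se - true_sd) / true_sd < 0.15)

    def test_deterministic_given_seed(self, rasch_dataset):
        m = rasch_dataset.responses
        se1 = se_item_H(m, n_boot=200, seed=3)
        se2 = se_item_H(m, n_boot=200, seed=3)
        np.testing.assert_array_equal(se1, se2)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_H_never_exceeds_one(seed_val):
    rng = np.random.default_rng(seed_val)
    m = random_valid_matrix(rng, n_max=30, k_max=4)
    rep = compute_scalability(m, include_transpose=False)
    assert all(p.H_ij <= 1.0 + 1e-12 for p in rep.pair_table)
    assert rep.scale_H <= 1.0 + 1e-12
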