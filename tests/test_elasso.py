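"""eLASSO estimation: penalized paths, EBIC selection, symmetrization, recovery."""

import numpy as np
import pytest

from symptomnet.data_model import BinaryMatrix
from symptomnet.elasso import (
    ebic,
    fit_ising,
    l1_logistic_path,
    lambda_max,
    penalized_objective,
    select_per_node,
    symmetrize,
)
from symptomnet.synthetic import sample_ising_exact
from symptomnet.validation import l1_reference_fit
from symptomnet.ising import IsingNetwork


def logistic_sample(rng, n, m, beta0, beta):
    X = (rng.random((n, m)) < 0.4).astype(float)
    eta = beta0 + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return y, X


class TestEbic:
    def test_hand_evaluated_formula(self):
        # 200 + 3 ln 1000 + 1.5 ln 9 = 224.019...
        val = ebic(-100.0, 3, 1000, 10, 0.25)
        assert val == pytest.approx(200 + 3 * np.log(1000) + 1.5 * np.log(9))
        assert val == pytest.approx(224.019, abs=5e-3)

    def test_k_zero_is_deviance_only(self):
        assert ebic(-50.0, 0, 100, 5, 0.25) == pytest.approx(100.0)

    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(-50.0, 2, 100, 5, 0.0) == pytest.approx(100 + 2 * np.log(100))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ebic(-1.0, -1, 10, 5, 0.25)
        with pytest.raises(ValueError):
            ebic(-1.0, 1, 0, 5, 0.25)


class TestPath:
    def test_lambda_max_endpoint_is_null_model(self, rng):
        y, X = logistic_sample(rng, 300, 4, -0.5, np.array([1.0, 0, -0.8, 0]))
        res = l1_logistic_path(y, X)
        assert res["lambdas"][0] == pytest.approx(lambda_max(X, y))
        assert np.all(res["coefficients"][0] == 0.0)
        assert res["intercepts"][0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_matches_reference_convex_optimizer(self, rng):
        y, X = logistic_sample(rng, 200, 4, -0.5, np.array([1.2, 0, -0.8, 0]))
        res = l1_logistic_path(y, X)
        for li in (10, 50, 90):
            lam = res["lambdas"][li]
            mine = penalized_objective(res["intercepts"][li], res["coefficients"][li], y, X, lam)
            _, _, ref = l1_reference_fit(y, X, lam)
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_single_class_error_names_node(self):
        X = np.zeros((10, 2))
        X[:5, 0] = 1
        with pytest.raises(ValueError, match="H3"):
            l1_logistic_path(np.ones(10), X, node_label="H3")

    def test_constant_column_forced_zero_with_warning(self, rng):
        y, X = logistic_sample(rng, 200, 3, 0.0, np.array([1.0, 0, 0]))
        X[:, 2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = l1_logistic_path(y, X)
        assert np.all(res["coefficients"][:, 2] == 0.0)

    def test_nonzero_counts_nondecreasing(self, rng):
        y, X = logistic_sample(rng, 400, 5, -0.3, np.array([1.0, 0.9, -0.8, 0, 0]))
        res = l1_logistic_path(y, X)
        k = res["nonzero_counts"]
        # monotone along decreasing lambda up to occasional numerical ties
        assert np.sum(np.diff(k) < 0) == 0

    def test_lambda_floor_guards_separable_data(self):
        rng = np.random.default_rng(0)
        X = (rng.random((200, 2)) < 0.5).astype(float)
        y = X[:, 0].copy()  # perfectly separable: MLE diverges
        res = l1_logistic_path(y, X)
        assert np.isfinite(res["coefficients"]).all()
        assert np.abs(res["coefficients"]).max() <= 15.0

    def test_separation_guard_caps_coefficients(self):
        rng = np.random.default_rng(0)
        X = (rng.random((200, 2)) < 0.5).astype(float)
        y = X[:, 0].copy()
        # push the penalty far below the default floor to force divergence
        grid = np.geomspace(1.0, 1e-9, 30) * lambda_max(X, y)
        with pytest.warns(UserWarning, match="separation"):
            res = l1_logistic_path(y, X, lambda_grid=grid)
        assert np.abs(res["coefficients"]).max() <= 15.0


class TestSelection:
    def test_single_lambda_path(self):
        assert select_per_node({"ebic_values": np.array([3.2])}) == 0

    def test_tie_breaks_to_sparser(self):
        assert select_per_node({"ebic_values": np.array([5.0, 7.0, 5.0])}) == 0

    def test_interior_minimum(self):
        assert select_per_node({"ebic_values": np.array([9.0, 4.0, 6.0])}) == 1


class TestSymmetrize:
    def test_and_requires_both_nonzero(self):
        b = np.array([[0.0, 0.4], [0.0, 0.0]])
        assert symmetrize(b, "AND")[0, 1] == 0.0

    def test_and_mean_convention(self):
        b = np.array([[0.0, 0.4], [0.6, 0.0]])
        w = symmetrize(b, "AND")
        assert w[0, 1] == pytest.approx(0.5)
        assert w[1, 0] == pytest.approx(0.5)

    def test_or_mean_includes_zero(self):
        b = np.array([[0.0, 0.4], [0.0, 0.0]])
        assert symmetrize(b, "OR")[0, 1] == pytest.approx(0.2)

    def test_and_subset_of_or(self, rng):
        for _ in range(20):
            b = rng.normal(0, 1, (5, 5)) * (rng.random((5, 5)) < 0.5)
            np.fill_diagonal(b, 0.0)
            a = symmetrize(b, "AND") != 0
            o = symmetrize(b, "OR") != 0
            assert np.all(o[a])


class TestFit:
    def test_planted_single_edge_recovered(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.2
        net = IsingNetwork(np.full(5, -1.0), w, tuple("abcde"))
        data = sample_ising_exact(net, 5000, seed=3)
        fit = fit_ising(data)
        est = fit.network.weights != 0
        expected = np.zeros((5, 5), dtype=bool)
        expected[0, 1] = expected[1, 0] = True
        assert np.array_equal(est, expected)
        assert fit.network.weights[0, 1] == pytest.approx(1.2, abs=0.25)

    def test_row_permutation_invariance(self, pair_net):
        data = sample_ising_exact(pair_net, 600, seed=4)
        perm = np.random.default_rng(0).permutation(600)
        fit_a = fit_ising(data)
        fit_b = fit_ising(BinaryMatrix(data.values[perm], data.node_labels))
        # identical edge set; weights equal up to float summation order
        np.testing.assert_array_equal(
            fit_a.network.weights != 0, fit_b.network.weights != 0
        )
        np.testing.assert_allclose(fit_a.network.weights, fit_b.network.weights, atol=1e-10)
        np.testing.assert_allclose(fit_a.network.thresholds, fit_b.network.thresholds, atol=1e-10)

    def test_gamma_monotone_in_edge_count(self, pair_net):
        data = sample_ising_exact(pair_net, 800, seed=5)
        counts = [fit_ising(data, gamma=g).network.n_edges for g in (0.0, 0.25, 0.5, 1.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_and_edges_subset_of_or_edges(self, pair_net):
        data = sample_ising_exact(pair_net, 800, seed=6)
        and_e = fit_ising(data, rule="AND").network.weights != 0
        or_e = fit_ising(data, rule="OR").network.weights != 0
        assert np.all(or_e[and_e])

    def test_constant_column_error_lists_labels(self):
        vals = np.zeros((50, 3), dtype=np.int8)
        vals[:, 0] = np.arange(50) % 2
        vals[:, 2] = (np.arange(50) // 2) % 2
        data = BinaryMatrix(vals, ("a", "b", "c"))
        with pytest.raises(ValueError, match="b"):
            fit_ising(data)

    def test_thresholds_are_selected_intercepts(self, pair_net):
        data = sample_ising_exact(pair_net, 500, seed=7)
        fit = fit_ising(data)
        for path in fit.paths:
            assert fit.network.thresholds[path.node_index] == path.selected_intercept
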