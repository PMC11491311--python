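"""Samplers, threshold calibration and the cohort generator round trip."""

import numpy as np
import pytest

from symptomnet.data_model import build_binary_matrix, impute_median
from symptomnet.ising import IsingNetwork, exact_marginals
from symptomnet.synthetic import (
    CohortSpec,
    calibrate_thresholds,
    default_cohort_spec,
    generate_cohort,
    sample_ising_exact,
    sample_ising_gibbs,
)
from symptomnet.validation import chisquare_gof


def coupled_net(p=4, beta=0.8, tau=-0.5):
    w = np.zeros((p, p))
    for i in range(p - 1):
        w[i, i + 1] = w[i + 1, i] = beta
    return IsingNetwork(np.full(p, tau), w, tuple(f"N{i}" for i in range(p)))


class TestExactSampler:
    def test_single_node_marginal(self):
        net = IsingNetwork(np.zeros(1), np.zeros((1, 1)), ("a",))
        x = sample_ising_exact(net, 100_000, seed=1)
        assert abs(x.values.mean() - 0.5) < 3 * np.sqrt(0.25 / 100_000)

    def test_two_node_joint_matches_hand_enumeration(self):
        w = np.log(2) * (np.ones((2, 2)) - np.eye(2))
        net = IsingNetwork(np.zeros(2), w, ("a", "b"))
        x = sample_ising_exact(net, 100_000, seed=2)
        p11 = (x.values.sum(1) == 2).mean()
        se = np.sqrt(0.4 * 0.6 / 100_000)
        assert abs(p11 - 0.4) < 3 * se

    def test_seed_determinism(self):
        net = coupled_net()
        a = sample_ising_exact(net, 500, seed=7)
        b = sample_ising_exact(net, 500, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_large_p_rejected(self):
        p = 18
        net = IsingNetwork(np.zeros(p), np.zeros((p, p)), tuple(f"N{i}" for i in range(p)))
        with pytest.raises(ValueError, match="exact"):
            sample_ising_exact(net, 10, seed=0)


class TestGibbsSampler:
    def test_matches_exact_distribution(self):
        net = coupled_net(p=4, beta=1.0)
        draws = sample_ising_gibbs(net, 20_000, seed=3)
        assert chisquare_gof(draws.values, net) > 0.01

    def test_independence_limit(self):
        tau = np.array([-1.0, 0.0, 0.5])
        net = IsingNetwork(tau, np.zeros((3, 3)), ("a", "b", "c"))
        draws = sample_ising_gibbs(net, 20_000, seed=4)
        expected = 1 / (1 + np.exp(-tau))
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert np.all(np.abs(draws.values.mean(0) - expected) < 4 * se)

    def test_thinning_invariance_of_marginals(self):
        net = coupled_net(p=3, beta=1.2)
        m1 = sample_ising_gibbs(net, 10_000, thin=5, seed=5).values.mean(0)
        m2 = sample_ising_gibbs(net, 10_000, thin=10, seed=5).values.mean(0)
        assert np.all(np.abs(m1 - m2) < 4 * np.sqrt(0.25 / 10_000) * 2)

    def test_seed_determinism(self):
        net = coupled_net()
        a = sample_ising_gibbs(net, 200, seed=6)
        b = sample_ising_gibbs(net, 200, seed=6)
        np.testing.assert_array_equal(a.values, b.values)


class TestCalibration:
    def test_hits_targets_on_coupled_network(self):
        net = coupled_net(p=5, beta=0.9)
        targets = np.array([0.15, 0.3, 0.45, 0.25, 0.1])
        tau = calibrate_thresholds(net.weights, targets, net.node_labels)
        realized = exact_marginals(IsingNetwork(tau, net.weights, net.node_labels))
        assert np.all(np.abs(realized - targets) <= 0.015)

    def test_threshold_marginal_monotonicity(self):
        net = coupled_net(p=4, beta=0.8)
        base = exact_marginals(net)
        for i in range(4):
            tau2 = net.thresholds.copy()
            tau2[i] += 0.7
            bumped = exact_marginals(IsingNetwork(tau2, net.weights, net.node_labels))
            assert bumped[i] > base[i]

    def test_unreachable_target_names_node(self):
        net = coupled_net(p=3, beta=0.5)
        with pytest.raises(RuntimeError, match="N"):
            calibrate_thresholds(
                net.weights, np.array([0.2, 0.5, 0.8]), net.node_labels,
                max_iter=1, tol=1e-6,
            )

    def test_targets_must_be_interior(self):
        net = coupled_net(p=3)
        with pytest.raises(ValueError):
            calibrate_thresholds(net.weights, np.array([0.0, 0.5, 0.5]), net.node_labels)


class TestGenerateCohort:
    def test_round_trip_binary_layer(self, small_cohort):
        responses, truth = small_cohort
        mat = build_binary_matrix(impute_median(responses))
        assert np.array_equal(mat.values, truth["binary"].values)

    def test_round_trip_with_stochastic_ordinalization(self):
        spec = default_cohort_spec(n=200, seed=3, missing_rate=0.0, ordinal_jitter=True)
        responses, truth = generate_cohort(spec)
        mat = build_binary_matrix(impute_median(responses))
        assert np.array_equal(mat.values, truth["binary"].values)

    def test_missingness_rate_close_to_requested(self):
        spec = default_cohort_spec(n=800, seed=4, missing_rate=0.039)
        responses, _ = generate_cohort(spec)
        from symptomnet.instruments import ORDINAL_ITEM_COLUMNS

        frac = responses[list(ORDINAL_ITEM_COLUMNS)].isna().to_numpy().mean()
        assert 0.03 < frac < 0.05

    def test_missing_rate_capped_at_observed_maximum(self):
        with pytest.raises(ValueError, match="missing_rate"):
            default_cohort_spec(n=10, missing_rate=0.2)

    def test_determinism(self):
        a, _ = generate_cohort(default_cohort_spec(n=100, seed=5, missing_rate=0.01))
        b, _ = generate_cohort(default_cohort_spec(n=100, seed=5, missing_rate=0.01))
        assert a.equals(b)

    def test_sex_and_alcohol_consistent_with_al_node(self, small_cohort):
        responses, truth = small_cohort
        al = truth["binary"].values[:, list(truth["binary"].node_labels).index("AL")]
        male = responses["sex"] == "male"
        units = responses["alcohol_units_week"]
        cut = np.where(male, 21, 14)
        np.testing.assert_array_equal(al == 1, (units > cut).to_numpy())
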