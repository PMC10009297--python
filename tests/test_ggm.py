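"""GGM estimation: partials, edge tests, constrained fit, recursive pruning."""

import numpy as np
import pytest
from scipy import stats

from resilnet import (
    CorrelationEstimate,
    TrueNetworkSpec,
    build_true_precision,
    partials_from_precision,
    sample_ordinal_group,
    default_thresholds,
    estimate_correlations,
    saturated_partials,
    edge_pvalues,
    fit_constrained_ggm,
    fit_indices,
    prune_network,
    estimate_network,
)
from conftest import brute_force_constrained_mle, random_correlation, true_edge_set


class TestEstimateCorrelations:
    def test_perfect_correlation(self):
        x = np.arange(30.0)
        X = np.column_stack([x, 2 * x + 1, np.random.default_rng(0).standard_normal(30)])
        R = estimate_correlations(X).matrix
        assert R[0, 1] == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        X = np.random.default_rng(1).standard_normal((20000, 5))
        R = estimate_correlations(X).matrix
        assert np.abs(R[~np.eye(5, dtype=bool)]).max() < 0.03

    def test_symmetric_exactly(self):
        X = np.random.default_rng(2).standard_normal((100, 6))
        R = estimate_correlations(X).matrix
        assert np.array_equal(R, R.T)

    def test_zero_variance_item_named(self):
        X = np.random.default_rng(3).standard_normal((50, 4))
        X[:, 2] = 7.0
        with pytest.raises(ValueError, match="2"):
            estimate_correlations(X)

    def test_spearman_matches_rank_pearson(self):
        X = np.random.default_rng(4).standard_normal((200, 3))
        Rs = estimate_correlations(X, method="spearman").matrix
        ranks = np.argsort(np.argsort(X, axis=0), axis=0).astype(float)
        assert np.allclose(Rs, np.corrcoef(ranks.T), atol=1e-10)

    def test_polychoric_recovers_latent_correlation(self):
        K = np.linalg.inv(np.array([[1.0, 0.5], [0.5, 1.0]]))
        X = sample_ordinal_group(K, 3000, default_thresholds(), seed=5)
        R = estimate_correlations(X, method="polychoric").matrix
        assert R[0, 1] == pytest.approx(0.5, abs=0.05)
        # ordinal discretization attenuates the raw Pearson correlation
        assert estimate_correlations(X).matrix[0, 1] < R[0, 1]


class TestSaturatedPartials:
    def test_trivariate_equicorrelation_closed_form(self):
        for r in (0.2, 0.5, 0.7):
            R = np.full((3, 3), r)
            np.fill_diagonal(R, 1.0)
            W = saturated_partials(R)
            expected = r / (1 + r)
            off = W[~np.eye(3, dtype=bool)]
            assert np.abs(off - expected).max() < 1e-10

    def test_diagonal_correlation_gives_zero_partials(self):
        assert np.allclose(saturated_partials(np.eye(4)), 0.0)

    def test_bivariate_identity(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert saturated_partials(R)[0, 1] == pytest.approx(0.4, abs=1e-12)


class TestEdgePvalues:
    def test_zero_partial_p_one(self):
        W = np.zeros((3, 3))
        assert np.all(edge_pvalues(W, 100, 3) == 1.0)

    def test_closed_form_fisher_z(self):
        W = np.zeros((27, 27))
        W[0, 1] = W[1, 0] = 0.2
        pv = edge_pvalues(W, 500, 27)
        z = np.arctanh(0.2) * np.sqrt(500 - 27 - 1)
        assert pv[0, 1] == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)
        assert pv[0, 1] < 0.001

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(-0.3, 0.3, (5, 5))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        pv = edge_pvalues(W, 200, 5)
        assert np.array_equal(pv, pv.T)
        assert np.all(np.diag(pv) == 1.0)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            edge_pvalues(np.zeros((10, 10)), 11, 10)


class TestFitConstrainedGGM:
    def test_saturated_returns_s_exactly(self):
        S = random_correlation(4, seed=1)
        fit = fit_constrained_ggm(S, [], 100)
        assert np.array_equal(fit.sigma, S)

    def test_single_constraint_three_variables(self):
        S = random_correlation(3, seed=2)
        fit = fit_constrained_ggm(S, [(0, 2)], 100)
        assert abs(fit.precision[0, 2]) < 1e-8
        assert abs(fit.sigma[0, 1] - S[0, 1]) < 1e-7
        assert abs(fit.sigma[1, 2] - S[1, 2]) < 1e-7
        assert np.allclose(np.diag(fit.sigma), np.diag(S))

    def test_independence_model_gives_diagonal(self):
        S = random_correlation(4, seed=3)
        all_pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        fit = fit_constrained_ggm(S, all_pairs, 100)
        assert np.allclose(fit.sigma, np.diag(np.diag(S)), atol=1e-10)

    @pytest.mark.parametrize("p,seed", [(3, 10), (4, 11), (5, 12)])
    def test_matches_brute_force_optimizer(self, p, seed):
        S = random_correlation(p, seed=seed)
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        zero = [pairs[0], pairs[-1]]
        fit = fit_constrained_ggm(S, zero, 200)
        sigma_bf = brute_force_constrained_mle(S, zero)
        assert np.abs(fit.sigma - sigma_bf).max() < 1e-5

    def test_sigma_matches_s_on_retained_pairs(self, study_spec):
        K = build_true_precision(study_spec)
        X = sample_ordinal_group(K, 1500, default_thresholds(), seed=6)
        S = estimate_correlations(X).matrix
        p = S.shape[0]
        rng = np.random.default_rng(7)
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        zero = [pairs[k] for k in rng.choice(len(pairs), 200, replace=False)]
        fit = fit_constrained_ggm(S, zero, 1500)
        retained = [pr for pr in pairs if pr not in set(zero)]
        err = max(abs(fit.sigma[i, j] - S[i, j]) for (i, j) in retained)
        assert err < 1e-7
        assert all(abs(fit.precision[i, j]) == 0.0 for (i, j) in zero)


class TestFitIndices:
    def test_saturated_model_perfect_fit(self):
        S = random_correlation(4, seed=20)
        fit = fit_constrained_ggm(S, [], 300)
        fi = fit_indices(fit.loglik, S, fit.sigma, 300, df=0, n_retained_edges=6)
        assert fi.chi_square == pytest.approx(0.0, abs=1e-8)
        assert fi.cfi == 1.0 and fi.rmsea == 0.0 and fi.tli == 1.0

    def test_bivariate_pruned_edge_closed_form(self):
        r, n = 0.5, 400
        S = np.array([[1.0, r], [r, 1.0]])
        fit = fit_constrained_ggm(S, [(0, 1)], n)
        fi = fit_indices(fit.loglik, S, fit.sigma, n, df=1, n_retained_edges=0)
        F = -np.log(1 - r**2)
        assert fi.chi_square == pytest.approx((n - 1) * F, rel=1e-12)

    def test_independence_fit_to_independent_data(self):
        rng = np.random.default_rng(21)
        n, p = 50000, 5
        S = np.corrcoef(rng.standard_normal((n, p)).T)
        all_pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        fit = fit_constrained_ggm(S, all_pairs, n)
        fi = fit_indices(fit.loglik, S, fit.sigma, n, df=len(all_pairs), n_retained_edges=0)
        assert fi.chi_square / fi.df == pytest.approx(1.0, abs=0.6)

    def test_bic_penalizes_parameters(self):
        S = random_correlation(4, seed=22)
        sat = fit_constrained_ggm(S, [], 500)
        ind = fit_constrained_ggm(S, [(i, j) for i in range(4) for j in range(i + 1, 4)], 500)
        fi_sat = fit_indices(sat.loglik, S, sat.sigma, 500, 0, 6)
        fi_ind = fit_indices(ind.loglik, S, ind.sigma, 500, 6, 0)
        # saturated always attains the higher likelihood
        assert fi_sat.log_likelihood >= fi_ind.log_likelihood


class TestPruneNetwork:
    def test_alpha_one_prunes_nothing(self):
        X = np.random.default_rng(30).standard_normal((200, 5))
        corr = estimate_correlations(X)
        net = prune_network(corr, alpha=1.0)
        assert net.zero_pattern == frozenset()
        assert net.fit.df == 0
        assert np.allclose(net.weights, saturated_partials(corr), atol=1e-10)

    def test_type_one_error_rate_under_empty_graph(self):
        # data from mutually independent items: retained-edge fraction ~ alpha
        p, n, reps = 10, 1000, 100
        n_pairs = p * (p - 1) // 2
        rng = np.random.default_rng(31)
        kept = 0
        for _ in range(reps):
            X = rng.standard_normal((n, p))
            net = prune_network(estimate_correlations(X), alpha=0.05)
            kept += len(net.edges())
        frac = kept / (reps * n_pairs)
        assert abs(frac - 0.05) < 0.03

    def test_recovery_of_known_sparse_network(self, study_spec):
        spec = TrueNetworkSpec(
            within_density=0.15, bridge_count=8, negative_bridge_count=1,
            weight_range=(0.15, 0.35), seed=40,
        )
        K = build_true_precision(spec)
        true = true_edge_set(K)
        X = sample_ordinal_group(K, 2000, default_thresholds(), seed=41)
        net = estimate_network(X)
        est = set(net.edges())
        assert len(est & true) / len(true) >= 0.90

    def test_invariant_to_item_order(self):
        spec = TrueNetworkSpec(n_items_a=3, n_items_b=4, within_density=0.4,
                               bridge_count=2, negative_bridge_count=0, seed=42)
        K = build_true_precision(spec)
        X = sample_ordinal_group(K, 800, default_thresholds(), seed=43)
        perm = np.random.default_rng(44).permutation(7)
        net1 = estimate_network(X)
        net2 = estimate_network(X[:, perm])
        # column k of the permuted data is original item perm[k]
        edges1 = {frozenset((i, j)) for (i, j) in net1.edges()}
        edges2 = {frozenset((int(perm[i]), int(perm[j]))) for (i, j) in net2.edges()}
        assert edges1 == edges2
        for (i, j) in net2.edges():
            assert net2.weights[i, j] == pytest.approx(
                net1.weights[perm[i], perm[j]], abs=1e-6
            )

    def test_monotonicity_of_first_round(self):
        X = np.random.default_rng(45).standard_normal((300, 8))
        corr = estimate_correlations(X)
        pv = edge_pvalues(saturated_partials(corr), corr.n, corr.p)
        kept_strict = {(i, j) for i in range(8) for j in range(i + 1, 8) if pv[i, j] < 0.01}
        kept_loose = {(i, j) for i in range(8) for j in range(i + 1, 8) if pv[i, j] < 0.10}
        assert kept_strict <= kept_loose

    def test_never_readds_pruned_edges(self):
        spec = TrueNetworkSpec(seed=46)
        K = build_true_precision(spec)
        X = sample_ordinal_group(K, 600, default_thresholds(), seed=47)
        corr = estimate_correlations(X)
        net = prune_network(corr)
        # every pruned pair has exactly zero weight in the final model
        for (i, j) in net.zero_pattern:
            assert net.weights[i, j] == 0.0
        assert net.iterations >= 1
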