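"""OLS baseline and network autocorrelation model fitting."""

import numpy as np
import pytest

import friendnet as fn
from friendnet.models import fits_table, gaussian_loglik, profile_loglik

from conftest import random_weight_matrix


@pytest.fixture(scope="module")
def lag_data():
    from friendnet.experiments import simulate_lag_dataset

    _, y, X, W, _ = simulate_lag_dataset(5, rho=0.25, n_schools=8)
    return y, X, W


class TestOLS:
    def test_intercept_only_is_mean(self):
        rng = np.random.default_rng(0)
        y = rng.normal(50, 5, 40)
        clusters = np.repeat(np.arange(4), 10)
        fit = fn.fit_ols(y, np.ones((40, 1)), clusters)
        assert fit.beta[0] == pytest.approx(y.mean())

    def test_cluster_sandwich_hand_oracle(self):
        # one observation per cluster: the cluster sandwich equals the HC0
        # estimator times G/(G-1)*(n-1)/(n-k); verified on a 6-point set
        y = np.array([1.0, 2.0, 4.0, 3.0, 6.0, 5.0])
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        X = np.column_stack([np.ones(6), x])
        fit = fn.fit_ols(y, X, np.arange(6))
        bread = np.linalg.inv(X.T @ X)
        u = fit.residuals
        meat = X.T @ np.diag(u**2) @ X
        factor = (6 / 5) * (5 / 4)
        expect = factor * bread @ meat @ bread
        np.testing.assert_allclose(fit.vcov_cluster, expect, rtol=1e-10)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ [1.0, 2.0] + rng.normal(size=30)
        clusters = np.repeat(np.arange(5), 6)
        f1 = fn.fit_ols(y, X, clusters)
        f2 = fn.fit_ols(np.tile(y, 2), np.tile(X, (2, 1)), np.tile(clusters, 2))
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-12)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
        y = rng.normal(size=50)
        fit = fn.fit_ols(y, X, np.repeat(np.arange(5), 10))
        np.testing.assert_allclose(X.T @ fit.residuals, 0.0, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(ValueError, match="collinear"):
            fn.fit_ols(np.random.default_rng(0).normal(size=20), X,
                       np.repeat(np.arange(4), 5), names=["const", "a", "b"])

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="cluster"):
            fn.fit_ols(np.ones(10), np.ones((10, 1)), np.zeros(10))


class TestProfileLoglik:
    def test_rho_zero_equals_ols_loglik(self, lag_data):
        y, X, W = lag_data
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert profile_loglik(0.0, y, X, W) == pytest.approx(
            gaussian_loglik(y - X @ beta), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_dense_determinant_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        W = random_weight_matrix(rng, n, p_edge=0.5)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        lo, hi = W.feasible_interval()
        for rho in np.linspace(lo + 0.05, hi - 0.05, 7):
            z = y - rho * (W.w @ y)
            beta, *_ = np.linalg.lstsq(X, z, rcond=None)
            rss = float((z - X @ beta) @ (z - X @ beta))
            s2 = rss / n
            direct = (
                -0.5 * n * (np.log(2 * np.pi) + np.log(s2) + 1.0)
                + np.log(abs(np.linalg.det(np.eye(n) - rho * W.w)))
            )
            assert profile_loglik(rho, y, X, W) == pytest.approx(direct, abs=1e-9)

    def test_logdet_eigenvalue_identity(self):
        rng = np.random.default_rng(9)
        W = random_weight_matrix(rng, 10, p_edge=0.4)
        lam = W.eigenvalues()
        for rho in [-0.5, -0.1, 0.3, 0.7]:
            lhs = float(np.sum(np.log(np.abs(1 - rho * lam))))
            rhs = np.log(abs(np.linalg.det(np.eye(10) - rho * W.w)))
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_singularity_error(self):
        w = fn.WeightMatrix(
            np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"], ["s", "s"]
        ).standardise()
        y = np.array([1.0, 2.0])
        X = np.ones((2, 1))
        with pytest.raises(ValueError, match="singular"):
            profile_loglik(1.0, y, X, w)


class TestNetworkFit:
    def test_nesting_reproduces_ols(self, lag_data):
        y, X, W = lag_data
        clusters = W.schools
        ols = fn.fit_ols(y, X, clusters)
        net = fn.fit_network_model(y, X, W, rho_fixed=0.0)
        np.testing.assert_allclose(net.beta, ols.beta, atol=1e-8)
        assert net.loglik == pytest.approx(ols.loglik, abs=1e-9)
        assert net.aic - ols.aic == pytest.approx(2.0, abs=1e-9)

    def test_grid_search_agrees_with_optimiser(self, lag_data):
        y, X, W = lag_data
        fit = fn.fit_network_model(y, X, W)
        lo, hi = fit.feasible_interval
        grid = np.arange(lo + 1e-3, hi - 1e-3, 1e-4)
        lls = [profile_loglik(r, y, X, W) for r in grid]
        assert abs(grid[int(np.argmax(lls))] - fit.rho) < 1e-3

    def test_optimum_dominates_grid(self, lag_data):
        y, X, W = lag_data
        fit = fn.fit_network_model(y, X, W)
        ll_star = profile_loglik(fit.rho, y, X, W)
        for r in np.linspace(fit.feasible_interval[0] + 0.01, fit.feasible_interval[1] - 0.01, 25):
            assert ll_star >= profile_loglik(r, y, X, W) - 1e-9

    def test_reordering_invariance(self, lag_data):
        y, X, W = lag_data
        rng = np.random.default_rng(0)
        perm = rng.permutation(W.n)
        W2 = fn.WeightMatrix(
            W.w[np.ix_(perm, perm)], [W.ids[i] for i in perm], W.schools[perm],
            standardised=True,
        )
        f1 = fn.fit_network_model(y, X, W, compute_vcov=False)
        f2 = fn.fit_network_model(y[perm], X[perm], W2, compute_vcov=False)
        assert f1.rho == pytest.approx(f2.rho, abs=1e-6)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-6)

    def test_unstandardised_w_rejected(self, lag_data):
        y, X, W = lag_data
        raw = fn.WeightMatrix(W.w * 2, W.ids, W.schools, standardised=False)
        with pytest.raises(ValueError, match="standardised"):
            fn.fit_network_model(y, X, raw)

    def test_rho_recovery_single_large_replicate(self):
        from friendnet.experiments import simulate_lag_dataset

        _, y, X, W, _ = simulate_lag_dataset(11, rho=0.2)
        fit = fn.fit_network_model(y, X, W)
        assert fit.converged
        assert fit.feasible_interval[0] < fit.rho < fit.feasible_interval[1]
        assert abs(fit.rho - 0.2) < 3 * fit.se_rho + 0.03
        assert fit.sigma2 > 0


class TestAIC:
    def test_model_aic_definition(self, lag_data):
        y, X, W = lag_data
        fit = fn.fit_network_model(y, X, W)
        assert fn.model_aic(fit) == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.k == X.shape[1] + 2

    def test_network_beats_ols_under_dependence(self):
        from friendnet.experiments import simulate_lag_dataset

        wins = 0
        for seed in range(10):
            _, y, X, W, _ = simulate_lag_dataset(100 + seed, rho=0.3, n_schools=8)
            ols = fn.fit_ols(y, X, W.schools)
            net = fn.fit_network_model(y, X, W, compute_vcov=False)
            wins += net.aic < ols.aic
        assert wins >= 9

    def test_shift_invariance_of_aic_difference(self, lag_data):
        y, X, W = lag_data
        ols1 = fn.fit_ols(y, X, W.schools)
        net1 = fn.fit_network_model(y, X, W, compute_vcov=False)
        ols2 = fn.fit_ols(y + 100.0, X, W.schools)
        net2 = fn.fit_network_model(y + 100.0, X, W, compute_vcov=False)
        # the intercept absorbs the shift in the baseline; the lag model's
        # shift also passes through (I - rho W), so the difference moves
        # only within optimisation tolerance
        assert (net1.aic - ols1.aic) == pytest.approx(net2.aic - ols2.aic, abs=0.1)

    def test_fits_table_shape(self, lag_data):
        y, X, W = lag_data
        names = ["const", "x1", "x2", "x3"][: X.shape[1]]
        ols = fn.fit_ols(y, X, W.schools, names=names)
        net = fn.fit_network_model(y, X, W, names=names)
        tbl = fits_table(ols, net)
        assert {"baseline_ols", "network"} == set(tbl["model"])
        assert "network_dependence" in tbl["term"].to_list()
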