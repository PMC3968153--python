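import numpy as np
import pytest
from scipy import optimize, stats

from rvlrt.data_io import GenotypeMatrix
from rvlrt.vc_lrt import test_set as vc_test_set
from rvlrt.vc_lrt import (LambdaGrid, ProfiledLikelihood, SpectralBasis,
                          chibar_pvalue, default_lambda_grid,
                          maximize_over_lambda, profile_ml_loglik,
                          profile_reml_loglik, pvalue_from_null, simulate_null,
                          spectral_basis_kernel, spectral_basis_mixed)
from rvlrt.weights_kernels import (KernelMatrix, beta_maf_weights,
                                   kernel_sqrt, null_projection,
                                   weighted_linear_kernel)


def make_instance(rng, n, m, p_cov=2, freq=0.15):
    from conftest import random_genotypes

    g = random_genotypes(rng, n, m, p=freq)
    w = beta_maf_weights(g.maf)
    X = rng.standard_normal((n, p_cov)) if p_cov else None
    y = rng.standard_normal(n)
    proj = null_projection(X, n=n)
    return g, w, X, y, proj


def dense_ml(lam, y, Xd, C):
    n = len(y)
    V = np.eye(n) + lam * C
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(Xd.T @ Vi @ Xd, Xd.T @ Vi @ y)
    r = y - Xd @ b
    return -0.5 * n * np.log(r @ Vi @ r) - 0.5 * np.linalg.slogdet(V)[1]


def dense_reml(lam, y, Xd, C):
    n, p1 = Xd.shape
    V = np.eye(n) + lam * C
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(Xd.T @ Vi @ Xd, Xd.T @ Vi @ y)
    r = y - Xd @ b
    return (-0.5 * (n - p1) * np.log(r @ Vi @ r)
            - 0.5 * np.linalg.slogdet(V)[1]
            - 0.5 * np.linalg.slogdet(Xd.T @ Vi @ Xd)[1])


class TestSpectralBasis:
    def test_single_variant_scalars(self, rng):
        g, w, X, y, proj = make_instance(rng, 30, 1)
        basis = spectral_basis_mixed(g, w, proj)
        gv = g.counts[:, 0]
        assert basis.xi[0] == pytest.approx(w.scaled[0] ** 2 * gv @ gv)
        assert basis.mu[0] == pytest.approx(w.scaled[0] ** 2 * gv @ proj.P0 @ gv)
        assert basis.K_active == 1

    def test_trace_identity_and_ordering(self, rng):
        for _ in range(5):
            g, w, X, y, proj = make_instance(rng, 20, 4)
            basis = spectral_basis_mixed(g, w, proj)
            K = weighted_linear_kernel(g, w).values
            assert basis.xi.sum() == pytest.approx(np.trace(K), rel=1e-8)
            assert np.all(basis.mu <= basis.xi + 1e-8)
            assert np.all(np.diff(basis.xi) <= 1e-12)

    def test_dense_eigensolver_oracle_4x2(self, rng):
        g, w, _, _, proj = make_instance(rng, 4, 2, p_cov=0, freq=0.3)
        basis = spectral_basis_mixed(g, w, proj)
        A = g.counts * w.scaled
        xi_dense = np.sort(np.linalg.eigvalsh(A.T @ A))[::-1]
        mu_dense = np.sort(np.linalg.eigvalsh(A.T @ proj.P0 @ A))[::-1]
        np.testing.assert_allclose(basis.xi, xi_dense[:basis.K_active], rtol=1e-10)
        np.testing.assert_allclose(basis.mu, np.clip(mu_dense, 0, None)[:basis.K_active],
                                   atol=1e-10)

    def test_kernel_route_matches_mixed_route(self, rng):
        g, w, X, y, proj = make_instance(rng, 25, 5)
        bm = spectral_basis_mixed(g, w, proj)
        bk = spectral_basis_kernel(weighted_linear_kernel(g, w), proj)
        assert bk.K_active == bm.K_active
        np.testing.assert_allclose(bk.xi, bm.xi, rtol=1e-6)
        np.testing.assert_allclose(bk.mu, bm.mu, rtol=1e-6, atol=1e-8 * bm.xi[0])

    def test_kernel_projected_spectrum_matches_explicit_sqrt(self, rng):
        g, w, X, y, proj = make_instance(rng, 15, 3)
        k = weighted_linear_kernel(g, w)
        basis = spectral_basis_kernel(k, proj)
        R = kernel_sqrt(k)
        M = R @ proj.P0 @ R
        mu_dense = np.sort(np.clip(np.linalg.eigvalsh(M), 0, None))[::-1]
        np.testing.assert_allclose(basis.mu, mu_dense[:basis.K_active],
                                   rtol=1e-6, atol=1e-8 * basis.xi[0])

    def test_identity_kernel_centering_spectrum(self):
        proj = null_projection(None, n=3)
        basis = spectral_basis_kernel(KernelMatrix(np.eye(3)), proj)
        np.testing.assert_allclose(basis.xi, [1, 1, 1], atol=1e-12)
        np.testing.assert_allclose(basis.mu, [1, 1, 0], atol=1e-10)

    def test_zero_kernel_degenerates(self):
        proj = null_projection(None, n=5)
        basis = spectral_basis_kernel(KernelMatrix(np.zeros((5, 5))), proj)
        assert basis.degenerate


class TestProfileLikelihoods:
    def test_ml_matches_dense_oracle(self, rng):
        g, w, X, y, proj = make_instance(rng, 12, 3)
        Xd = proj.X_design
        C = weighted_linear_kernel(g, w).values
        for lam in (0.1, 1.0, 10.0):
            ours = (profile_ml_loglik(lam, y, proj, genotypes=g, weights=w)
                    - profile_ml_loglik(0.0, y, proj, genotypes=g, weights=w))
            oracle = dense_ml(lam, y, Xd, C) - dense_ml(0.0, y, Xd, C)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_reml_matches_dense_oracle(self, rng):
        g, w, X, y, proj = make_instance(rng, 14, 3)
        Xd = proj.X_design
        C = weighted_linear_kernel(g, w).values
        for lam in (0.5, 2.0):
            ours = (profile_reml_loglik(lam, y, proj, genotypes=g, weights=w)
                    - profile_reml_loglik(0.0, y, proj, genotypes=g, weights=w))
            oracle = dense_reml(lam, y, Xd, C) - dense_reml(0.0, y, Xd, C)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_null_point_difference_zero(self, rng):
        g, w, X, y, proj = make_instance(rng, 10, 2)
        lik = ProfiledLikelihood.from_genotypes(y, proj, g, w)
        assert lik.ml(0.0) == lik.ml(0.0)
        assert lik.reml(0.0) - lik.reml(0.0) == 0.0

    def test_zero_covariance_constant_in_lambda(self, rng):
        proj = null_projection(None, n=8)
        y = rng.standard_normal(8)
        lik = ProfiledLikelihood.from_kernel(y, proj, KernelMatrix(np.zeros((8, 8))))
        assert lik.ml(5.0) == pytest.approx(lik.ml(0.0), abs=1e-12)
        assert lik.reml(3.0) == pytest.approx(lik.reml(0.0), abs=1e-12)

    def test_kernel_and_genotype_paths_agree(self, rng):
        g, w, X, y, proj = make_instance(rng, 16, 4)
        lik_m = ProfiledLikelihood.from_genotypes(y, proj, g, w)
        lik_k = ProfiledLikelihood.from_kernel(y, proj, weighted_linear_kernel(g, w))
        for lam in (0.0, 0.3, 4.0):
            assert lik_m.ml(lam) == pytest.approx(lik_k.ml(lam), abs=1e-8)
            assert lik_m.reml(lam) == pytest.approx(lik_k.reml(lam), abs=1e-8)


class TestMaximizeOverLambda:
    def test_monotone_decreasing_boundary_solution(self):
        lam_hat, stat = maximize_over_lambda(lambda l: -l, default_lambda_grid())
        assert (lam_hat, stat) == (0.0, 0.0)

    def test_recovers_constructed_interior_peak(self):
        target = np.log(3.7)
        obj = lambda l: -(np.log(l + 1e-12) - target) ** 2
        lam_hat, stat = maximize_over_lambda(obj, default_lambda_grid())
        assert lam_hat == pytest.approx(3.7, rel=1e-2)
        assert stat == pytest.approx(2 * (obj(lam_hat) - obj(0.0)), rel=1e-9)

    def test_peak_at_grid_boundary_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="rvlrt.vc_lrt"):
            lam_hat, stat = maximize_over_lambda(lambda l: l, default_lambda_grid())
        assert stat > 0 and lam_hat >= 1e4 * 0.9
        assert any("boundary" in r.message for r in caplog.records)


class TestSimulatedNull:
    def test_fixed_seed_bit_identical(self, rng):
        g, w, X, y, proj = make_instance(rng, 40, 3)
        basis = spectral_basis_mixed(g, w, proj)
        a = simulate_null(basis, "LRT", 500, seed=5)
        b = simulate_null(basis, "LRT", 500, seed=5)
        np.testing.assert_array_equal(a, b)
        c = simulate_null(basis, "LRT", 500, seed=6)
        assert not np.array_equal(a, c)

    def test_all_zero_spectrum_gives_zero_statistics(self):
        basis = SpectralBasis(xi=np.zeros(3), mu=np.zeros(3), n=20, p_rank=1)
        np.testing.assert_array_equal(simulate_null(basis, "ReLRT", 200, seed=0),
                                      np.zeros(200))

    def test_matches_direct_fit_distribution_single_variant(self, rng):
        """The spectral null must agree with brute-force profile-ML fits on
        fresh null data: same point mass at zero and close upper quantiles."""
        n = 150
        gvec = np.zeros(n)
        gvec[: 12] = 1.0
        rng.shuffle(gvec)
        g = GenotypeMatrix([f"s{i}" for i in range(n)], ["v1"],
                           gvec.reshape(-1, 1), np.array([gvec.mean() / 2]))
        w = beta_maf_weights(g.maf)
        proj = null_projection(None, n=n)
        grid = default_lambda_grid()
        stats_direct = []
        for _ in range(600):
            yy = rng.standard_normal(n)
            lik = ProfiledLikelihood.from_genotypes(yy, proj, g, w)
            stats_direct.append(maximize_over_lambda(lik.ml, grid)[1])
        stats_direct = np.array(stats_direct)
        basis = spectral_basis_mixed(g, w, proj)
        null = simulate_null(basis, "LRT", 20000, grid, seed=3)
        assert abs(np.mean(null == 0) - np.mean(stats_direct == 0)) < 0.06
        for q in (0.9, 0.95):
            assert np.quantile(null, q) == pytest.approx(
                np.quantile(stats_direct, q), abs=0.35)

    def test_single_variant_null_below_chisq1(self, rng):
        """Upper quantiles of the exact null sit below chi2_1's, which is why
        the 50:50 mixture p-value is conservative."""
        g, w, X, y, proj = make_instance(rng, 200, 1, p_cov=0, freq=0.03)
        basis = spectral_basis_mixed(g, w, proj)
        null = simulate_null(basis, "LRT", 20000, seed=9)
        for q in (0.9, 0.95, 0.99):
            assert np.quantile(null, q) < stats.chi2.ppf(q, 1)

    def test_invalid_inputs(self, rng):
        g, w, X, y, proj = make_instance(rng, 20, 2)
        basis = spectral_basis_mixed(g, w, proj)
        with pytest.raises(ValueError):
            simulate_null(basis, "LRT", 50, seed=0)
        with pytest.raises(ValueError):
            simulate_null(basis, "nope", 200, seed=0)


class TestPvalueFromNull:
    def test_zero_statistic_gives_one(self):
        assert pvalue_from_null(0.0, np.array([0.0, 0.5, 1.0])) == 1.0

    def test_above_maximum_pseudocount(self):
        null = np.linspace(0, 5, 9999)
        assert pvalue_from_null(6.0, null) == pytest.approx(1e-4)

    def test_median_statistic(self):
        null = np.arange(1001, dtype=float)
        assert pvalue_from_null(500.0, null) == pytest.approx(0.5, abs=2e-3)

    def test_chibar_cross_check_is_more_conservative(self, rng):
        g, w, X, y, proj = make_instance(rng, 150, 1, p_cov=0, freq=0.03)
        basis = spectral_basis_mixed(g, w, proj)
        null = simulate_null(basis, "LRT", 5000, seed=1)
        for stat in (0.5, 1.5, 3.0):
            assert chibar_pvalue(stat) > pvalue_from_null(stat, null)


class TestTestSet:
    def test_formulation_equivalence(self, rng):
        g, w, X, y, proj = make_instance(rng, 60, 5)
        rm = vc_test_set(y, X, genotypes=g, weights=w, method="ReLRT.M",
                      n_null_sims=1000, seed=4)
        rk = vc_test_set(y, X, genotypes=g, weights=w, method="ReLRT.K",
                      n_null_sims=1000, seed=4)
        assert rm.statistic == pytest.approx(rk.statistic, abs=1e-6)
        assert rm.lambda_hat == pytest.approx(rk.lambda_hat, rel=1e-4, abs=1e-8)
        assert rm.p_value == rk.p_value
        lm = vc_test_set(y, X, genotypes=g, weights=w, method="LRT.M",
                      n_null_sims=1000, seed=4)
        lk = vc_test_set(y, X, genotypes=g, weights=w, method="LRT.K",
                      n_null_sims=1000, seed=4)
        assert lm.statistic == pytest.approx(lk.statistic, abs=1e-6)

    def test_statistic_lambda_linkage_and_heritability(self, rng):
        for _ in range(6):
            g, w, X, y, proj = make_instance(rng, 40, 3)
            r = vc_test_set(y, X, genotypes=g, weights=w, method="LRT.M",
                         n_null_sims=500, seed=1)
            assert r.statistic >= 0
            assert (r.statistic == 0) == (r.lambda_hat == 0)
            assert r.heritability == r.lambda_hat / (1 + r.lambda_hat)
            if r.statistic == 0:
                assert r.p_value >= r.null_zero_mass

    def test_observed_statistic_matches_generic_optimizer(self, rng):
        """Grid+golden maximisation agrees with a dense-matrix generic
        optimiser to 1e-5 on small random instances."""
        for _ in range(6):
            n = int(rng.integers(15, 30))
            m = int(rng.integers(1, 6))
            g, w, X, y, proj = make_instance(rng, n, m)
            Xd = proj.X_design
            C = weighted_linear_kernel(g, w).values
            for kind, dense in (("LRT.M", dense_ml), ("ReLRT.M", dense_reml)):
                r = vc_test_set(y, X, genotypes=g, weights=w, method=kind,
                             n_null_sims=500, seed=2)
                f0 = dense(0.0, y, Xd, C)
                best = -optimize.minimize_scalar(
                    lambda t: -dense(np.exp(t), y, Xd, C),
                    bounds=(-12, 12), method="bounded",
                    options={"xatol": 1e-10}).fun
                oracle = max(0.0, 2 * (best - f0))
                assert r.statistic == pytest.approx(oracle, abs=1e-5)

    def test_degenerate_set_not_testable(self):
        proj_n = 10
        y = np.random.default_rng(0).standard_normal(proj_n)
        r = vc_test_set(y, None, kernel=KernelMatrix(np.zeros((proj_n, proj_n))),
                     method="LRT.K", n_null_sims=500, seed=0)
        assert not r.testable
        assert r.p_value == 1.0 and r.lambda_hat == 0.0
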