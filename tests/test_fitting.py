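"""Penalized least-squares solver, smoothing selection, prediction."""

import warnings

import numpy as np
import pytest

import splanova as sp
from splanova.fitting import (
    Observations,
    PenalizedSystem,
    build_design,
    default_representers,
    fit_spline,
    select_lambda,
    solve_penalized,
)
from splanova.kernels import MarginalCubicKernel, make_tps_kernel

from conftest import make_example1_obs


class TestObservations:
    def test_validation(self):
        with pytest.raises(ValueError, match="missing"):
            Observations(np.array([[0.1, 0.2], [np.nan, 0.3], [0.5, 0.5],
                                   [0.6, 0.1]]), np.zeros(4))
        with pytest.raises(ValueError, match="at least"):
            Observations(np.array([[0.1, 0.2], [0.3, 0.4]]), np.zeros(2))
        with pytest.raises(ValueError, match="weights"):
            Observations(np.random.rand(5, 2), np.zeros(5),
                         weights=np.array([1, 1, 0, 1, 1.0]))


class TestBuildDesign:
    def test_tps_penalized_diagonal_is_zero(self):
        obs = make_example1_obs(10, 0.1, 0)
        d = build_design(make_tps_kernel(), obs)
        np.testing.assert_allclose(np.diag(d.P), 0.0, atol=1e-15)
        assert d.T.shape == (10, 3)

    def test_penalty_matches_reevaluated_gram(self):
        """Direct re-evaluation oracle on 4 random points."""
        obs = make_example1_obs(4 + 3, 0.1, 1)
        kern = make_tps_kernel()
        d = build_design(kern, obs, representers=obs.x[:4])
        again = kern.gram(obs.x[:4], obs.x[:4])
        np.testing.assert_allclose(d.P, 0.5 * (again + again.T), atol=1e-12)
        np.testing.assert_allclose(d.P, d.P.T, atol=1e-12)

    def test_duplicate_representers_deduplicated_with_warning(self):
        obs = make_example1_obs(8, 0.1, 2)
        reps = np.vstack([obs.x[:4], obs.x[:2]])
        with pytest.warns(UserWarning, match="duplicate"):
            d = build_design(make_tps_kernel(), obs, representers=reps)
        assert d.representers.shape[0] == 4

    def test_quantile_grid_knots_for_large_bivariate_n(self):
        rng = np.random.default_rng(0)
        x = rng.random((2000, 2))
        reps = default_representers(x)
        assert reps.shape[0] <= 200
        assert reps[:, 0].min() == pytest.approx(x[:, 0].min())


class TestSolvePenalized:
    def test_zero_response_gives_zero_fit(self):
        obs = make_example1_obs(12, 0.1, 3)
        kern = make_tps_kernel()
        d = build_design(kern, obs)
        alpha, beta, cov, edf, sigma2 = solve_penalized(
            d.J, d.T, d.P, np.zeros(12), lam=1.0, T_rep=d.T_rep
        )
        np.testing.assert_allclose(alpha, 0.0, atol=1e-12)
        np.testing.assert_allclose(beta, 0.0, atol=1e-12)
        assert sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_infinite_smoothing_reduces_to_least_squares_plane(self):
        obs = make_example1_obs(40, 0.3, 4)
        kern = make_tps_kernel()
        fit = fit_spline(kern, obs, lam=1e12)
        # OLS oracle on {1, x, y}
        T = kern.nullspace_matrix(obs.x)
        beta_ols, *_ = np.linalg.lstsq(T, obs.z, rcond=None)
        pred, _ = fit.predict(obs.x)
        np.testing.assert_allclose(pred, T @ beta_ols, atol=1e-4)

    def test_ridge_formula_matches_dense_oracle(self):
        """alpha_hat = (J'J + lam J)^(-1) J'z for an empty null space."""
        kern = MarginalCubicKernel((0, 1))
        rng = np.random.default_rng(5)
        x = np.sort(rng.random(5))
        z = np.sin(2 * np.pi * x) + rng.normal(0, 0.1, 5)
        J = kern.gram(x, x)
        lam = 1.0
        alpha, beta, cov, edf, sigma2 = solve_penalized(
            J, np.zeros((5, 0)), J, z, lam
        )
        dense = np.linalg.solve(J.T @ J + lam * J, J.T @ z)
        np.testing.assert_allclose(alpha, dense, atol=1e-8)
        # and the posterior covariance matches sigma^2 (J'J + lam J)^-1
        dense_cov = sigma2 * np.linalg.inv(J.T @ J + lam * J)
        np.testing.assert_allclose(cov, dense_cov, atol=1e-8 * abs(dense_cov).max())

    def test_lambda_must_be_positive(self):
        with pytest.raises(ValueError):
            solve_penalized(np.eye(3), np.zeros((3, 0)), np.eye(3),
                            np.ones(3), lam=0.0)


class TestSelectLambda:
    def _system(self, obs, kern=None):
        kern = kern or make_tps_kernel()
        d = build_design(kern, obs)
        return PenalizedSystem(d, obs.z, obs.weights)

    def test_pure_noise_shrinks_to_null_space(self):
        rng = np.random.default_rng(6)
        obs = Observations(rng.random((60, 2)), rng.normal(0, 1, 60))
        system = self._system(obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = select_lambda(system, "gcv")
        assert system.edf(lam) <= 3 + 2  # null space dim + 2

    def test_selected_lambda_is_a_local_minimizer(self):
        obs = make_example1_obs(80, 0.3, 7)
        system = self._system(obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = select_lambda(system, "gcv")
        g0 = system.gcv(lam)
        assert g0 <= system.gcv(lam * 10.0)
        assert g0 <= system.gcv(lam / 10.0)

    def test_refinement_matches_exhaustive_scan(self):
        """Golden-section refinement vs a 1000-point exhaustive grid."""
        kern = MarginalCubicKernel((0, 1))
        rng = np.random.default_rng(8)
        x = rng.random(50)
        z = np.sin(2 * np.pi * x) + rng.normal(0, 0.3, 50)
        J = kern.gram(x, x)
        T = kern.nullspace_matrix(x[:, None])
        from splanova.fitting import Design

        d = Design(J=J, T=T, P=J, T_rep=np.zeros((50, T.shape[1])),
                   representers=x[:, None], constrain=False)
        system = PenalizedSystem(d, z)
        lam = select_lambda(system, "gcv")
        dense = 10.0 ** np.linspace(np.log10(system.d_scale) - 10,
                                    np.log10(system.d_scale) + 4, 1000)
        vals = np.array([system.gcv(l) for l in dense])
        lam_dense = dense[int(np.argmin(vals))]
        step = np.log10(dense[1] / dense[0]) * (1000 / 57)
        assert abs(np.log10(lam) - np.log10(lam_dense)) < step

    def test_monotone_criterion_warns_boundary(self):
        obs = make_example1_obs(20, 0.1, 9)
        system = self._system(obs)
        grid = np.array([1e8, 1e9, 1e10])  # far beyond any transition
        with pytest.warns(UserWarning, match="boundary"):
            select_lambda(system, "gcv", grid=grid)

    def test_edf_monotone_in_lambda(self):
        obs = make_example1_obs(50, 0.3, 10)
        system = self._system(obs)
        ladder = 10.0 ** np.linspace(-8, 4, 13)
        edfs = [system.edf(l) for l in ladder]
        assert all(a >= b - 1e-10 for a, b in zip(edfs, edfs[1:]))


class TestPredict:
    def test_interpolation_limit(self):
        obs = make_example1_obs(25, 0.01, 11)
        fit = fit_spline(make_tps_kernel(), obs, lam=1e-10)
        pred, var = fit.predict(obs.x)
        assert np.max(np.abs(pred - obs.z)) < 1e-6
        assert np.all(var >= 0)

    def test_monte_carlo_predictive_sd_matches_analytic(self, tps_fit_400):
        """Sampling oracle: draws from N(coef, cov) vs analytic sd."""
        fit = tps_fit_400
        pts = np.array([[0.2, 0.3], [0.5, 0.5], [0.8, 0.1],
                        [0.1, 0.9], [0.6, 0.7]])
        mean, var = fit.predict(pts)
        rng = np.random.default_rng(123)
        draws = rng.multivariate_normal(fit.coef, fit.cov, size=2000,
                                        method="eigh")
        M = fit.design_rows(pts)
        emp_sd = (draws @ M.T).std(axis=0, ddof=1)
        np.testing.assert_allclose(emp_sd, np.sqrt(var), rtol=0.05)

    def test_posterior_covariance_shrinks_with_n(self):
        """Nested data, fixed lambda: cov trace decreases as n grows."""
        obs_big = make_example1_obs(200, 0.3, 12)
        obs_small = Observations(obs_big.x[:60], obs_big.z[:60])
        kern = make_tps_kernel()
        reps = obs_small.x  # common representers
        f_small = fit_spline(kern, obs_small, lam=1e-3, representers=reps)
        f_big = fit_spline(kern, obs_big, lam=1e-3, representers=reps)
        assert np.trace(f_big.cov) < np.trace(f_small.cov)

    def test_theta_blocks_equal_single_kernel_assembly(self, unit_measures):
        """Block-weighted tensor solve vs an independently summed kernel."""
        from splanova.kernels import make_marginal_kernel, make_tensor_kernel

        obs = make_example1_obs(40, 0.3, 13)
        theta = (np.inf, 1.0, 3.0, 0.5)
        kern = make_tensor_kernel(
            make_marginal_kernel(), make_marginal_kernel(), unit_measures, theta
        )
        fit = fit_spline(kern, obs, lam=0.1, representers=obs.x)

        class Summed:
            dim = 2
            domain = kern.domain
            nullspace_basis = kern.nullspace_basis

            def gram(self, A, B):
                return (kern.kx.gram(np.atleast_2d(A)[:, 0], np.atleast_2d(B)[:, 0])
                        + 3.0 * kern.ky.gram(np.atleast_2d(A)[:, 1],
                                             np.atleast_2d(B)[:, 1])
                        + 0.5 * kern.kx.gram(np.atleast_2d(A)[:, 0],
                                             np.atleast_2d(B)[:, 0])
                        * kern.ky.gram(np.atleast_2d(A)[:, 1],
                                       np.atleast_2d(B)[:, 1]))

            def nullspace_matrix(self, P):
                return kern.nullspace_matrix(P)

        s = Summed()
        fit2 = fit_spline(s, obs, lam=0.1, representers=obs.x)
        p1, _ = fit.predict(obs.x)
        p2, _ = fit2.predict(obs.x)
        np.testing.assert_allclose(p1, p2, atol=1e-8)
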