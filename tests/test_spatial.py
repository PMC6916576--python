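"""Predictive process, process variance, ALR link, temporal priors."""

import numpy as np
import pytest

from stepps.grids import build_grid
from stepps.spatial import (
    fit_field_hyperparams,
    DEFAULT_NUGGET,
    KnotSet,
    SpatialHyperparams,
    alr_inverse,
    alr_transform,
    exponential_covariance,
    explained_variance,
    fit_spatial_hyperparams,
    innovation_prior,
    predictive_process_project,
    process_variance,
    temporal_mean_prior,
)


@pytest.fixture(scope="module")
def grid6():
    return build_grid((144.0, 144.0), 24.0)


class TestPredictiveProcess:
    def test_all_cells_as_knots_is_identity(self, grid6):
        knots = KnotSet.from_grid(grid6, every=1)
        C_star, c = knots.covariances(eta=1.3, rho=80.0)
        alpha = np.random.default_rng(0).standard_normal(knots.n_knots)
        nu = predictive_process_project(alpha, c, C_star)
        np.testing.assert_allclose(nu, alpha, atol=1e-8)

    def test_single_knot_reduces_to_correlation_times_alpha(self, grid6):
        knot = grid6.cell_centers[[14]]
        d_cross = np.hypot(*(grid6.cell_centers - knot).T)[:, None]
        knots = KnotSet(knots=knot, d_knots=np.zeros((1, 1)), d_cross=d_cross)
        eta, rho = 2.0, 75.0
        C_star, c = knots.covariances(eta, rho)
        nu = predictive_process_project(np.array([1.7]), c, C_star)
        np.testing.assert_allclose(nu, 1.7 * np.exp(-d_cross[:, 0] / rho), atol=1e-12)

    def test_zero_coefficients_give_zero_field(self, grid6):
        knots = KnotSet.from_grid(grid6, every=2)
        C_star, c = knots.covariances(1.0, 50.0)
        np.testing.assert_array_equal(
            predictive_process_project(np.zeros(knots.n_knots), c, C_star), 0.0
        )

    def test_full_knot_prior_covariance_equals_gp_covariance(self, grid6):
        # knots = all cells: cov(nu) = c C*^-1 C* C*^-1 c' = full GP covariance
        knots = KnotSet.from_grid(grid6, every=1)
        eta, rho = 1.1, 60.0
        C_star, c = knots.covariances(eta, rho)
        P = c @ np.linalg.inv(C_star)
        implied = P @ C_star @ P.T
        full = exponential_covariance(
            np.hypot(
                grid6.cell_centers[:, None, 0] - grid6.cell_centers[None, :, 0],
                grid6.cell_centers[:, None, 1] - grid6.cell_centers[None, :, 1],
            ),
            eta, rho,
        )
        np.testing.assert_allclose(implied, full, atol=1e-8)


class TestProcessVariance:
    def test_knot_coincident_cells_reduce_to_nugget(self, grid6):
        knots = KnotSet.from_grid(grid6, every=2)
        sigma2 = process_variance(knots, eta=1.5, rho=80.0, omega=0.7)
        at_knots = np.isin(
            np.arange(grid6.n_cells),
            grid6.cell_of(knots.knots),
        )
        np.testing.assert_allclose(sigma2[at_knots], 1e-5, atol=1e-10)

    def test_all_cells_as_knots_gives_nugget_everywhere(self, grid6):
        knots = KnotSet.from_grid(grid6, every=1)
        for first in (True, False):
            sigma2 = process_variance(knots, 1.2, 60.0, 0.8, t_is_first=first)
            np.testing.assert_allclose(sigma2, DEFAULT_NUGGET, atol=1e-9)

    def test_far_from_knots_approaches_marginal_variance(self):
        grid = build_grid((48.0, 48.0), 24.0)
        far = np.array([[1e6, 1e6]])
        knots = KnotSet(
            knots=far,
            d_knots=np.zeros((1, 1)),
            d_cross=np.hypot(*(grid.cell_centers - far).T)[:, None],
        )
        eta = 1.4
        sigma2 = process_variance(knots, eta, 100.0, 0.5, t_is_first=True)
        np.testing.assert_allclose(sigma2, eta**2 + DEFAULT_NUGGET, rtol=1e-10)

    def test_later_bins_add_innovation_correction(self, grid6):
        knots = KnotSet.from_grid(grid6, every=3)
        omega = 0.6
        s1 = process_variance(knots, 1.0, 50.0, omega, t_is_first=True)
        s2 = process_variance(knots, 1.0, 50.0, omega, t_is_first=False)
        corr = s1 - DEFAULT_NUGGET
        np.testing.assert_allclose(s2, s1 + (1 - omega**2) * corr, rtol=1e-10)


class TestTemporalPriors:
    def test_temporal_mean_starts_at_zero_mean(self):
        d = temporal_mean_prior(0.7, xi=0.2, t=2)
        assert d.mean() == 0.0 and d.std() == pytest.approx(0.2)

    def test_random_walk_mean_is_previous_value(self):
        d = temporal_mean_prior(0.7, xi=0.2, t=5)
        assert d.mean() == pytest.approx(0.7)

    def test_variance_accumulates_linearly_over_bins(self):
        # prior var of the temporal mean at bin T is (T-1) xi^2
        rng = np.random.default_rng(0)
        xi, T, n = 0.3, 7, 20000
        mu = np.zeros(n)
        for t in range(2, T + 1):
            mu = temporal_mean_prior(0.0, xi, t).rvs(n, random_state=rng) + (mu if t > 2 else 0.0)
        expected = (T - 1) * xi**2
        assert np.var(mu) == pytest.approx(expected, rel=0.05)

    def test_innovation_prior_is_iid_at_zero_omega(self):
        C = exponential_covariance(np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0))), 1.0, 2.0)
        d = innovation_prior(np.ones(4), omega=0.0, C_star=C)
        np.testing.assert_allclose(d.mean, 0.0)
        np.testing.assert_allclose(d.cov, C, atol=1e-7)

    def test_innovation_stationary_covariance_is_knot_covariance(self):
        # solve Sigma = omega^2 Sigma + (1 - omega^2) C*  ->  Sigma = C*
        C = exponential_covariance(np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0))), 1.3, 3.0)
        omega = 0.85
        rng = np.random.default_rng(1)
        L = np.linalg.cholesky(C)
        n_chains, T = 4000, 60
        x = L @ rng.standard_normal((5, n_chains))
        for _ in range(T):
            x = omega * x + np.sqrt(1 - omega**2) * (L @ rng.standard_normal((5, n_chains)))
        emp = np.cov(x)
        mc_sd = np.sqrt(2.0 / n_chains) * np.outer(np.sqrt(np.diag(C)), np.sqrt(np.diag(C)))
        assert np.all(np.abs(emp - C) < 3 * mc_sd + 0.05)

    def test_innovations_freeze_as_omega_approaches_one(self):
        C = np.eye(3)
        d = innovation_prior(np.array([1.0, -2.0, 0.5]), omega=0.9999, C_star=C)
        np.testing.assert_allclose(d.mean, [1.0, -2.0, 0.5], rtol=1e-3)
        assert np.all(np.diag(d.cov) < 1e-3)


class TestAlr:
    def test_equal_fields_give_uniform_composition(self):
        np.testing.assert_allclose(alr_inverse(np.full(5, 3.7)), 0.2)

    def test_shift_invariance(self):
        g = np.array([0.3, -1.2, 2.0])
        np.testing.assert_allclose(alr_inverse(g), alr_inverse(g + 17.0), atol=1e-12)

    def test_hand_value(self):
        np.testing.assert_allclose(alr_inverse(np.array([np.log(3), 0.0])), [0.75, 0.25])

    def test_sums_to_one_even_for_extreme_fields(self):
        g = np.array([[1e4, 0.0, -1e4], [700.0, -700.0, 0.0]])
        r = alr_inverse(g, axis=1)
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-15)

    def test_transform_is_softmax_pseudo_inverse(self):
        rng = np.random.default_rng(2)
        r = rng.dirichlet(np.ones(4), size=10)
        np.testing.assert_allclose(alr_inverse(alr_transform(r, axis=1), axis=1), r, atol=1e-6)


class TestHyperparamFit:
    @staticmethod
    def _simulate_field(grid, knots, eta, rho, rng):
        """One predictive-process field with exponential covariance."""
        C_star, c = knots.covariances(eta, rho)
        L = np.linalg.cholesky(C_star + 1e-8 * np.eye(knots.n_knots))
        P = c @ np.linalg.inv(C_star + 1e-8 * np.eye(knots.n_knots))
        resid_sd = np.sqrt(np.clip(eta**2 - explained_variance(c, C_star), 0, None) + 1e-5)
        return P @ (L @ rng.standard_normal(knots.n_knots)) + resid_sd * rng.standard_normal(grid.n_cells)

    def test_range_recovered_within_factor_two(self):
        grid = build_grid((480.0, 480.0), 24.0)
        knots = KnotSet.from_grid(grid, every=2)
        rho_true = 100.0
        hits, reps = 0, 10
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            g = self._simulate_field(grid, knots, 1.0, rho_true, rng)
            _, rho = fit_field_hyperparams(g, grid, knots, seed=rep, n_steps=200)
            hits += (rho_true / 2 < rho < rho_true * 2)
        assert hits >= 0.8 * reps

    def test_white_noise_field_collapses_range(self):
        grid = build_grid((240.0, 240.0), 24.0)
        knots = KnotSet.from_grid(grid, every=2)
        rng = np.random.default_rng(7)
        r = alr_inverse(rng.standard_normal((grid.n_cells, 3)), axis=1)
        _, rho = fit_spatial_hyperparams(r, grid, knots, seed=0, n_steps=200)
        assert np.all(rho < 40.0)  # well below domain scale

    def test_constant_field_collapses_scale(self):
        grid = build_grid((240.0, 240.0), 24.0)
        knots = KnotSet.from_grid(grid, every=2)
        r = np.tile([0.5, 0.3, 0.2], (grid.n_cells, 1))
        eta, _ = fit_spatial_hyperparams(r, grid, knots, seed=0, n_steps=200)
        assert np.all(eta < 0.05)


class TestHyperparamValidation:
    def test_supports_enforced(self):
        with pytest.raises(ValueError):
            SpatialHyperparams(eta=np.array([1.0]), rho=np.array([10.0]), omega=1.0)
        with pytest.raises(ValueError):
            SpatialHyperparams(eta=np.array([-1.0]), rho=np.array([10.0]))
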