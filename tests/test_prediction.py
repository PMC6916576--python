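"""Prediction-stage model: density, gradient, sampling contracts."""

import numpy as np
import pytest

from stepps.calibration import CalibrationDraw
from stepps.prediction import BinnedPollen, PredictionModel
from stepps.spatial import SpatialHyperparams
from stepps.synthetic import PRESETS, bin_records


@pytest.fixture(scope="module")
def tiny_model(tiny_truth, tiny_records, tiny_ages):
    cfg = PRESETS["tiny"]
    binned = bin_records(tiny_records, tiny_ages, 0)
    calib = CalibrationDraw(gamma=cfg.gamma_vec, phi=cfg.phi_vec, kernel=cfg.kernel)
    return PredictionModel(binned, tiny_truth.grid, tiny_truth.knots, calib,
                           cfg.hyperparams())


# conftest fixtures are session-scoped; re-export at module scope for clarity
@pytest.fixture(scope="module")
def tiny_fit(tiny_model):
    return tiny_model.fit(warmup=150, samples=200, thin=2, seed=11)


class TestBinnedPollen:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="nonnegative"):
            BinnedPollen(np.array(["a"]), np.array([0]),
                         -np.ones((1, 2, 3), dtype=int),
                         np.array([350.0, 250.0, 150.0]), ("x", "y", "z"))
        with pytest.raises(ValueError, match="decrease"):
            BinnedPollen(np.array(["a"]), np.array([0]),
                         np.ones((1, 2, 3), dtype=int),
                         np.array([150.0, 250.0, 350.0]), ("x", "y", "z"))

    def test_bin_midpoints(self, tiny_model):
        mids = tiny_model.data.bin_mid
        assert mids[0] > mids[-1]  # oldest first
        np.testing.assert_allclose(np.diff(mids), -100.0)


class TestProcessMeanAssembly:
    def test_first_bin_carries_only_time_invariant_terms(self, tiny_model):
        from stepps.spatial import process_mean

        assert process_mean(0.5, -0.2, t=1) == pytest.approx(0.3)
        assert process_mean(0.5, -0.2, mu_t=0.1, nu_st=0.05, t=3) == pytest.approx(0.45)
        assert process_mean(0.0, 0.0, mu_t=0.0, nu_st=0.0, t=2) == 0.0

    def test_unpacked_state_matches_process_mean_field(self, tiny_model):
        rng = np.random.default_rng(5)
        x = 0.2 * rng.standard_normal(tiny_model.n_params)
        st = tiny_model.unpack(x)
        mu_g = tiny_model.process_mean_field(st)
        # residual g - mu_g must match sigma-scaled whitened coordinates
        resid = st.g - mu_g
        assert np.isfinite(resid).all()
        assert np.all(np.abs(resid) < 10 * tiny_model._sigma.max() + 10)
        # first-bin column has no temporal terms: mu_t[0] == 0, alpha_t[0] == 0
        assert np.all(st.mu_t[0] == 0)
        assert np.all(st.alpha_t[0] == 0)


class TestJointPosterior:
    def test_gradient_matches_finite_differences(self, tiny_model):
        rng = np.random.default_rng(3)
        x = 0.3 * rng.standard_normal(tiny_model.n_params)
        lp, grad = tiny_model.logp_and_grad(x)
        idx = rng.choice(tiny_model.n_params, 20, replace=False)
        eps = 1e-6
        for i in idx:
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            num = (tiny_model.logp_and_grad(xp)[0] - tiny_model.logp_and_grad(xm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=5e-3, abs=1e-4)

    def test_whitened_and_natural_densities_differ_by_constant(self, tiny_model):
        rng = np.random.default_rng(4)
        offsets = []
        for _ in range(3):
            x = 0.3 * rng.standard_normal(tiny_model.n_params)
            lp_white, _ = tiny_model.logp_and_grad(x)
            lp_nat = tiny_model.joint_log_posterior(tiny_model.unpack(x))
            offsets.append(lp_white - lp_nat)
        assert np.ptp(offsets) < 1e-6

    def test_scalar_oracle_single_site_single_bin(self):
        """Independently coded scalar formula for a 1-cell, K=2, T=1 model."""
        from scipy.special import gammaln

        from stepps.grids import KernelParams, build_grid
        from stepps.prediction import LatentState
        from stepps.spatial import KnotSet

        grid = build_grid((24.0, 24.0), 24.0)
        knots = KnotSet.from_grid(grid, every=1)
        hyper = SpatialHyperparams(eta=np.ones(2), rho=np.full(2, 50.0),
                                   omega=0.5, xi=0.1, mu_scale=1.0)
        counts = np.array([[[7, 3]]])
        data = BinnedPollen(np.array(["s"]), np.array([0]), counts,
                            np.array([250.0, 150.0]), ("a", "b"))
        calib = CalibrationDraw(gamma=np.array([0.9, 0.8]),
                                phi=np.array([10.0, 5.0]),
                                kernel=KernelParams(a=30.0, b=4.0))
        model = PredictionModel(data, grid, knots, calib, hyper)
        mu = np.array([0.3, -0.2])
        alpha_s = np.array([[0.5, 0.1]])
        g = np.array([[[0.9, 0.0]]])
        state = LatentState(mu=mu, mu_t=np.zeros((1, 2)), alpha_s=alpha_s,
                            alpha_t=np.zeros((1, 1, 2)), g=g)
        # by hand: knots == cell -> nu = alpha; sigma^2 = tau^2 = 1e-5
        tau2 = 1e-5
        lp_hand = 0.0
        for k in range(2):
            lp_hand += -0.5 * mu[k] ** 2 - 0.5 * np.log(2 * np.pi)          # mu prior
            lp_hand += (-0.5 * alpha_s[0, k] ** 2 / 1.0**2
                        - 0.5 * np.log(2 * np.pi * 1.0**2))                  # alpha^s prior
            mean = mu[k] + alpha_s[0, k]
            lp_hand += (-0.5 * (g[0, 0, k] - mean) ** 2 / tau2
                        - 0.5 * np.log(2 * np.pi * tau2))                    # g prior
        r = np.exp(g[0, 0]) / np.exp(g[0, 0]).sum()
        conc = calib.gamma * calib.phi * r + 0.0  # single cell: purely local
        n, A = 10, conc.sum()
        lp_hand += (gammaln(n + 1) - gammaln(counts[0, 0] + 1.0).sum()
                    + gammaln(A) - gammaln(n + A)
                    + (gammaln(counts[0, 0] + conc) - gammaln(conc)).sum())
        assert model.joint_log_posterior(state) == pytest.approx(lp_hand, rel=1e-10)

    def test_nonfinite_component_is_named(self, tiny_model):
        rng = np.random.default_rng(6)
        st = tiny_model.unpack(0.1 * rng.standard_normal(tiny_model.n_params))
        st.g[0, 0, 0] = np.inf
        with pytest.raises(FloatingPointError, match="g|likelihood"):
            tiny_model.joint_log_posterior(st)


class TestSampling:
    def test_same_seed_reproduces_draws_exactly(self, tiny_model, tiny_fit):
        res2 = tiny_model.fit(warmup=150, samples=200, thin=2, seed=11)
        np.testing.assert_array_equal(tiny_fit.r, res2.r)
        np.testing.assert_array_equal(tiny_fit.mu, res2.mu)

    def test_simplex_conservation(self, tiny_fit):
        np.testing.assert_allclose(tiny_fit.r.sum(axis=-1), 1.0, atol=1e-12)
        np.testing.assert_allclose(tiny_fit.r_mean.sum(axis=-1), 1.0, atol=1e-12)

    def test_diagnostics_reported(self, tiny_fit):
        d = tiny_fit.diagnostics()
        assert set(d) >= {"accept_rate", "rhat_max", "ess_min", "n_divergent"}
        assert 0.2 < d["accept_rate"] <= 1.0
        assert d["n_divergent"] == 0

    def test_posterior_tracks_truth_direction(self, tiny_fit, tiny_truth):
        # weak desk-scale check; the full recovery study lives in acceptance
        pear = np.corrcoef(tiny_fit.posterior_mean_r.ravel(), tiny_truth.r.ravel())[0, 1]
        assert pear > 0.5

    def test_summary_table_shape(self, tiny_fit):
        df = tiny_fit.summary()
        assert set(df.columns) >= {"bin_yb1950", "taxon", "mean", "sd"}
        assert len(df) == tiny_fit.model.T * tiny_fit.model.K


class TestPriorSampling:
    def test_no_data_sampler_matches_generative_prior(self, tiny_truth):
        """With zero pollen, the posterior is the prior: HMC draws of mu and
        domain-mean g must match their analytic prior moments."""
        cfg = PRESETS["tiny"]
        edges = cfg.bin_edges
        S, T, K = 1, cfg.T, cfg.K
        data = BinnedPollen(np.array(["empty"]), np.array([0]),
                            np.zeros((S, T, K), dtype=int), edges, cfg.taxa)
        calib = CalibrationDraw(gamma=cfg.gamma_vec, phi=cfg.phi_vec, kernel=cfg.kernel)
        model = PredictionModel(data, tiny_truth.grid, tiny_truth.knots, calib,
                                cfg.hyperparams())
        res = model.fit(warmup=200, samples=600, thin=1, seed=5)
        # mu_k ~ N(0, mu_scale^2)
        z = res.mu.mean(axis=0) / (cfg.mu_scale / np.sqrt(res.n_draws / 10))
        assert np.all(np.abs(res.mu.mean(axis=0)) < 0.5)
        assert np.all(np.abs(res.mu.std(axis=0) - cfg.mu_scale) < 0.35)
        # temporal mean variance grows ~ (t-1) xi^2
        var_T = res.mu_t[:, -1, :].var(axis=0).mean()
        assert var_T == pytest.approx((T - 1) * cfg.xi**2, rel=0.6)


class TestAgeEnsemble:
    def test_pooled_variance_not_below_single_run(self, tiny_truth, tiny_records, tiny_ages):
        from stepps.io import records_to_frames
        from stepps.pipeline import run_age_ensemble
        from stepps.calibration import CalibrationModel

        cfg = PRESETS["tiny"]
        m = CalibrationModel(tiny_truth.settlement_composition,
                             tiny_records.calibration_counts,
                             tiny_records.calibration_coords, tiny_truth.grid,
                             taxa=cfg.taxa)
        calib = m.fit(n_steps=600, burn=300, thin=10, seed=2)
        pollen, sites = records_to_frames(tiny_records)
        hyper = cfg.hyperparams()
        ens = run_age_ensemble(pollen, sites, tiny_ages, calib, tiny_truth.grid,
                               tiny_truth.knots, hyper, cfg.bin_edges, cfg.taxa,
                               n_sets=2, warmup=100, samples=120, thin=2, seed=9)
        assert ens.n_draws == 2 * 60
        assert len(ens.provenance) == 2
        assert {p["age_draw_set"] for p in ens.provenance} <= set(range(3))
        np.testing.assert_allclose(ens.r.sum(axis=-1), 1.0, atol=1e-12)
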