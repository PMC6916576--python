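"""Prediction stage: spatiotemporal inference of forest composition.

The model links binned fossil pollen counts to gridded composition through
time.  Per taxon k, a latent field g_{s,t,k} follows a Gaussian process
whose mean combines an overall adjustment mu_k, a time-invariant spatial
field nu^s (a modified predictive process), a spatially invariant temporal
mean mu^t_t (random walk, N(0, xi^2) increments), and spatially correlated
innovations nu^st whose knot coefficients are AR(1) with coefficient omega
and stationary covariance C*.  The conditional variance of g is the
predictive-process variance correction plus a fixed nugget tau^2 = 1e-5.
Latent fields map to the composition simplex by the additive log-ratio
(softmax) link; pollen counts are Dirichlet-multinomial with concentrations
built from the calibrated local/non-local mixing.

Sampling uses Hamiltonian Monte Carlo with analytically coded gradients on
a non-centered (whitened) parameterization: every latent block is expressed
as a deterministic transform of standard-normal coordinates, so the prior
is isotropic and the likelihood gradient is propagated through the
predictive-process projection and the AR recursions by the chain rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .calibration import CalibrationDraw
from .grids import Grid, WeightMatrix, kernel_density, pairwise_distance
from .hmc import HMCConfig, sample_hmc
from .likelihood import dm_log_pmf, mixing_operator
from .spatial import (
    DEFAULT_NUGGET,
    KnotSet,
    SpatialHyperparams,
    _chol_with_jitter,
    alr_inverse,
    process_variance,
)

__all__ = [
    "BinnedPollen",
    "LatentState",
    "PosteriorEnsemble",
    "PredictionModel",
    "PredictionResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinnedPollen:
    """Site-level pollen counts aggregated into contiguous 100-yr time bins.

    The time axis runs oldest to youngest: bin t covers ages (YB1950) in the
    half-open interval [edges[t+1], edges[t]) with ``bin_edges`` descending
    (default 2,150 ... 150).
    """

    site_ids: np.ndarray      # (S,)
    site_cells: np.ndarray    # (S,) grid-cell index per site
    counts: np.ndarray        # (S, T, K)
    bin_edges: np.ndarray     # (T+1,) YB1950, strictly decreasing
    taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        edges = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(edges) >= 0):
            raise ValueError("bin edges must strictly decrease (oldest first)")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "bin_edges", edges)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def T(self) -> int:
        return self.counts.shape[1]

    @property
    def K(self) -> int:
        return self.counts.shape[2]

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    @property
    def bin_mid(self) -> np.ndarray:
        """Bin midpoint labels in YB1950 (oldest first)."""
        e = self.bin_edges
        return (e[:-1] + e[1:]) / 2.0


@dataclass
class LatentState:
    """All prediction-stage unknowns in their natural parameterization.

    ``mu_t[0]`` and ``alpha_t[0]`` are identically zero: the first time step
    carries only the time-invariant mean.
    """

    mu: np.ndarray        # (K,)
    mu_t: np.ndarray      # (T, K), row 0 == 0
    alpha_s: np.ndarray   # (M, K)
    alpha_t: np.ndarray   # (T, M, K), slab 0 == 0
    g: np.ndarray         # (N, T, K)

    @property
    def r(self) -> np.ndarray:
        """Composition implied by g (softmax over taxa)."""
        return alr_inverse(self.g, axis=2)


@dataclass
class PosteriorEnsemble:
    """Retained posterior draws of composition with provenance.

    ``r`` are draws of the full-field composition softmax(g); ``r_mean``
    draws of the composition implied by the smooth process mean mu^g (the
    quantity the change analysis operates on by default).
    """

    r: np.ndarray          # (D, N, T, K)
    r_mean: np.ndarray     # (D, N, T, K)
    bin_edges: np.ndarray  # (T+1,) descending YB1950
    taxa: tuple[str, ...]
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.r.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("composition draws must satisfy the simplex constraint")

    @property
    def n_draws(self) -> int:
        return self.r.shape[0]

    @property
    def bin_mid(self) -> np.ndarray:
        e = self.bin_edges
        return (e[:-1] + e[1:]) / 2.0

    def composition_draws(self, source: str = "process_mean") -> np.ndarray:
        if source == "process_mean":
            return self.r_mean
        if source == "full_field":
            return self.r
        raise ValueError("source must be 'process_mean' or 'full_field'")

    @classmethod
    def pool(cls, members: Sequence["PosteriorEnsemble"]) -> "PosteriorEnsemble":
        """Pool draws across runs (age-draw sets), keeping provenance."""
        if not members:
            raise ValueError("nothing to pool")
        prov = []
        for m in members:
            prov.extend(m.provenance)
        return cls(
            r=np.concatenate([m.r for m in members], axis=0),
            r_mean=np.concatenate([m.r_mean for m in members], axis=0),
            bin_edges=members[0].bin_edges,
            taxa=members[0].taxa,
            provenance=prov,
        )


class PredictionModel:
    """Spatiotemporal composition model for one binned pollen dataset.

    Parameters
    ----------
    data : BinnedPollen
    grid : Grid
    knots : KnotSet
    calib : CalibrationDraw
        One joint draw of (gamma, phi, kernel) from the calibration posterior.
    hyper : SpatialHyperparams
        Fixed (eta_k, rho_k, omega, xi, tau2) — eta/rho estimated a priori
        from the settlement-era composition.
    """

    def __init__(
        self,
        data: BinnedPollen,
        grid: Grid,
        knots: KnotSet,
        calib: CalibrationDraw,
        hyper: SpatialHyperparams,
        weights: WeightMatrix | None = None,
    ) -> None:
        self.data = data
        self.grid = grid
        self.knots = knots
        self.calib = calib
        self.hyper = hyper
        self.N, self.M = grid.n_cells, knots.n_knots
        self.T, self.K = data.T, data.K
        eta = np.broadcast_to(hyper.eta, (self.K,))
        rho = np.broadcast_to(hyper.rho, (self.K,))
        if weights is None:
            d = pairwise_distance(grid.cell_centers, grid.cell_centers)
            W = kernel_density(d, calib.kernel) * grid.cell_area
            np.fill_diagonal(W, 0.0)
            weights = WeightMatrix(W=W, C=W.sum(axis=1), params=calib.kernel)
        self.weights = weights
        # per-taxon spatial structure
        self._L, self._PL, self._P = [], [], []
        self._sigma1, self._sigma2 = [], []
        for k in range(self.K):
            C_star, c = knots.covariances(eta[k], rho[k])
            L = _chol_with_jitter(C_star, "knot covariance")
            # P = c C*^-1 via two triangular solves
            P = np.linalg.solve(L.T, np.linalg.solve(L, c.T)).T
            self._L.append(L)
            self._P.append(P)
            self._PL.append(P @ L)
            self._sigma1.append(
                np.sqrt(process_variance(knots, eta[k], rho[k], hyper.omega,
                                         hyper.tau2, t_is_first=True))
            )
            self._sigma2.append(
                np.sqrt(process_variance(knots, eta[k], rho[k], hyper.omega,
                                         hyper.tau2, t_is_first=False))
            )
        self._sigma = np.stack(
            [np.column_stack([s1] + [s2] * (self.T - 1))
             for s1, s2 in zip(self._sigma1, self._sigma2)],
            axis=2,
        )  # (N, T, K)
        # mixing operators: conc[:, t, k] = phi_k * (Mmix[k] @ r[:, t, k])
        self._Mmix = mixing_operator(calib.gamma, weights, data.site_cells)
        self._MmixT = np.ascontiguousarray(self._Mmix.transpose(0, 2, 1))
        self._counts = data.counts.astype(float)       # (S, T, K)
        self._totals = self._counts.sum(axis=2)        # (S, T)
        self._eta, self._rho = eta, rho
        # whitened layout per taxon: m | zs (M) | u (T-1) | zt ((T-1)M) | zg (NT)
        self._per_k = 1 + self.M + (self.T - 1) * (1 + self.M) + self.N * self.T
        self.n_params = self.K * self._per_k

    # ------------------------------------------------------------------ #
    # whitened <-> natural
    # ------------------------------------------------------------------ #
    def _split(self, xk: np.ndarray):
        M, T, N = self.M, self.T, self.N
        i = 0
        m = xk[i]; i += 1
        zs = xk[i : i + M]; i += M
        u = xk[i : i + T - 1]; i += T - 1
        zt = xk[i : i + (T - 1) * M].reshape(T - 1, M); i += (T - 1) * M
        zg = xk[i:].reshape(N, T)
        return m, zs, u, zt, zg

    def _temporal_coef(self) -> float:
        return self.hyper.omega if self.hyper.temporal_model == "ar1" else 1.0

    def unpack(self, x: np.ndarray) -> LatentState:
        """Map a whitened parameter vector to the natural LatentState."""
        h = self.hyper
        K, T, M, N = self.K, self.T, self.M, self.N
        sw = np.sqrt(1.0 - h.omega**2)
        ct = self._temporal_coef()
        mu = np.zeros(K)
        mu_t = np.zeros((T, K))
        alpha_s = np.zeros((M, K))
        alpha_t = np.zeros((T, M, K))
        g = np.zeros((N, T, K))
        for k in range(K):
            m, zs, u, zt, zg = self._split(x[k * self._per_k : (k + 1) * self._per_k])
            mu[k] = h.mu_scale * m
            alpha_s[:, k] = self._L[k] @ zs
            nu_s = self._PL[k] @ zs
            for t in range(1, T):
                prev = mu_t[t - 1, k] if t > 1 else 0.0
                mu_t[t, k] = (ct * prev if t > 1 else 0.0) + h.xi * u[t - 1]
                e = self._L[k] @ zt[t - 1]
                if t == 1:
                    alpha_t[t, :, k] = e
                else:
                    alpha_t[t, :, k] = h.omega * alpha_t[t - 1, :, k] + sw * e
            mu_g = mu[k] + nu_s[:, None] + mu_t[None, :, k]
            mu_g = mu_g + (self._P[k] @ alpha_t[:, :, k].T)
            g[:, :, k] = mu_g + self._sigma[:, :, k] * zg
        return LatentState(mu=mu, mu_t=mu_t, alpha_s=alpha_s, alpha_t=alpha_t, g=g)

    def process_mean_field(self, state: LatentState) -> np.ndarray:
        """mu^g_{s,t,k} implied by a latent state (no nugget-scale noise)."""
        out = np.empty((self.N, self.T, self.K))
        for k in range(self.K):
            nu_s = self._P[k] @ state.alpha_s[:, k]
            nu_st = self._P[k] @ state.alpha_t[:, :, k].T  # (N, T)
            out[:, :, k] = state.mu[k] + nu_s[:, None] + state.mu_t[None, :, k] + nu_st
        return out

    # ------------------------------------------------------------------ #
    # posterior density and gradient
    # ------------------------------------------------------------------ #
    def _loglik_and_grad_g(self, g: np.ndarray) -> tuple[float, np.ndarray]:
        """DM log-likelihood (up to count-factorial constants) and dL/dg."""
        phi = self.calib.phi
        r = alr_inverse(g, axis=2)                        # (N, T, K)
        conc = np.einsum("ksn,ntk->stk", self._Mmix, r)   # (S, T, K)
        conc *= phi[None, None, :]
        conc = np.clip(conc, 1e-12, None)
        A = conc.sum(axis=2)                              # (S, T)
        n = self._totals
        ll = float(
            np.sum(gammaln(A) - gammaln(n + A))
            + np.sum(gammaln(self._counts + conc) - gammaln(conc))
        )
        d_shared = digamma(A) - digamma(n + A)            # (S, T)
        d_conc = digamma(self._counts + conc) - digamma(conc) + d_shared[:, :, None]
        d_r = np.einsum("kns,stk->ntk", self._MmixT, d_conc * phi[None, None, :])
        inner = np.sum(r * d_r, axis=2, keepdims=True)
        d_g = r * (d_r - inner)
        return ll, d_g

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Whitened log posterior (up to a constant) and its gradient."""
        h = self.hyper
        K, T, M, N = self.K, self.T, self.M, self.N
        sw = np.sqrt(1.0 - h.omega**2)
        ct = self._temporal_coef()
        state = self.unpack(x)
        ll, G = self._loglik_and_grad_g(state.g)
        logp = ll - 0.5 * float(x @ x)
        grad = -np.array(x, dtype=float)
        for k in range(K):
            sl = slice(k * self._per_k, (k + 1) * self._per_k)
            m, zs, u, zt, zg = self._split(x[sl])
            Gk = G[:, :, k]                               # (N, T)
            # g = mu_g + sigma * zg
            gzg = self._sigma[:, :, k] * Gk
            # mu_g sensitivities
            Gcell = Gk.sum(axis=1)                        # (N,)
            Gt = Gk.sum(axis=0)                           # (T,)
            gm = h.mu_scale * Gt.sum()
            gzs = self._PL[k].T @ Gcell
            # temporal mean chain (affects t >= 1)
            b = 0.0
            gu = np.zeros(T - 1)
            for t in range(T - 1, 0, -1):
                b = Gt[t] + (ct * b if t < T - 1 else 0.0)
                gu[t - 1] = h.xi * b
            # innovation chain
            Ak = self._P[k].T @ Gk                        # (M, T)
            gzt = np.zeros((T - 1, M))
            bvec = np.zeros(M)
            for t in range(T - 1, 0, -1):
                bvec = Ak[:, t] + (h.omega * bvec if t < T - 1 else 0.0)
                scale = 1.0 if t == 1 else sw
                gzt[t - 1] = scale * (self._L[k].T @ bvec)
            gk = np.concatenate([[gm], gzs, gu, gzt.ravel(), gzg.ravel()])
            grad[sl] += gk
        return logp, grad

    def joint_log_posterior(self, state: LatentState) -> float:
        """Log posterior density of a natural-parameterization state.

        Includes the full DM log pmf (with multinomial coefficients) and all
        Gaussian priors; raises naming the offending component if any part
        is non-finite.
        """
        h = self.hyper
        K, T = self.K, self.T
        sw2 = 1.0 - h.omega**2
        ct = self._temporal_coef()
        parts: dict[str, float] = {}
        lp_mu = float(np.sum(-0.5 * (state.mu / h.mu_scale) ** 2
                             - np.log(h.mu_scale) - 0.5 * np.log(2 * np.pi)))
        parts["mu"] = lp_mu
        lp_mut = 0.0
        for t in range(1, T):
            mean = 0.0 if t == 1 else ct * state.mu_t[t - 1]
            z = (state.mu_t[t] - mean) / h.xi
            lp_mut += float(np.sum(-0.5 * z**2 - np.log(h.xi) - 0.5 * np.log(2 * np.pi)))
        parts["mu_t"] = lp_mut
        lp_as, lp_at = 0.0, 0.0
        for k in range(K):
            L = self._L[k]
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            z = np.linalg.solve(L, state.alpha_s[:, k])
            lp_as += -0.5 * float(z @ z) - 0.5 * logdet - 0.5 * self.M * np.log(2 * np.pi)
            for t in range(1, T):
                mean = 0.0 if t == 1 else h.omega * state.alpha_t[t - 1, :, k]
                scale2 = 1.0 if t == 1 else sw2
                z = np.linalg.solve(L, state.alpha_t[t, :, k] - mean) / np.sqrt(scale2)
                lp_at += (-0.5 * float(z @ z) - 0.5 * (logdet + self.M * np.log(scale2))
                          - 0.5 * self.M * np.log(2 * np.pi))
        parts["alpha_s"], parts["alpha_t"] = lp_as, lp_at
        mu_g = self.process_mean_field(state)
        zg = (state.g - mu_g) / self._sigma
        parts["g"] = float(np.sum(-0.5 * zg**2 - np.log(self._sigma)
                                  - 0.5 * np.log(2 * np.pi)))
        r = state.r
        conc = np.einsum("ksn,ntk->stk", self._Mmix, r) * self.calib.phi[None, None, :]
        parts["likelihood"] = float(np.sum(dm_log_pmf(self._counts, np.clip(conc, 1e-12, None))))
        for name, value in parts.items():
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite log-posterior component: {name}")
        return float(sum(parts.values()))

    # ------------------------------------------------------------------ #
    def fit(
        self,
        warmup: int = 300,
        samples: int = 600,
        thin: int = 2,
        n_leapfrog: int = 24,
        seed: int = 0,
        target_accept: float = 0.8,
    ) -> "PredictionResults":
        """Sample the posterior with adaptive HMC; reproducible given seed."""
        rng = np.random.default_rng(seed)
        x0 = 0.1 * rng.standard_normal(self.n_params)
        cfg = HMCConfig(
            warmup=warmup, samples=samples, thin=thin, n_leapfrog=n_leapfrog,
            target_accept=target_accept, seed=int(rng.integers(2**31 - 1)),
        )
        res = sample_hmc(self.logp_and_grad, x0, cfg)
        if res.n_divergent > 0:
            logger.warning("%d divergent transitions after warmup", res.n_divergent)
        D = res.n_draws
        r = np.empty((D, self.N, self.T, self.K))
        r_mean = np.empty_like(r)
        mu_draws = np.empty((D, self.K))
        mu_t_draws = np.empty((D, self.T, self.K))
        for i, xd in enumerate(res.draws):
            st = self.unpack(xd)
            r[i] = st.r
            r_mean[i] = alr_inverse(self.process_mean_field(st), axis=2)
            mu_draws[i] = st.mu
            mu_t_draws[i] = st.mu_t
        return PredictionResults(
            model=self, r=r, r_mean=r_mean, mu=mu_draws, mu_t=mu_t_draws,
            accept_rate=res.accept_rate, step_size=res.step_size,
            n_divergent=res.n_divergent, logp=res.logp, seed=seed, thin=thin,
        )


@dataclass
class PredictionResults:
    """Posterior draws of the composition fields plus sampler diagnostics."""

    model: PredictionModel
    r: np.ndarray          # (D, N, T, K) full-field composition draws
    r_mean: np.ndarray     # (D, N, T, K) process-mean composition draws
    mu: np.ndarray         # (D, K)
    mu_t: np.ndarray       # (D, T, K)
    accept_rate: float
    step_size: float
    n_divergent: int
    logp: np.ndarray
    seed: int = 0
    thin: int = 1

    @property
    def n_draws(self) -> int:
        return self.r.shape[0]

    @property
    def posterior_mean_r(self) -> np.ndarray:
        return self.r.mean(axis=0)

    def credible_interval(self, level: float = 0.9, source: str = "full_field") -> np.ndarray:
        """Equal-tailed credible band of composition, shape (2, N, T, K)."""
        draws = self.r if source == "full_field" else self.r_mean
        q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
        return np.percentile(draws, q, axis=0)

    def diagnostics(self) -> dict:
        """Split-Rhat and ESS on tracked scalar series, plus HMC stats."""
        import arviz as az

        # split the single chain in two so rhat is the split statistic
        half = (self.n_draws // 2) * 2
        tracked = {
            "mu": self.mu[:half].reshape(2, half // 2, self.model.K),
            "mu_t": self.mu_t[:half, 1:, :].reshape(2, half // 2, self.model.T - 1, self.model.K),
        }
        idata = az.from_dict(posterior=tracked)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        rhat_max = float(max(np.nanmax(rhat[v].values) for v in rhat.data_vars))
        ess_min = float(min(np.nanmin(ess[v].values) for v in ess.data_vars))
        return {
            "accept_rate": self.accept_rate,
            "step_size": self.step_size,
            "n_divergent": self.n_divergent,
            "rhat_max": rhat_max,
            "ess_min": ess_min,
            "n_draws": self.n_draws,
        }

    def summary(self) -> pd.DataFrame:
        """Per-taxon posterior summary of domain-mean composition by bin."""
        rows = []
        mid = self.model.data.bin_mid
        for t in range(self.model.T):
            for k, name in enumerate(self.model.data.taxa):
                d = self.r[:, :, t, k].mean(axis=1)
                rows.append(
                    {
                        "bin_yb1950": mid[t],
                        "taxon": name,
                        "mean": d.mean(),
                        "sd": d.std(),
                        "q05": np.percentile(d, 5),
                        "q95": np.percentile(d, 95),
                    }
                )
        return pd.DataFrame(rows)

    def plot_composition(self, taxon: int | str, time_bin: int, ax=None):
        """Map the posterior-mean proportion of one taxon at one time bin."""
        from .plotting import plot_composition_map

        k = (self.model.data.taxa.index(taxon)
             if isinstance(taxon, str) else int(taxon))
        field = self.posterior_mean_r[:, time_bin, k]
        label = self.model.data.taxa[k]
        mid = self.model.data.bin_mid[time_bin]
        return plot_composition_map(field, self.model.grid, ax=ax,
                                    title=f"{label}, {mid:.0f} YB1950")

    def to_ensemble(self, provenance: dict | None = None) -> PosteriorEnsemble:
        prov = dict(provenance or {})
        prov.setdefault("seed", self.seed)
        prov.setdefault("thin", self.thin)
        return PosteriorEnsemble(
            r=self.r,
            r_mean=self.r_mean,
            bin_edges=self.model.data.bin_edges,
            taxa=self.model.data.taxa,
            provenance=[prov],
        )
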