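"""Calibration stage: estimating the pollen-vegetation process parameters.

Given a settlement-era pair — gridded forest composition (known) and pollen
counts at point sites — the calibration model estimates, with uncertainty,
the per-taxon local fraction gamma_k, the pollen productivity phi_k, and the
dispersal-kernel parameters theta, under the Dirichlet-multinomial
likelihood with local/non-local mixing.  The posterior is explored with an
affine-invariant ensemble sampler; the resulting draws feed the prediction
stage, one draw per prediction run, so calibration uncertainty propagates
into the reconstructions.

Priors (overridable): gamma_k ~ Beta(2, 2); log phi_k ~ Normal(log 10, 3^2)
(the concentration total is identified by the data through overdispersion,
so phi is sampled freely rather than normalized); kernel scale
a ~ half-Normal(domain diameter / 4); shape b - 2 ~ half-Normal(2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln as gammaln_

from .grids import Grid, KernelParams, WeightMatrix, kernel_density, pairwise_distance

__all__ = [
    "CalibrationPriors",
    "CalibrationDraw",
    "CalibrationModel",
    "CalibrationResults",
]


@dataclass(frozen=True)
class CalibrationPriors:
    gamma_alpha: float = 2.0
    gamma_beta: float = 2.0
    log_phi_loc: float = np.log(10.0)
    log_phi_scale: float = 3.0
    a_scale: float | None = None   # default: domain diameter / 4
    b_shift_scale: float = 2.0     # half-Normal scale of b - 2


@dataclass(frozen=True)
class CalibrationDraw:
    """One joint posterior draw of the calibration parameters."""

    gamma: np.ndarray       # (K,)
    phi: np.ndarray         # (K,)
    kernel: KernelParams


class CalibrationModel:
    """Pollen-vegetation calibration model for a settlement-era pair.

    Parameters
    ----------
    composition : (n_cells, K) array
        Known relative-abundance surface; rows sum to 1.
    counts : (n_sites, K) int array
        Pollen counts per site.
    site_coords : (n_sites, 2) array
        Site coordinates in km; each site must fall within the grid domain.
    grid : Grid
    kernel_family : {"inverse_power_law", "gaussian"}
    priors : CalibrationPriors
    """

    def __init__(
        self,
        composition: np.ndarray,
        counts: np.ndarray,
        site_coords: np.ndarray,
        grid: Grid,
        kernel_family: str = "inverse_power_law",
        priors: CalibrationPriors | None = None,
        taxa: tuple[str, ...] | None = None,
    ) -> None:
        self.composition = np.asarray(composition, dtype=float)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.grid = grid
        self.kernel_family = kernel_family
        self.priors = priors or CalibrationPriors()
        self.K = self.composition.shape[1]
        self.taxa = taxa or tuple(f"taxon_{k}" for k in range(self.K))
        if self.counts.shape[1] != self.K:
            raise ValueError("counts and composition disagree on taxon count")
        if not np.allclose(self.composition.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("composition rows must sum to 1")
        self.site_coords = np.asarray(site_coords, dtype=float)
        self.site_cells = grid.cell_of(self.site_coords)
        half = grid.cell_size / 2.0
        lo = grid.cell_centers.min(axis=0) - half
        hi = grid.cell_centers.max(axis=0) + half
        if np.any(self.site_coords < lo) or np.any(self.site_coords > hi):
            raise ValueError("all sites must fall inside the grid domain")
        # kernel params vary during sampling; cache distances and constants
        self._d = pairwise_distance(grid.cell_centers, grid.cell_centers)
        self._d_site = self._d[self.site_cells].copy()
        self._site_self = (np.arange(len(self.site_cells)), self.site_cells)
        self._cell_area = grid.cell_area
        self._totals = self.counts.sum(axis=1)
        self._log_coef = float(np.sum(gammaln_(self._totals + 1.0)
                                      - gammaln_(self.counts + 1.0).sum(axis=1)))
        diam = float(self._d.max())
        self._a_scale = self.priors.a_scale or diam / 4.0

    # --- parameter vector: [logit gamma (K), log phi (K), log a, log(b-2)] ---
    @property
    def n_params(self) -> int:
        return 2 * self.K + (2 if self.kernel_family == "inverse_power_law" else 1)

    def _unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, KernelParams]:
        K = self.K
        gamma = 1.0 / (1.0 + np.exp(-theta[:K]))
        phi = np.exp(theta[K : 2 * K])
        a = float(np.exp(theta[2 * K]))
        if self.kernel_family == "inverse_power_law":
            b = 2.0 + float(np.exp(theta[2 * K + 1]))
            kp = KernelParams("inverse_power_law", a=a, b=b)
        else:
            kp = KernelParams("gaussian", a=a)
        return gamma, phi, kp

    def _weights(self, kp: KernelParams) -> WeightMatrix:
        W = kernel_density(self._d, kp) * self._cell_area
        np.fill_diagonal(W, 0.0)
        return WeightMatrix(W=W, C=W.sum(axis=1), params=kp)

    def log_prior(self, theta: np.ndarray) -> float:
        # direct densities (incl. unconstraining Jacobians); Beta(a,b) on
        # gamma, lognormal phi, half-Normal kernel scale and tail shape
        K, pr = self.K, self.priors
        lg, lph = theta[:K], theta[K : 2 * K]
        if np.any(np.abs(lg) > 30) or np.any(np.abs(theta[2 * K :]) > 30):
            return -np.inf
        log_gamma = -np.logaddexp(0.0, -lg)       # log sigmoid
        log_1mg = -np.logaddexp(0.0, lg)
        beta_norm = (gammaln_(pr.gamma_alpha + pr.gamma_beta)
                     - gammaln_(pr.gamma_alpha) - gammaln_(pr.gamma_beta))
        lp = float(np.sum(pr.gamma_alpha * log_gamma + pr.gamma_beta * log_1mg)) + K * beta_norm
        z = (lph - pr.log_phi_loc) / pr.log_phi_scale
        lp += float(np.sum(-0.5 * z**2)) - K * (np.log(pr.log_phi_scale)
                                                + 0.5 * np.log(2 * np.pi))
        half_const = 0.5 * np.log(2.0 / np.pi)
        a = np.exp(theta[2 * K])
        lp += half_const - np.log(self._a_scale) - a**2 / (2 * self._a_scale**2) + theta[2 * K]
        if self.kernel_family == "inverse_power_law":
            b_shift = np.exp(theta[2 * K + 1])
            lp += (half_const - np.log(pr.b_shift_scale)
                   - b_shift**2 / (2 * pr.b_shift_scale**2) + theta[2 * K + 1])
        return lp

    def log_likelihood(self, theta: np.ndarray) -> float:
        gamma, phi, kp = self._unpack(theta)
        d = self._d_site  # (S, n_cells) focal-row distances, diagonal-excluded
        Wrow = kernel_density(d, kp) * self._cell_area
        Wrow[self._site_self] = 0.0
        C = Wrow.sum(axis=1)
        if np.any(C <= 0):
            return -np.inf
        nonlocal_r = (Wrow / C[:, None]) @ self.composition      # (S, K)
        local_r = self.composition[self.site_cells]              # (S, K)
        conc = phi * (gamma * local_r + (1.0 - gamma) * nonlocal_r)
        if np.any(conc <= 0):
            return -np.inf
        n = self._totals
        A = conc.sum(axis=1)
        ll = (np.sum(gammaln_(A) - gammaln_(n + A))
              + np.sum(gammaln_(self.counts + conc) - gammaln_(conc)))
        return float(ll) + self._log_coef

    def log_posterior(self, theta: np.ndarray) -> float:
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.log_likelihood(theta)
        return lp + ll if np.isfinite(ll) else -np.inf

    def fit(
        self,
        n_steps: int = 4000,
        n_walkers: int | None = None,
        burn: int | None = None,
        thin: int = 10,
        seed: int = 0,
    ) -> "CalibrationResults":
        """Sample the calibration posterior; reproducible given ``seed``."""
        import emcee

        from scipy.optimize import minimize

        dim = self.n_params
        n_walkers = n_walkers or max(2 * dim + 2, 48)
        burn = burn if burn is not None else n_steps // 2
        rng = np.random.default_rng(seed)
        x0 = np.zeros(dim)
        x0[self.K : 2 * self.K] = self.priors.log_phi_loc
        x0[2 * self.K] = np.log(self._a_scale / 2.0)
        # warm-start walkers near the posterior mode to shorten burn-in
        opt = minimize(lambda th: -self.log_posterior(th), x0,
                       method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-3, "fatol": 1e-2})
        if np.isfinite(opt.fun):
            x0 = opt.x
        p0 = x0 + 0.2 * rng.standard_normal((n_walkers, dim))
        sampler = emcee.EnsembleSampler(
            n_walkers, dim, self.log_posterior,
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        sampler.random_state = np.random.RandomState(seed + 1).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=burn, thin=thin, flat=True)
        acc = float(np.mean(sampler.acceptance_fraction))
        try:
            act = sampler.get_autocorr_time(discard=burn, quiet=True)
        except Exception:  # pragma: no cover - emcee raises on short chains
            act = np.full(dim, np.nan)
        return CalibrationResults(model=self, chain=chain, accept_fraction=acc,
                                  autocorr_time=np.asarray(act, dtype=float))


@dataclass
class CalibrationResults:
    """Posterior draws of (gamma_k, phi_k, theta) and convenience accessors."""

    model: CalibrationModel
    chain: np.ndarray                  # (n_draws, n_params), unconstrained scale
    accept_fraction: float
    autocorr_time: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_draws(self) -> int:
        return len(self.chain)

    @property
    def gamma(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.chain[:, : self.model.K]))

    @property
    def phi(self) -> np.ndarray:
        return np.exp(self.chain[:, self.model.K : 2 * self.model.K])

    @property
    def kernel_a(self) -> np.ndarray:
        return np.exp(self.chain[:, 2 * self.model.K])

    @property
    def kernel_b(self) -> np.ndarray:
        if self.model.kernel_family != "inverse_power_law":
            raise AttributeError("gaussian kernel has no shape parameter b")
        return 2.0 + np.exp(self.chain[:, 2 * self.model.K + 1])

    def draw(self, index: int | None = None, rng: np.random.Generator | None = None) -> CalibrationDraw:
        """One joint draw, by index or sampled uniformly with ``rng``."""
        if index is None:
            rng = rng or np.random.default_rng()
            index = int(rng.integers(self.n_draws))
        theta = self.chain[index]
        gamma, phi, kp = self.model._unpack(theta)
        return CalibrationDraw(gamma=gamma, phi=phi, kernel=kp)

    def median_draw(self) -> CalibrationDraw:
        theta = np.median(self.chain, axis=0)
        gamma, phi, kp = self.model._unpack(theta)
        return CalibrationDraw(gamma=gamma, phi=phi, kernel=kp)

    def credible_interval(self, param: str, level: float = 0.9) -> np.ndarray:
        """Equal-tailed credible intervals, shape (K, 2) or (2,) for kernel params."""
        draws = getattr(self, param)
        q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
        return np.percentile(draws, q, axis=0).T

    def summary(self) -> pd.DataFrame:
        """Posterior summary table (mean, sd, 5%/50%/95% quantiles)."""
        rows = []
        names = (
            [f"gamma[{t}]" for t in self.model.taxa]
            + [f"phi[{t}]" for t in self.model.taxa]
            + ["kernel_a"]
            + (["kernel_b"] if self.model.kernel_family == "inverse_power_law" else [])
        )
        cols = [self.gamma, self.phi, self.kernel_a[:, None]]
        if self.model.kernel_family == "inverse_power_law":
            cols.append(self.kernel_b[:, None])
        draws = np.column_stack(cols)
        for name, d in zip(names, draws.T):
            rows.append(
                {
                    "param": name,
                    "mean": np.mean(d),
                    "sd": np.std(d),
                    "q05": np.percentile(d, 5),
                    "median": np.percentile(d, 50),
                    "q95": np.percentile(d, 95),
                }
            )
        return pd.DataFrame(rows).set_index("param")
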