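"""Spatial building blocks of the prediction stage.

The latent per-taxon fields are Gaussian processes with isotropic
exponential covariance eta^2 * exp(-d / rho), represented through a
*modified predictive process*: the process is estimated at a reduced set of
knot locations and projected to the full grid by the kriging operator
c C*^-1, with a per-cell variance correction restoring the fine-scale
variance the low-rank projection cannot carry, plus a small fixed nugget
tau^2 = 1e-5 keeping the conditional variance positive at knot-coincident
cells.  Latent fields map to the composition simplex through the additive
log-ratio (softmax) link.

The marginal scale eta_k and range rho_k are estimated a priori from the
settlement-era composition by fitting the same predictive-process model to
the ALR-transformed composition surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky

from .grids import Grid, pairwise_distance

__all__ = [
    "DEFAULT_NUGGET",
    "KnotSet",
    "SpatialHyperparams",
    "exponential_covariance",
    "predictive_process_project",
    "process_variance",
    "process_mean",
    "temporal_mean_prior",
    "innovation_prior",
    "alr_inverse",
    "alr_transform",
    "fit_spatial_hyperparams",
]

logger = logging.getLogger(__name__)

DEFAULT_NUGGET = 1e-5
_JITTER = 1e-8


def exponential_covariance(d: np.ndarray, eta: float, rho: float) -> np.ndarray:
    """Isotropic exponential covariance eta^2 * exp(-d / rho)."""
    if eta <= 0 or rho <= 0:
        raise ValueError("eta and rho must be positive")
    return eta**2 * np.exp(-np.asarray(d, dtype=float) / rho)


@dataclass(frozen=True)
class KnotSet:
    """Knot locations with precomputed distances to themselves and the grid."""

    knots: np.ndarray          # (M, 2) km
    d_knots: np.ndarray        # (M, M)
    d_cross: np.ndarray        # (N, M) grid cells x knots

    @classmethod
    def from_grid(cls, grid: Grid, every: int = 2) -> "KnotSet":
        """Regular subgrid knots: every ``every``-th cell in each direction."""
        if every < 1:
            raise ValueError("knot spacing must be >= 1")
        ny, nx = grid.shape
        idx = np.arange(grid.n_cells).reshape(ny, nx)[::every, ::every].ravel()
        knots = grid.cell_centers[idx]
        return cls(
            knots=knots,
            d_knots=pairwise_distance(knots, knots),
            d_cross=pairwise_distance(grid.cell_centers, knots),
        )

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def covariances(self, eta: float, rho: float) -> tuple[np.ndarray, np.ndarray]:
        """(C*, c): knot covariance (M, M) and cross-covariance (N, M)."""
        return (
            exponential_covariance(self.d_knots, eta, rho),
            exponential_covariance(self.d_cross, eta, rho),
        )


@dataclass(frozen=True)
class SpatialHyperparams:
    """Fixed hyperparameters of the latent spatiotemporal process.

    eta : (K,) marginal standard deviation of each taxon's latent field.
    rho : (K,) spatial range in km.
    omega : innovation autoregression coefficient, |omega| < 1.
    xi : innovation sd of the temporal (spatially invariant) mean.
    tau2 : nugget variance, fixed at 1e-5.
    mu_scale : prior sd of the overall per-taxon adjustment mu_k.
    """

    eta: np.ndarray
    rho: np.ndarray
    omega: float = 0.8
    xi: float = 0.1
    tau2: float = DEFAULT_NUGGET
    mu_scale: float = 1.0
    temporal_model: str = "random_walk"  # or "ar1" (damped, mean omega*mu_prev)

    def __post_init__(self) -> None:
        eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "rho", rho)
        if np.any(eta <= 0) or np.any(rho <= 0):
            raise ValueError("eta and rho must be positive")
        if not abs(self.omega) < 1:
            raise ValueError("|omega| must be < 1")
        if self.xi < 0 or self.tau2 <= 0:
            raise ValueError("xi must be >= 0 and tau2 > 0")
        if self.temporal_model not in ("random_walk", "ar1"):
            raise ValueError("temporal_model must be 'random_walk' or 'ar1'")


def _chol_with_jitter(C: np.ndarray, what: str = "covariance") -> np.ndarray:
    try:
        return cholesky(C, lower=True)
    except np.linalg.LinAlgError:
        logger.warning("adding %.0e jitter to %s diagonal", _JITTER, what)
        try:
            return cholesky(C + _JITTER * np.eye(len(C)), lower=True)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"{what} not positive definite after jitter") from err


def predictive_process_project(
    alpha: np.ndarray, c: np.ndarray, C_star: np.ndarray
) -> np.ndarray:
    """Project knot coefficients to the grid: nu = c C*^-1 alpha."""
    if c.shape[1] != C_star.shape[0]:
        raise ValueError("cross-covariance and knot covariance shapes do not conform")
    L = _chol_with_jitter(C_star, "knot covariance")
    return c @ cho_solve((L, True), np.asarray(alpha, dtype=float))


def explained_variance(c: np.ndarray, C_star: np.ndarray) -> np.ndarray:
    """Per-cell predictive-process explained variance diag(c C*^-1 c')."""
    L = _chol_with_jitter(C_star, "knot covariance")
    half = np.linalg.solve(L, c.T)  # (M, N)
    return np.sum(half * half, axis=0)


def process_variance(
    knots: KnotSet,
    eta: float,
    rho: float,
    omega: float,
    tau2: float = DEFAULT_NUGGET,
    t_is_first: bool = True,
) -> np.ndarray:
    """Conditional variance sigma^2 of the latent field at each grid cell.

    The marginal variance eta^2 minus the variance the predictive process
    already explains, plus the nugget; for t > 1 the same correction enters
    once more scaled by (1 - omega^2) for the innovation process.  Cells
    coincident with knots reduce to tau^2 exactly.  Negative values from
    round-off are clipped at tau2 with a warning.
    """
    C_star, c = knots.covariances(eta, rho)
    corr = eta**2 - explained_variance(c, C_star)
    sigma2 = corr + tau2 if t_is_first else corr + (1 - omega**2) * corr + tau2
    if np.any(sigma2 < tau2 - 1e-12):
        logger.warning("clipping %d negative process variances at tau2", int((sigma2 < tau2).sum()))
    return np.clip(sigma2, tau2, None)


def process_mean(
    mu: float,
    nu_s: np.ndarray,
    mu_t: float | None = None,
    nu_st: np.ndarray | None = None,
    t: int = 1,
) -> np.ndarray:
    """Latent process mean: mu + nu^s at t=1; adds mu^t + nu^st for t > 1."""
    if t < 1:
        raise ValueError("time index starts at 1")
    base = mu + np.asarray(nu_s, dtype=float)
    if t == 1:
        return base
    return base + (0.0 if mu_t is None else mu_t) + (0.0 if nu_st is None else np.asarray(nu_st))


def temporal_mean_prior(
    mu_t_prev: float, xi: float, t: int, omega_t: float | None = None
):
    """Prior of the temporal mean mu^t_t: N(0, xi^2) at t=2, else a random
    walk N(mu^t_{t-1}, xi^2) (or damped AR(1) N(omega_t mu^t_{t-1}, xi^2))."""
    if t < 2:
        raise ValueError("temporal mean is defined for t >= 2")
    if t == 2:
        return stats.norm(0.0, xi)
    mean = mu_t_prev if omega_t is None else omega_t * mu_t_prev
    return stats.norm(mean, xi)


def innovation_prior(alpha_prev: np.ndarray, omega: float, C_star: np.ndarray):
    """AR(1) prior of knot innovation coefficients:
    MVN(omega * alpha_prev, (1 - omega^2) C*); stationary covariance C*."""
    if not abs(omega) < 1:
        raise ValueError("|omega| must be < 1")
    cov = (1 - omega**2) * C_star + _JITTER * np.eye(len(C_star))
    return stats.multivariate_normal(mean=omega * np.asarray(alpha_prev, dtype=float), cov=cov)


def alr_inverse(g: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax link from latent fields to the composition simplex."""
    g = np.asarray(g, dtype=float)
    g_shift = g - np.max(g, axis=axis, keepdims=True)
    e = np.exp(g_shift)
    return e / np.sum(e, axis=axis, keepdims=True)


def alr_transform(r: np.ndarray, axis: int = -1, floor: float = 1e-6) -> np.ndarray:
    """Centered log-ratio representative of softmax^-1 (defined up to a
    constant shift); proportions floored at ``floor`` before the log."""
    r = np.clip(np.asarray(r, dtype=float), floor, None)
    logr = np.log(r)
    return logr - np.mean(logr, axis=axis, keepdims=True)


def _pp_marginal_loglik(
    g: np.ndarray, knots: KnotSet, eta: float, rho: float, mean: float, tau2: float
) -> float:
    """Gaussian log-likelihood of a field under the predictive-process model.

    Covariance c C*^-1 c' + diag(eta^2 - explained + tau2), evaluated with
    the Woodbury identity so cost scales with the knot count.
    """
    C_star, c = knots.covariances(eta, rho)
    dvec = np.clip(eta**2 - explained_variance(c, C_star), 0.0, None) + tau2
    resid = g - mean
    # Woodbury: (D + c C*^-1 c')^-1 ; let U = c, A = C*
    Dinv_c = c / dvec[:, None]
    inner = C_star + c.T @ Dinv_c
    L_star = _chol_with_jitter(C_star, "knot covariance")
    L_inner = _chol_with_jitter(inner, "inner matrix")
    tmp = cho_solve((L_inner, True), Dinv_c.T @ resid)
    quad = resid @ (resid / dvec) - (Dinv_c.T @ resid) @ tmp
    logdet = (
        np.sum(np.log(dvec))
        + 2 * np.sum(np.log(np.diag(L_inner)))
        - 2 * np.sum(np.log(np.diag(L_star)))
    )
    return -0.5 * (quad + logdet + len(g) * np.log(2 * np.pi))


def fit_field_hyperparams(
    field: np.ndarray,
    grid: Grid,
    knots: KnotSet,
    seed: int = 0,
    tau2: float = DEFAULT_NUGGET,
    n_steps: int = 300,
    n_walkers: int = 12,
) -> tuple[float, float]:
    """Maximum-likelihood (eta, rho) for one latent field on the grid.

    Maximizes the modified-predictive-process marginal likelihood (same
    knots and domain as prediction) over (log eta, log rho, mean) by
    multistart Nelder-Mead; the point estimates are used as fixed inputs
    downstream.  ``seed``/``n_steps``/``n_walkers`` are accepted for
    interface stability; the optimizer itself is deterministic.
    """
    from scipy.optimize import minimize

    gk = np.asarray(field, dtype=float)
    if gk.shape != (grid.n_cells,):
        raise ValueError("field must have one value per grid cell")
    diam = float(np.max(pairwise_distance(grid.cell_centers, grid.cell_centers)))
    lo_eta, hi_eta, lo_rho, hi_rho = -8.0, 8.0, np.log(1e-2), np.log(10 * diam)

    def nll(theta: np.ndarray) -> float:
        log_eta, log_rho, mean = theta
        if not (lo_eta < log_eta < hi_eta and lo_rho < log_rho < hi_rho):
            return 1e12
        try:
            return -_pp_marginal_loglik(gk, knots, np.exp(log_eta), np.exp(log_rho), mean, tau2)
        except np.linalg.LinAlgError:
            return 1e12

    sd0 = max(float(np.std(gk)), 1e-3)
    best = None
    for rho0 in (diam / 8.0, diam / 3.0, diam):
        res = minimize(
            nll, np.array([np.log(sd0), np.log(rho0), float(np.mean(gk))]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 1500},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(np.exp(best.x[0])), float(np.exp(best.x[1]))


def fit_spatial_hyperparams(
    settlement_composition: np.ndarray,
    grid: Grid,
    knots: KnotSet,
    seed: int = 0,
    tau2: float = DEFAULT_NUGGET,
    n_steps: int = 300,
    n_walkers: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate (eta_k, rho_k) per taxon from settlement-era composition.

    Each taxon's centered log-ratio field is fitted independently with
    :func:`fit_field_hyperparams`; posterior medians are returned and used
    as fixed inputs downstream.
    """
    r = np.asarray(settlement_composition, dtype=float)
    if r.shape[0] != grid.n_cells:
        raise ValueError("composition does not cover the grid")
    g_fields = alr_transform(r, axis=1)
    K = r.shape[1]
    etas, rhos = np.empty(K), np.empty(K)
    for k in range(K):
        etas[k], rhos[k] = fit_field_hyperparams(
            g_fields[:, k], grid, knots, seed=seed + 1000 * k,
            tau2=tau2, n_steps=n_steps, n_walkers=n_walkers,
        )
    return etas, rhos
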