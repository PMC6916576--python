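"""Adaptive Hamiltonian Monte Carlo with hand-coded gradients.

A compact HMC engine used for the prediction-stage posterior, where the
latent dimension (thousands of whitened field values) rules out
gradient-free samplers.  Warm-up adapts the leapfrog step size by dual
averaging (targeting a given acceptance statistic) and estimates a diagonal
mass matrix from an intermediate adaptation window; sampling uses a jittered
number of leapfrog steps to avoid periodic trajectories.  Divergent
transitions (large energy error) are counted and reported, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["HMCConfig", "HMCResult", "sample_hmc"]

_DIVERGENCE_ENERGY = 1000.0


@dataclass
class HMCConfig:
    warmup: int = 300
    samples: int = 600
    thin: int = 1
    n_leapfrog: int = 24
    target_accept: float = 0.8
    init_step_size: float = 0.1
    max_step_size: float = 2.0
    seed: int = 0


@dataclass
class HMCResult:
    """Retained draws plus sampler diagnostics."""

    draws: np.ndarray  # (n_kept, dim)
    accept_rate: float
    step_size: float
    n_divergent: int
    logp: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def _leapfrog(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    p = p + 0.5 * eps * grad
    lp = -np.inf
    for step in range(n_steps):
        x = x + eps * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, -np.inf, grad, False
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, lp, grad, True


def sample_hmc(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    config: HMCConfig,
) -> HMCResult:
    """Run adaptive HMC from ``x0``.

    ``logp_grad`` returns the log target density and its gradient.  Draws
    are collected after ``config.warmup`` adaptation iterations and thinned
    by ``config.thin``.  Fully reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    x = np.array(x0, dtype=float)
    dim = x.size
    inv_mass = np.ones(dim)
    sqrt_mass = np.ones(dim)

    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    # dual averaging state (Hoffman & Gelman 2014 defaults)
    eps = config.init_step_size
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    n_total = config.warmup + config.samples
    mass_lo = int(0.4 * config.warmup)
    mass_hi = int(0.8 * config.warmup)
    mass_window: list[np.ndarray] = []

    kept, logps = [], []
    n_divergent = 0
    accept_sum, accept_n = 0.0, 0

    for it in range(n_total):
        p = rng.standard_normal(dim) * sqrt_mass
        h0 = -lp + 0.5 * np.sum(inv_mass * p * p)
        n_steps = int(rng.integers(max(1, int(0.8 * config.n_leapfrog)),
                                   int(1.2 * config.n_leapfrog) + 1))
        x_new, p_new, lp_new, grad_new, ok = _leapfrog(
            logp_grad, x, p, grad, eps, n_steps, inv_mass
        )
        if ok:
            h1 = -lp_new + 0.5 * np.sum(inv_mass * p_new * p_new)
            d_energy = h1 - h0
            alpha = min(1.0, np.exp(min(0.0, -d_energy)))
            divergent = d_energy > _DIVERGENCE_ENERGY
        else:
            alpha, divergent = 0.0, True
        if divergent and it >= config.warmup:
            n_divergent += 1
        if ok and (not divergent) and rng.uniform() < alpha:
            x, lp, grad = x_new, lp_new, grad_new

        if it < config.warmup:
            # dual averaging of the step size
            m = it + 1
            h_bar = (1 - 1 / (m + t0_da)) * h_bar + (config.target_accept - alpha) / (m + t0_da)
            log_eps = mu_da - np.sqrt(m) / gamma_da * h_bar
            eta = m**-kappa_da
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = min(np.exp(log_eps), config.max_step_size)
            if mass_lo <= it < mass_hi:
                mass_window.append(x.copy())
            if it == mass_hi - 1 and len(mass_window) >= 10:
                var = np.var(np.asarray(mass_window), axis=0)
                var = np.clip(var, 1e-4, 1e4)
                inv_mass = var            # mass = 1/var, kinetic uses inv mass
                sqrt_mass = 1.0 / np.sqrt(var)
                # restart step-size adaptation under the new metric
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar = np.log(eps), 0.0
            if it == config.warmup - 1:
                eps = min(np.exp(log_eps_bar), config.max_step_size)
        else:
            accept_sum += alpha
            accept_n += 1
            if (it - config.warmup) % config.thin == 0:
                kept.append(x.copy())
                logps.append(lp)

    return HMCResult(
        draws=np.asarray(kept),
        accept_rate=accept_sum / max(accept_n, 1),
        step_size=float(eps),
        n_divergent=n_divergent,
        logp=np.asarray(logps),
    )
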