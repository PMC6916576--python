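"""Dirichlet-multinomial pollen likelihood and local/non-local mixing.

Pollen counts y_{i,.} at a sedimentary basin i are modelled as
Dirichlet-multinomial, DM(n_i, phi_i), with concentration vector phi_i built
by mixing the focal cell's vegetation with kernel-weighted vegetation from
all other cells:

    phi_{i,k} = gamma_k * phi_prod_k * r[s(i), k]
              + (1 - gamma_k) * phi_prod_k * (1/C_i) * sum_{j != s(i)} r[j, k] W[s(i), j]

where gamma_k splits local from non-local pollen, phi_prod_k is the pollen
productivity of taxon k, and W / C are the kernel weight matrix and its
per-focal-cell scaling.  The concentration total sum_k phi_{i,k} governs
overdispersion relative to the multinomial (larger total -> closer to
multinomial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .grids import WeightMatrix

__all__ = [
    "TaxonSet",
    "PollenSample",
    "dm_log_pmf",
    "phi_mixing",
    "mixing_operator",
    "overdispersion_index",
]


@dataclass(frozen=True)
class TaxonSet:
    """Ordered taxon labels (e.g. 10 genera + Other Hardwood + Other Conifer)."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("taxon labels must be unique")
        if len(self.names) < 2:
            raise ValueError("need at least two taxa")

    @property
    def K(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class PollenSample:
    """Taxon counts for one sedimentary-basin sample."""

    site_id: str
    counts: np.ndarray
    x_km: float = np.nan
    y_km: float = np.nan

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def dm_log_pmf(counts: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Log pmf of the Dirichlet-multinomial distribution.

    Parameters
    ----------
    counts : (..., K) int array
        Category counts; the trial total is their sum along the last axis.
    phi : (..., K) positive array
        Concentration parameters (broadcast against ``counts``).

    Returns
    -------
    Log probability, shape of the broadcast leading dims.  For n = 0 the
    pmf is 1 (log 0.0).
    """
    counts = np.asarray(counts, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if counts.shape[-1] != phi.shape[-1]:
        raise ValueError(
            f"counts have K={counts.shape[-1]} but phi has K={phi.shape[-1]}"
        )
    if np.any(phi <= 0):
        raise ValueError("all concentration parameters must be positive")
    n = counts.sum(axis=-1)
    A = phi.sum(axis=-1)
    # multinomial coefficient + Dirichlet normalization ratio
    log_coef = gammaln(n + 1.0) - gammaln(counts + 1.0).sum(axis=-1)
    log_ratio = (
        gammaln(A)
        - gammaln(n + A)
        + (gammaln(counts + phi) - gammaln(phi)).sum(axis=-1)
    )
    return log_coef + log_ratio


def mixing_operator(gamma: np.ndarray, weights: WeightMatrix, site_cells: np.ndarray) -> np.ndarray:
    """Per-taxon linear operators mapping composition fields to mixed proportions.

    Returns M of shape (K, n_sites, n_cells) such that for taxon k
    ``phi[:, k] = phi_prod[k] * (M[k] @ r[:, k])``.  Row i of M[k] is
    gamma_k on the site's own cell plus (1 - gamma_k) times the normalized
    kernel weights of all other cells.  On a single-cell grid (C = 0) the
    non-local term vanishes and only gamma_k of the local cell remains.
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    site_cells = np.asarray(site_cells, dtype=int)
    Wn = weights.normalized[site_cells]  # (n_sites, n_cells); zero rows if C = 0
    K, n_sites, n_cells = len(gamma), len(site_cells), weights.W.shape[0]
    M = np.zeros((K, n_sites, n_cells))
    for k in range(K):
        M[k] = (1.0 - gamma[k]) * Wn
        M[k, np.arange(n_sites), site_cells] += gamma[k]
    return M


def phi_mixing(
    r: np.ndarray,
    gamma: np.ndarray,
    phi_prod: np.ndarray,
    weights: WeightMatrix,
    site_cell: int | np.ndarray,
) -> np.ndarray:
    """DM concentration vector(s) from local + kernel-weighted non-local vegetation.

    Parameters
    ----------
    r : (n_cells, K) array
        Composition field for one time; rows sum to 1.
    gamma : (K,) array in [0, 1]
        Local fraction per taxon.
    phi_prod : (K,) positive array
        Pollen productivity per taxon.
    weights : WeightMatrix
    site_cell : int or (n_sites,) int array
        Grid cell(s) containing the site(s).

    Returns
    -------
    (K,) vector for a scalar site_cell, else (n_sites, K).
    """
    r = np.asarray(r, dtype=float)
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    phi_prod = np.atleast_1d(np.asarray(phi_prod, dtype=float))
    K = r.shape[1]
    if not (len(gamma) == len(phi_prod) == K):
        raise ValueError(
            f"taxon count mismatch: r has K={K}, gamma {len(gamma)}, phi {len(phi_prod)}"
        )
    scalar = np.isscalar(site_cell) or np.ndim(site_cell) == 0
    cells = np.atleast_1d(np.asarray(site_cell, dtype=int))
    M = mixing_operator(gamma, weights, cells)  # (K, n_sites, n_cells)
    phi = np.empty((len(cells), K))
    for k in range(K):
        phi[:, k] = phi_prod[k] * (M[k] @ r[:, k])
    return phi[0] if scalar else phi


def overdispersion_index(phi: np.ndarray) -> float:
    """Concentration total sum_k phi_k; larger means closer to multinomial."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    return float(phi.sum())
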