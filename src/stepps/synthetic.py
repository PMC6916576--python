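"""Synthetic inputs with the statistical structure the analysis assumes.

Emulates the three real data products the pipeline consumes — a gridded
settlement-era composition surface, fossil pollen records with age-model
uncertainty, and the calibration pollen/vegetation pair — by simulating
forward from the model itself: latent Gaussian fields with exponential
spatial covariance through the modified predictive process, centennial-scale
compositional drift from the temporal random walk and AR(1) innovations,
Dirichlet-multinomial pollen counts mixed from local and kernel-weighted
non-local vegetation, and monotone age-depth perturbations of decadal to
centennial magnitude.  Truth is retained for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid, KernelParams, WeightMatrix, build_grid, kernel_density, pairwise_distance
from .likelihood import phi_mixing
from .prediction import BinnedPollen, LatentState
from .spatial import KnotSet, SpatialHyperparams, _chol_with_jitter, alr_inverse, process_variance

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_composition",
    "simulate_pollen",
    "simulate_records",
    "simulate_age_draws",
    "make_fixture",
    "PRESETS",
]

_CANONICAL_TAXA = (
    "pine", "oak", "birch", "maple", "spruce", "hemlock", "elm", "ash",
    "tamarack", "beech", "other_hardwood", "other_conifer",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic dataset.

    Defaults describe the small desk-scale configuration: a 10x10 grid of
    24-km cells, 5 taxa, 8 centennial bins, 30 pollen sites with ~300
    grains per sample, local fraction gamma = 0.85 for every taxon, spread
    pollen productivities, a 100-km spatial range, and 60-yr age errors.
    """

    extent: tuple[float, float] = (240.0, 240.0)
    cell_size: float = 24.0
    K: int = 5
    T: int = 8
    eta: float = 1.0
    rho: float = 100.0
    omega: float = 0.8
    xi: float = 0.1
    mu_scale: float = 1.0
    gamma: tuple[float, ...] | float = 0.85
    phi: tuple[float, ...] = (15.0, 10.0, 7.0, 5.0, 3.0)
    kernel: KernelParams = field(default_factory=lambda: KernelParams("inverse_power_law", a=40.0, b=4.0))
    n_sites: int = 30
    mean_grains: float = 300.0
    n_calibration_sites: int = 200   # denser settlement-era network
    calibration_grains: float = 500.0
    site_density_gradient: float = 0.0   # 0 = uniform; >0 biases sites west
    age_sd: float = 60.0
    age_ar: float = 0.7
    sample_spacing_yr: float = 80.0
    knot_every: int = 2
    youngest: float = 150.0
    seed: int = 0

    @property
    def oldest(self) -> float:
        """Oldest bin edge: T centennial bins ending at ``youngest`` YB1950
        (the full published span 2,150-150 corresponds to T = 20)."""
        return self.youngest + 100.0 * self.T

    @property
    def taxa(self) -> tuple[str, ...]:
        return _CANONICAL_TAXA[: self.K]

    @property
    def gamma_vec(self) -> np.ndarray:
        g = self.gamma
        return np.full(self.K, g) if np.isscalar(g) else np.asarray(g, dtype=float)

    @property
    def phi_vec(self) -> np.ndarray:
        return np.asarray(self.phi[: self.K], dtype=float)

    @property
    def bin_edges(self) -> np.ndarray:
        """Descending YB1950 bin edges, oldest bin first, 100-yr width."""
        return np.arange(self.oldest, self.youngest - 1, -100.0)

    def hyperparams(self) -> SpatialHyperparams:
        return SpatialHyperparams(
            eta=np.full(self.K, self.eta), rho=np.full(self.K, self.rho),
            omega=self.omega, xi=self.xi, mu_scale=self.mu_scale,
        )

    def build_grid(self) -> Grid:
        return build_grid(self.extent, self.cell_size)


PRESETS: dict[str, SimulationConfig] = {
    "tiny": SimulationConfig(
        extent=(96.0, 96.0), K=3, T=4, n_sites=8, mean_grains=150.0,
        n_calibration_sites=40, calibration_grains=300.0,
        phi=(12.0, 8.0, 4.0), rho=80.0,
    ),
    "small": SimulationConfig(),
    "medium": SimulationConfig(
        extent=(480.0, 480.0), K=8, T=20, n_sites=60,
        phi=(15.0, 10.0, 8.0, 7.0, 5.0, 4.0, 3.0, 2.0),
    ),
}


@dataclass
class SyntheticTruth:
    """Simulation truth retained for recovery tests."""

    config: SimulationConfig
    grid: Grid
    knots: KnotSet
    r: np.ndarray             # (N, T, K) true composition
    r_mean: np.ndarray        # (N, T, K) composition of the smooth process mean
    state: LatentState
    weights: WeightMatrix

    @property
    def settlement_composition(self) -> np.ndarray:
        """Composition at the youngest (settlement-era) bin."""
        return self.r[:, -1, :]


def _weight_matrix(grid: Grid, kernel: KernelParams) -> WeightMatrix:
    d = pairwise_distance(grid.cell_centers, grid.cell_centers)
    W = kernel_density(d, kernel) * grid.cell_area
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W=W, C=W.sum(axis=1), params=kernel)


def simulate_composition(config: SimulationConfig, rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw composition fields from the generative prior of the model."""
    rng = rng or np.random.default_rng(config.seed)
    grid = config.build_grid()
    knots = KnotSet.from_grid(grid, config.knot_every)
    h = config.hyperparams()
    N, M, T, K = grid.n_cells, knots.n_knots, config.T, config.K
    sw = np.sqrt(1.0 - h.omega**2)

    mu = h.mu_scale * rng.standard_normal(K)
    mu_t = np.zeros((T, K))
    alpha_s = np.zeros((M, K))
    alpha_t = np.zeros((T, M, K))
    g = np.zeros((N, T, K))
    mu_g = np.zeros((N, T, K))
    for k in range(K):
        C_star, c = knots.covariances(h.eta[k], h.rho[k])
        L = _chol_with_jitter(C_star, "knot covariance")
        P = np.linalg.solve(L.T, np.linalg.solve(L, c.T)).T
        alpha_s[:, k] = L @ rng.standard_normal(M)
        nu_s = P @ alpha_s[:, k]
        s1 = np.sqrt(process_variance(knots, h.eta[k], h.rho[k], h.omega, h.tau2, True))
        s2 = np.sqrt(process_variance(knots, h.eta[k], h.rho[k], h.omega, h.tau2, False))
        for t in range(1, T):
            mu_t[t, k] = (mu_t[t - 1, k] if t > 1 else 0.0) + h.xi * rng.standard_normal()
            e = L @ rng.standard_normal(M)
            alpha_t[t, :, k] = e if t == 1 else h.omega * alpha_t[t - 1, :, k] + sw * e
        nu_st = P @ alpha_t[:, :, k].T
        mu_g[:, :, k] = mu[k] + nu_s[:, None] + mu_t[None, :, k] + nu_st
        sigma = np.column_stack([s1] + [s2] * (T - 1))
        g[:, :, k] = mu_g[:, :, k] + sigma * rng.standard_normal((N, T))
    state = LatentState(mu=mu, mu_t=mu_t, alpha_s=alpha_s, alpha_t=alpha_t, g=g)
    return SyntheticTruth(
        config=config, grid=grid, knots=knots,
        r=alr_inverse(g, axis=2), r_mean=alr_inverse(mu_g, axis=2),
        state=state, weights=_weight_matrix(grid, config.kernel),
    )


def place_sites(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Site coordinates: uniform over the domain, optionally density-biased
    along x to emulate uneven record density."""
    w, hgt = config.extent
    xs = rng.uniform(0, w, size=4 * config.n_sites)
    if config.site_density_gradient > 0:
        keep = rng.uniform(size=xs.size) < np.exp(-config.site_density_gradient * xs / w)
        xs = xs[keep]
    xs = xs[: config.n_sites]
    while len(xs) < config.n_sites:   # top up if the thinning was aggressive
        xs = np.append(xs, rng.uniform(0, w))
    ys = rng.uniform(0, hgt, size=config.n_sites)
    return np.column_stack([xs, ys])


def simulate_pollen(
    r: np.ndarray,
    site_cells: np.ndarray,
    config: SimulationConfig,
    weights: WeightMatrix,
    rng: np.random.Generator,
    n_grains: np.ndarray | None = None,
) -> np.ndarray:
    """Dirichlet-multinomial pollen counts at sites for one composition slice.

    ``r`` is (n_cells, K) for a single time; returns (n_sites, K) counts.
    """
    conc = phi_mixing(r, config.gamma_vec, config.phi_vec, weights, site_cells)
    conc = np.atleast_2d(conc)
    S = len(site_cells)
    if n_grains is None:
        n_grains = rng.poisson(config.mean_grains, size=S)
    counts = np.zeros((S, config.K), dtype=np.int64)
    for i in range(S):
        p = rng.dirichlet(conc[i])
        counts[i] = rng.multinomial(n_grains[i], p)
    return counts


@dataclass
class SyntheticRecords:
    """Fossil pollen records plus the calibration pair and hidden truth."""

    truth: SyntheticTruth
    site_coords: np.ndarray          # (S, 2)
    site_cells: np.ndarray           # (S,)
    sample_site: np.ndarray          # (n_samples,) site index per sample
    sample_ids: np.ndarray           # (n_samples,) unique ids
    depths: np.ndarray               # (n_samples,) cm, increasing with age per site
    true_ages: np.ndarray            # (n_samples,) YB1950
    counts: np.ndarray               # (n_samples, K)
    calibration_coords: np.ndarray   # (S_cal, 2) settlement-era network
    calibration_cells: np.ndarray    # (S_cal,)
    calibration_counts: np.ndarray   # (S_cal, K) settlement-era pollen

    @property
    def site_ids(self) -> np.ndarray:
        return np.array([f"site_{i:03d}" for i in range(len(self.site_coords))])

    @property
    def calibration_site_ids(self) -> np.ndarray:
        return np.array([f"cal_{i:03d}" for i in range(len(self.calibration_coords))])


def simulate_records(
    truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> SyntheticRecords:
    """Simulate depth-ordered fossil records and the settlement calibration pair."""
    cfg = truth.config
    rng = rng or np.random.default_rng(cfg.seed + 1)
    coords = place_sites(cfg, rng)
    cells = truth.grid.cell_of(coords)
    edges = cfg.bin_edges
    sample_site, depths, ages = [], [], []
    for i in range(cfg.n_sites):
        # true deposition ages: roughly regular, jittered, youngest first
        n_samp = int((cfg.oldest - cfg.youngest) / cfg.sample_spacing_yr)
        a = cfg.youngest + cfg.sample_spacing_yr * (np.arange(n_samp) + rng.uniform(0.2, 0.8, n_samp))
        a = np.sort(a[a < cfg.oldest])
        sample_site.extend([i] * len(a))
        depths.extend(10.0 + 2.5 * np.arange(len(a)))  # cm, monotone in age
        ages.extend(a)
    sample_site = np.asarray(sample_site)
    depths = np.asarray(depths)
    ages = np.asarray(ages)
    # assign each sample's true bin; digitize against descending edges
    tbin = np.clip(len(edges) - 2 - np.searchsorted(edges[::-1], ages, side="right") + 1,
                   0, cfg.T - 1)
    counts = np.zeros((len(ages), cfg.K), dtype=np.int64)
    for t in range(cfg.T):
        mask = tbin == t
        if not mask.any():
            continue
        counts[mask] = simulate_pollen(
            truth.r[:, t, :], cells[sample_site[mask]], cfg, truth.weights, rng
        )
    # settlement-era calibration pair on its own (denser) site network
    cal_coords = np.column_stack([
        rng.uniform(0, cfg.extent[0], cfg.n_calibration_sites),
        rng.uniform(0, cfg.extent[1], cfg.n_calibration_sites),
    ])
    cal_cells = truth.grid.cell_of(cal_coords)
    cal_grains = rng.poisson(cfg.calibration_grains, size=cfg.n_calibration_sites)
    calib_counts = simulate_pollen(truth.settlement_composition, cal_cells, cfg,
                                   truth.weights, rng, n_grains=cal_grains)
    sample_ids = np.array([f"s{j:05d}" for j in range(len(ages))])
    return SyntheticRecords(
        truth=truth, site_coords=coords, site_cells=cells,
        sample_site=sample_site, sample_ids=sample_ids, depths=depths,
        true_ages=ages, counts=counts, calibration_coords=cal_coords,
        calibration_cells=cal_cells, calibration_counts=calib_counts,
    )


def simulate_age_draws(
    records: SyntheticRecords,
    n_draws: int = 4,
    rng: np.random.Generator | None = None,
    sd: float | None = None,
    ar: float | None = None,
) -> pd.DataFrame:
    """Monotone age-model posterior draws for every sample.

    Each draw adds AR(1)-correlated noise (marginal sd = ``sd``) down-core
    and restores strict within-site age ordering by an isotonic (pool
    adjacent violators) projection, emulating joint age-depth posterior
    draws with decadal-to-centennial uncertainty.
    """
    cfg = records.truth.config
    rng = rng or np.random.default_rng(cfg.seed + 2)
    sd = cfg.age_sd if sd is None else sd
    ar = cfg.age_ar if ar is None else ar
    rows = []
    site_ids = records.site_ids
    for d in range(n_draws):
        for i in range(len(records.site_coords)):
            mask = records.sample_site == i
            true = records.true_ages[mask]
            if np.any(np.diff(true) <= 0):
                raise ValueError("true ages must strictly increase with depth")
            m = mask.sum()
            noise = np.empty(m)
            noise[0] = rng.standard_normal()
            for j in range(1, m):
                noise[j] = ar * noise[j - 1] + np.sqrt(1 - ar**2) * rng.standard_normal()
            perturbed = true + sd * noise
            mono = _isotonic(perturbed)
            mono += 1e-6 * np.arange(m)  # strictness after pooling
            for sid, age in zip(records.sample_ids[mask], mono):
                rows.append((site_ids[i], sid, d, age))
    return pd.DataFrame(rows, columns=["site_id", "sample_id", "draw_id", "age_yb1950"])


def _isotonic(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto nondecreasing sequences."""
    y = np.asarray(y, dtype=float)
    vals, wts, idxs = [], [], []
    for i in range(len(y)):
        vals.append(y[i]); wts.append(1.0); idxs.append([i])
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            w = wts[-2] + wts[-1]
            ix = idxs[-2] + idxs[-1]
            vals = vals[:-2] + [v]; wts = wts[:-2] + [w]; idxs = idxs[:-2] + [ix]
    out = np.empty_like(y)
    for v, ix in zip(vals, idxs):
        out[ix] = v
    return out


def bin_records(
    records: SyntheticRecords, ages: pd.DataFrame, draw_id: int
) -> BinnedPollen:
    """Bin a synthetic record set under one age-draw set (convenience for
    tests; the general reader-based path lives in :mod:`stepps.io`)."""
    from .io import bin_and_filter, records_to_frames

    pollen, sites = records_to_frames(records)
    sub = ages[ages.draw_id == draw_id]
    return bin_and_filter(
        pollen, sites, sub, records.truth.config.bin_edges,
        records.truth.grid, records.truth.config.taxa,
    )


def make_fixture(
    preset: str | SimulationConfig,
    outdir: str | Path,
    seed: int = 0,
    n_age_draw_sets: int = 4,
) -> Path:
    """Write a complete on-disk input set (CSV/NetCDF) plus truth sidecar."""
    from . import io as sio

    cfg = PRESETS[preset] if isinstance(preset, str) else preset
    cfg = replace(cfg, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth = simulate_composition(cfg, rng)
    records = simulate_records(truth, rng)
    ages = simulate_age_draws(records, n_draws=n_age_draw_sets, rng=rng)

    truth.grid.to_frame().to_csv(outdir / "grid.csv", index=False)
    sio.write_composition_csv(truth.settlement_composition, cfg.taxa,
                              outdir / "settlement_composition.csv")
    pollen, sites = sio.records_to_frames(records)
    sites.to_csv(outdir / "sites.csv", index=False)
    pollen.to_csv(outdir / "fossil_pollen.csv", index=False)
    calib = sio.calibration_to_frame(records)
    calib.to_csv(outdir / "calibration_pollen.csv", index=False)
    ages.to_csv(outdir / "age_draws.csv", index=False)
    sio.write_truth(truth, outdir / "truth.nc", seed=seed)
    sio.write_sim_config(cfg, outdir / "config.yaml", n_age_draw_sets=n_age_draw_sets)
    return outdir
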