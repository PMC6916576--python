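"""Readers, writers, and pollen preprocessing.

File dialects: long-format CSV for pollen (site_id, sample_id, depth,
taxon, count) with a per-site coordinate table; wide CSV or NetCDF for
composition surfaces; per-site long CSV for age-model draws (site_id,
sample_id, draw_id, age_yb1950); NetCDF (dimensions draw, cell, time_bin,
taxon) for posterior ensembles, with the config hash and seed embedded as
attributes; YAML for configuration; JSON for summaries.

Binning follows the half-open convention [lower, upper) in YB1950 with
100-yr bins ordered oldest first; samples younger than the settlement
cutoff (150 YB1950, or a per-site settlement-horizon age if provided) are
excluded as postsettlement, and samples older than the oldest edge are
dropped with a logged count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grids import Grid, KernelParams
from .prediction import BinnedPollen, PosteriorEnsemble

__all__ = [
    "PipelineConfig",
    "read_pollen_long",
    "bin_and_filter",
    "read_composition_csv",
    "write_composition_csv",
    "read_grid_csv",
    "write_ensemble",
    "read_ensemble",
]

logger = logging.getLogger(__name__)

_NC_ENGINE = "scipy"


# --------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------- #
@dataclass
class PipelineConfig:
    """End-to-end run configuration with the published defaults.

    Sampler settings default to desk scale; ``paper_scale()`` returns the
    published configuration (warmup 250, 2,000 sampling iterations, every
    40th sample retained, 40 age-draw sets).
    """

    taxa: tuple[str, ...] = ()
    cell_size: float = 24.0
    extent: tuple[float, float] = (240.0, 240.0)
    bin_oldest: float = 2150.0
    bin_youngest: float = 150.0
    bin_width: float = 100.0
    knot_every: int = 2
    warmup: int = 300
    samples: int = 600
    thin: int = 2
    n_leapfrog: int = 24
    n_age_draw_sets: int = 4
    calibration_steps: int = 1500
    omega: float = 0.8
    xi: float = 0.1
    exclude_bins_yb1950: tuple[float, ...] = ()
    prob_cut: float = 0.85
    eco_cut: float = 0.03
    large_cut: float = 0.05
    stability_cut: float = 0.03
    seed: int = 0

    @classmethod
    def paper_scale(cls, **overrides) -> "PipelineConfig":
        base = dict(warmup=250, samples=2000, thin=40, n_age_draw_sets=40,
                    exclude_bins_yb1950=(200.0,))
        base.update(overrides)
        return cls(**base)

    @property
    def bin_edges(self) -> np.ndarray:
        """Descending YB1950 edges, oldest first."""
        return np.arange(self.bin_oldest, self.bin_youngest - 1, -self.bin_width)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("taxa", "extent", "exclude_bins_yb1950"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("taxa", "extent", "exclude_bins_yb1950"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# --------------------------------------------------------------------- #
# pollen records
# --------------------------------------------------------------------- #
def read_pollen_long(
    pollen_path: str | Path,
    sites_path: str | Path,
    taxa: tuple[str, ...],
    taxon_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate long-format pollen plus the site coordinate table.

    Unknown taxa are renamed through ``taxon_map`` (e.g. onto the
    other_hardwood / other_conifer aggregates) or rejected.  Returns the
    validated (pollen, sites) frames; counts for taxa absent from a sample
    are implicitly zero.
    """
    pollen = pd.read_csv(pollen_path)
    sites = pd.read_csv(sites_path)
    need = {"site_id", "sample_id", "taxon", "count"}
    if missing := need - set(pollen.columns):
        raise ValueError(f"pollen file missing columns: {sorted(missing)}")
    need_sites = {"site_id", "x_km", "y_km"}
    if missing := need_sites - set(sites.columns):
        raise ValueError(f"sites file missing columns: {sorted(missing)}")
    if taxon_map:
        pollen = pollen.assign(taxon=pollen.taxon.replace(taxon_map))
    unknown = set(pollen.taxon) - set(taxa)
    if unknown:
        raise ValueError(f"unknown taxa (no mapping provided): {sorted(unknown)}")
    neg = pollen.index[pollen["count"] < 0]
    if len(neg):
        raise ValueError(f"negative counts at rows {list(neg[:10])}")
    dup = pollen.duplicated(subset=["sample_id", "taxon"])
    if dup.any():
        raise ValueError(f"duplicate (sample, taxon) rows at {list(pollen.index[dup][:10])}")
    orphan = set(pollen.site_id) - set(sites.site_id)
    if orphan:
        raise ValueError(f"pollen refers to sites without coordinates: {sorted(orphan)}")
    return pollen, sites


def bin_and_filter(
    pollen: pd.DataFrame,
    sites: pd.DataFrame,
    ages: pd.DataFrame,
    bin_edges: np.ndarray,
    grid: Grid,
    taxa: tuple[str, ...],
    settlement_horizon: dict[str, float] | None = None,
) -> BinnedPollen:
    """Assign samples to 100-yr bins under one age-draw set and aggregate.

    Postsettlement samples (younger than 150 YB1950 or than the per-site
    settlement horizon) are dropped; samples older than the oldest edge are
    dropped with a logged count; multiple samples of one site falling in
    one bin are summed.
    """
    edges = np.asarray(bin_edges, dtype=float)
    T, K = len(edges) - 1, len(taxa)
    youngest, oldest = edges[-1], edges[0]
    age_of = dict(zip(ages.sample_id, ages.age_yb1950))
    missing = set(pollen.sample_id) - set(age_of)
    if missing:
        raise ValueError(f"samples without ages in this draw set: {sorted(missing)[:10]}")

    site_ids = np.asarray(sites.site_id)
    site_index = {s: i for i, s in enumerate(site_ids)}
    coords = sites[["x_km", "y_km"]].to_numpy(dtype=float)
    cells = grid.cell_of(coords)
    tx_index = {t: k for k, t in enumerate(taxa)}

    counts = np.zeros((len(site_ids), T, K), dtype=np.int64)
    n_too_old = 0
    asc = edges[::-1]
    for (sid, samp), sub in pollen.groupby(["site_id", "sample_id"], sort=True):
        age = age_of[samp]
        cutoff = max(youngest, (settlement_horizon or {}).get(sid, youngest))
        if age < cutoff:
            continue  # postsettlement
        if age >= oldest:
            n_too_old += 1
            continue
        t = T - int(np.searchsorted(asc, age, side="right"))
        i = site_index[sid]
        for _, row in sub.iterrows():
            counts[i, t, tx_index[row.taxon]] += int(row["count"])
    if n_too_old:
        logger.info("dropped %d samples older than %.0f YB1950", n_too_old, oldest)
    return BinnedPollen(site_ids=site_ids, site_cells=cells, counts=counts,
                        bin_edges=edges, taxa=tuple(taxa))


# --------------------------------------------------------------------- #
# composition and grid
# --------------------------------------------------------------------- #
def write_composition_csv(r: np.ndarray, taxa: tuple[str, ...], path: str | Path) -> None:
    """Wide CSV, one row per cell, one column per taxon."""
    df = pd.DataFrame(np.asarray(r), columns=list(taxa))
    df.insert(0, "cell_id", np.arange(len(df)))
    df.to_csv(path, index=False, float_format="%.10g")


def read_composition_csv(path: str | Path, taxa: tuple[str, ...] | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path).sort_values("cell_id")
    cols = list(taxa) if taxa else [c for c in df.columns if c != "cell_id"]
    r = df[cols].to_numpy(dtype=float)
    if not np.allclose(r.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("composition rows must sum to 1")
    return r, tuple(cols)


def read_grid_csv(path: str | Path, cell_size: float) -> Grid:
    df = pd.read_csv(path).sort_values("cell_id")
    return Grid(cell_centers=df[["x_km", "y_km"]].to_numpy(dtype=float), cell_size=cell_size)


# --------------------------------------------------------------------- #
# posterior ensembles (NetCDF)
# --------------------------------------------------------------------- #
def ensemble_to_dataset(ens: PosteriorEnsemble, seed: int | None = None,
                        config_hash: str | None = None) -> xr.Dataset:
    ds = xr.Dataset(
        {
            "r": (("draw", "cell", "time_bin", "taxon"), ens.r),
            "r_mean": (("draw", "cell", "time_bin", "taxon"), ens.r_mean),
        },
        coords={
            "draw": np.arange(ens.n_draws),
            "cell": np.arange(ens.r.shape[1]),
            "time_bin": ens.bin_mid,
            "taxon": list(ens.taxa),
        },
        attrs={
            "bin_edges_yb1950": list(map(float, ens.bin_edges)),
            "provenance": json.dumps(ens.provenance, default=str),
        },
    )
    if seed is not None:
        ds.attrs["seed"] = int(seed)
    if config_hash is not None:
        ds.attrs["config_hash"] = config_hash
    return ds


def write_ensemble(ens: PosteriorEnsemble, path: str | Path,
                   seed: int | None = None, config_hash: str | None = None) -> None:
    ds = ensemble_to_dataset(ens, seed=seed, config_hash=config_hash)
    ds.to_netcdf(path, engine=_NC_ENGINE)


def read_ensemble(path: str | Path, expect_config_hash: str | None = None) -> PosteriorEnsemble:
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        ds = ds.load()
    if expect_config_hash is not None:
        found = ds.attrs.get("config_hash")
        if found != expect_config_hash:
            logger.warning("config hash mismatch: ensemble %s vs expected %s", found, expect_config_hash)
    for dim in ("draw", "cell", "time_bin", "taxon"):
        if dim not in ds.dims:
            raise ValueError(f"ensemble file missing dimension {dim!r}")
    return PosteriorEnsemble(
        r=ds["r"].values,
        r_mean=ds["r_mean"].values,
        bin_edges=np.asarray(ds.attrs["bin_edges_yb1950"], dtype=float),
        taxa=tuple(str(t) for t in ds["taxon"].values),
        provenance=json.loads(ds.attrs.get("provenance", "[]")),
    )


# --------------------------------------------------------------------- #
# synthetic-fixture serialization
# --------------------------------------------------------------------- #
def records_to_frames(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(pollen long frame, sites frame) from a SyntheticRecords object."""
    cfg = records.truth.config
    site_ids = records.site_ids
    rows = []
    for j in range(len(records.sample_ids)):
        for k, tx in enumerate(cfg.taxa):
            rows.append((site_ids[records.sample_site[j]], records.sample_ids[j],
                         records.depths[j], tx, int(records.counts[j, k])))
    pollen = pd.DataFrame(rows, columns=["site_id", "sample_id", "depth", "taxon", "count"])
    sites = pd.DataFrame({
        "site_id": site_ids,
        "x_km": records.site_coords[:, 0],
        "y_km": records.site_coords[:, 1],
    })
    return pollen, sites


def calibration_to_frame(records) -> pd.DataFrame:
    cfg = records.truth.config
    rows = []
    for i, sid in enumerate(records.calibration_site_ids):
        for k, tx in enumerate(cfg.taxa):
            rows.append((sid, records.calibration_coords[i, 0],
                         records.calibration_coords[i, 1],
                         tx, int(records.calibration_counts[i, k])))
    return pd.DataFrame(rows, columns=["site_id", "x_km", "y_km", "taxon", "count"])


def write_truth(truth, path: str | Path, seed: int) -> None:
    cfg = truth.config
    ds = xr.Dataset(
        {
            "r": (("cell", "time_bin", "taxon"), truth.r),
            "r_mean": (("cell", "time_bin", "taxon"), truth.r_mean),
        },
        coords={
            "cell": np.arange(truth.grid.n_cells),
            "time_bin": (cfg.bin_edges[:-1] + cfg.bin_edges[1:]) / 2.0,
            "taxon": list(cfg.taxa),
        },
        attrs={
            "seed": int(seed),
            "gamma": list(map(float, cfg.gamma_vec)),
            "phi": list(map(float, cfg.phi_vec)),
            "eta": cfg.eta, "rho": cfg.rho, "omega": cfg.omega, "xi": cfg.xi,
            "kernel_family": cfg.kernel.family,
            "kernel_a": cfg.kernel.a, "kernel_b": cfg.kernel.b,
        },
    )
    ds.to_netcdf(path, engine=_NC_ENGINE)


def read_truth(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        return ds.load()


def write_sim_config(cfg, path: str | Path, n_age_draw_sets: int) -> None:
    d = asdict(cfg)
    d["kernel"] = {"family": cfg.kernel.family, "a": cfg.kernel.a, "b": cfg.kernel.b}
    d["n_age_draw_sets"] = n_age_draw_sets
    d["extent"] = list(cfg.extent)
    d["gamma"] = list(map(float, cfg.gamma_vec))
    d["phi"] = list(map(float, cfg.phi_vec))
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_sim_config(path: str | Path):
    from .synthetic import SimulationConfig

    with open(path) as fh:
        d = yaml.safe_load(fh)
    n_sets = d.pop("n_age_draw_sets", 4)
    kern = d.pop("kernel")
    cfg = SimulationConfig(
        kernel=KernelParams(kern["family"], a=kern["a"], b=kern["b"]),
        **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d.items()
            if k in SimulationConfig.__dataclass_fields__ and k != "kernel"
        },
    )
    return cfg, n_sets
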