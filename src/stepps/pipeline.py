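"""End-to-end drivers: calibration, age-draw ensembles, and analyses.

Ties the stages together the way the published workflow runs them: fit the
calibration posterior on the settlement-era pair; estimate (eta, rho) a
priori from the settlement composition; for each selected age-draw set,
bin the fossil pollen under those ages, pair the run with a fresh
calibration-posterior draw, fit the prediction model, and pool the
per-run posteriors into one ensemble; then classify change and trace the
ecotone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .calibration import CalibrationModel, CalibrationResults
from .change import ChangeThresholds, classify_all_pairs
from .ecotone import default_transects, extract_zero_line, pc1_score_fields, transect_displacement
from .grids import Grid
from .prediction import PosteriorEnsemble, PredictionModel
from .spatial import KnotSet, SpatialHyperparams, fit_spatial_hyperparams

logger = logging.getLogger(__name__)

__all__ = ["run_age_ensemble", "run_pipeline"]


def run_age_ensemble(
    pollen: pd.DataFrame,
    sites: pd.DataFrame,
    ages: pd.DataFrame,
    calib: CalibrationResults,
    grid: Grid,
    knots: KnotSet,
    hyper: SpatialHyperparams,
    bin_edges: np.ndarray,
    taxa: tuple[str, ...],
    n_sets: int = 4,
    warmup: int = 300,
    samples: int = 600,
    thin: int = 2,
    n_leapfrog: int = 24,
    seed: int = 0,
    settlement_horizon: dict[str, float] | None = None,
) -> PosteriorEnsemble:
    """Pool prediction posteriors across randomly selected age-draw sets.

    Each member run bins the records under one joint age draw and pairs
    them with one calibration-posterior draw, so both dating and
    calibration uncertainty propagate into the pooled ensemble.  Failed
    member runs are reported and pooling proceeds over the successes.
    """
    rng = np.random.default_rng(seed)
    available = np.sort(ages.draw_id.unique())
    chosen = (rng.choice(available, size=n_sets, replace=False)
              if n_sets < len(available) else available)
    members, failures = [], []
    for run_i, d in enumerate(np.sort(chosen)):
        binned = sio.bin_and_filter(
            pollen, sites, ages[ages.draw_id == d], bin_edges, grid, taxa,
            settlement_horizon=settlement_horizon,
        )
        calib_draw = calib.draw(rng=rng)
        model = PredictionModel(binned, grid, knots, calib_draw, hyper)
        try:
            res = model.fit(warmup=warmup, samples=samples, thin=thin,
                            n_leapfrog=n_leapfrog,
                            seed=int(rng.integers(2**31 - 1)))
        except Exception as err:  # surfaced, pooling continues over successes
            logger.warning("prediction run %d (age-draw set %s) failed: %s", run_i, d, err)
            failures.append((run_i, int(d), str(err)))
            continue
        members.append(res.to_ensemble({"age_draw_set": int(d), "run": run_i}))
    if failures:
        logger.warning("%d of %d prediction runs failed", len(failures), len(chosen))
    if not members:
        raise RuntimeError(f"all prediction runs failed: {failures}")
    return PosteriorEnsemble.pool(members)


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    config: sio.PipelineConfig | None = None,
    seed: int = 0,
) -> dict:
    """Run calibrate -> predict -> change -> ecotone on an on-disk fixture.

    Reads the CSV inputs written by :func:`stepps.synthetic.make_fixture`
    (or equivalently formatted real data), writes the ensemble NetCDF,
    classification tables and ecotone products under ``out_dir``, and
    returns a dict of headline summaries.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg, n_sets_avail = sio.read_sim_config(data_dir / "config.yaml")
    cfg = config or sio.PipelineConfig(
        taxa=sim_cfg.taxa, cell_size=sim_cfg.cell_size, extent=sim_cfg.extent,
        bin_oldest=sim_cfg.oldest, bin_youngest=sim_cfg.youngest,
        knot_every=sim_cfg.knot_every, omega=sim_cfg.omega, xi=sim_cfg.xi,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    grid = sio.read_grid_csv(data_dir / "grid.csv", cfg.cell_size)
    comp, taxa = sio.read_composition_csv(data_dir / "settlement_composition.csv", cfg.taxa or None)
    calib_df = pd.read_csv(data_dir / "calibration_pollen.csv")
    csites = calib_df[["site_id", "x_km", "y_km"]].drop_duplicates().sort_values("site_id")
    wide = calib_df.pivot_table(index="site_id", columns="taxon", values="count",
                                fill_value=0).reindex(csites.site_id)[list(taxa)]
    pollen, sites = sio.read_pollen_long(data_dir / "fossil_pollen.csv",
                                         data_dir / "sites.csv", taxa)
    ages = pd.read_csv(data_dir / "age_draws.csv")

    # --- calibration stage ---
    cal_model = CalibrationModel(
        composition=comp, counts=wide.to_numpy(), taxa=taxa,
        site_coords=csites[["x_km", "y_km"]].to_numpy(dtype=float), grid=grid,
        kernel_family=sim_cfg.kernel.family,
    )
    calib = cal_model.fit(n_steps=cfg.calibration_steps,
                          seed=int(rng.integers(2**31 - 1)))
    calib.summary().to_csv(out_dir / "calibration_summary.csv")

    # --- spatial hyperparameters a priori from settlement composition ---
    knots = KnotSet.from_grid(grid, cfg.knot_every)
    eta, rho = fit_spatial_hyperparams(comp, grid, knots,
                                       seed=int(rng.integers(2**31 - 1)))
    hyper = SpatialHyperparams(eta=eta, rho=rho, omega=cfg.omega, xi=cfg.xi)

    # --- prediction over the age-draw ensemble ---
    ensemble = run_age_ensemble(
        pollen, sites, ages, calib, grid, knots, hyper, cfg.bin_edges, taxa,
        n_sets=min(cfg.n_age_draw_sets, n_sets_avail),
        warmup=cfg.warmup, samples=cfg.samples, thin=cfg.thin,
        n_leapfrog=cfg.n_leapfrog, seed=int(rng.integers(2**31 - 1)),
    )
    sio.write_ensemble(ensemble, out_dir / "ensemble.nc", seed=seed,
                       config_hash=cfg.hash())

    # --- change classification ---
    thresholds = ChangeThresholds(cfg.prob_cut, cfg.eco_cut, cfg.large_cut,
                                  cfg.stability_cut)
    keep = [t for t, mid in enumerate(ensemble.bin_mid)
            if mid not in cfg.exclude_bins_yb1950]
    pairs = [(a, b) for i, a in enumerate(keep) for b in keep[i + 1:]]
    classification = classify_all_pairs(ensemble, thresholds, pairs=pairs)
    classification.to_frame().to_csv(out_dir / "change_classification.csv", index=False)
    summary = classification.summary()
    summary.to_csv(out_dir / "change_summary.csv", index=False)
    with open(out_dir / "change_summary.json", "w") as fh:
        json.dump(
            {"config_hash": cfg.hash(), "seed": seed,
             "pairs": summary.to_dict(orient="records")},
            fh, indent=2, sort_keys=True,
        )

    # --- ecotone ---
    r_mean = ensemble.r_mean.mean(axis=0)
    eco_out: dict = {"lines": {}, "displacements": None}
    try:
        scores, _eof = pc1_score_fields(r_mean, grid)
        lines = {}
        for t in keep:
            try:
                lines[t] = extract_zero_line(scores[:, t], grid, time_bin=t)
            except ValueError:
                logger.warning("no ecotone in domain at bin %d", t)
        if lines:
            ref = max(lines)  # youngest analyzed bin as the reference time
            transects = default_transects(lines[ref], length=2 * max(cfg.extent))
            disp = transect_displacement(lines, transects, ref)
            disp.to_csv(out_dir / "ecotone_displacements.csv", index=False)
            with open(out_dir / "ecotone_lines.json", "w") as fh:
                json.dump(
                    {str(t): {"time_yb1950": float(ensemble.bin_mid[t]),
                              "coordinates_km": np.round(ln.vertices, 6).tolist()}
                     for t, ln in sorted(lines.items())},
                    fh, indent=2, sort_keys=True,
                )
            eco_out = {"lines": {t: ln.vertices for t, ln in lines.items()},
                       "displacements": disp}
    except ValueError as err:
        logger.warning("ecotone analysis skipped: %s", err)

    return {
        "calibration": calib,
        "ensemble": ensemble,
        "classification": classification,
        "change_summary": summary,
        "ecotone": eco_out,
        "hyper": hyper,
        "config": cfg,
    }
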