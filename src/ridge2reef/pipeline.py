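"""End-to-end orchestration: synthetic site → priority flow tubes.

Stage order: recharge → groundwater flow → nutrient loading → flow tubes →
coastal plumes → marine drivers → reef model calibration → prediction maps →
ordination → vulnerability overlay.  Every stage consumes the previous
stage's in-memory products; artifacts are written once at the end together
with a manifest of content hashes, the seed, and the package version, so a
re-run with an identical configuration is bit-identical.

All randomness flows from the single root seed through named substreams
(site, surveys, model fitting, permutation tests).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid import BENTHIC_COLS, FISH_COLS, RasterGrid, write_ascii_grid, write_surveys
from .groundwater import RechargeInputs, compute_recharge, darcy_flow, domain_water_budget, solve_steady_head
from .nutrients import RESIDENCE_WASTEWATER_M3_YR, background_flux, rasterize_sources
from .flowtubes import boundary_seed_points, delineate_flow_tubes, place_pour_points, trace_flowpaths, zone_budget
from .plume import cost_surface, stack_plumes
from .terrain import build_marine_stack, distance_to_shore
from .brt import (
    BRTConfig, fit_brt, morans_i, obs_vs_pred, predict_map, sample_at_points,
    transform_response,
)
from .ordination import dbrda
from .prioritize import classify_vulnerable, derive_thresholds, match_priority_tubes
from .synth import SiteBundle, generate_site, generate_surveys

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "LandSeaStage", "run_land_sea", "run_pipeline"]


@dataclass
class PipelineConfig:
    preset: str = "wet"
    size: int = 40
    seed: int = 0
    outdir: str | Path | None = None
    tube_spacing: float = 200.0
    n_surveys: int = 200
    survey_noise_fraction: float = 0.25
    plume_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    mass_conserving_plumes: bool = False
    brt: BRTConfig = field(default_factory=BRTConfig)

    def __post_init__(self) -> None:
        if self.size <= 0 or self.tube_spacing <= 0:
            raise ValueError("size and tube_spacing must be positive")


@dataclass
class PipelineResult:
    config: PipelineConfig
    site: SiteBundle
    recharge: RasterGrid
    budget: object
    tubes: list
    driver_stack: dict[str, RasterGrid]
    per_tube_plumes: dict[str, np.ndarray]
    d_c: float
    surveys: pd.DataFrame
    truth: object
    models: dict[str, object]
    predictions: dict[str, RasterGrid]
    metrics: pd.DataFrame
    ordination: object
    vulnerability: object
    ranking: list[dict]
    human_derived_fraction: dict[str, float]
    manifest: dict


def _osds_effluent_raster(site: SiteBundle) -> RasterGrid:
    """Per-cell OSDS leaching effluent expressed as a recharge depth (m·yr⁻¹)."""
    g = site.rainfall
    vals = np.zeros(g.shape)
    for f in site.sources:
        if f.attributes.get("class") in ("cesspool", "septic"):
            i, j = g.index_of(f.geometry.x, f.geometry.y)
            vals[i, j] += RESIDENCE_WASTEWATER_M3_YR / g.cell_area
    vals[~site.land_mask] = np.nan
    return g.like(vals, units="m.yr-1")


@dataclass
class LandSeaStage:
    """Products of the land and land-sea-link stages for one site."""

    recharge: RasterGrid
    n_clipped: int
    budget: object
    tubes: list
    driver_stack: dict[str, RasterGrid]
    plumes: dict[str, RasterGrid]
    per_tube: dict[str, np.ndarray]
    d_c: float
    human_derived_fraction: dict[str, float]


def run_land_sea(
    site: SiteBundle,
    tube_spacing: float = 200.0,
    plume_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    mass_conserving: bool = False,
) -> LandSeaStage:
    """Recharge → flow → loading → tubes → plumes → driver stack for one site."""
    osds = _osds_effluent_raster(site)
    recharge, n_clipped = compute_recharge(RechargeInputs(
        precipitation=site.rainfall,
        actual_et=site.actual_et,
        osds_effluent=osds,
        runoff_fraction=site.runoff_fraction,
    ))
    head = solve_steady_head(recharge, site.transmissivity, fixed_head=site.sea_mask)
    flow = darcy_flow(head, site.transmissivity)
    recharge_volume = float(np.nansum(recharge.values)) * recharge.cell_area
    budget = domain_water_budget(
        recharge_volume,
        injection=site.injection_volume,
        stream_discharge=site.stream_discharge,
    )

    n_bg, p_bg = background_flux(site.recharge_zones, recharge)
    n_anth, p_anth = rasterize_sources(site.sources, recharge)
    human_frac = {
        "N": 100.0 * n_anth.sum() / (n_anth.sum() + n_bg.sum()),
        "P": 100.0 * p_anth.sum() / (p_anth.sum() + p_bg.sum()),
    }

    pour_points = place_pour_points(site.shoreline, tube_spacing)
    seeds = boundary_seed_points(site.shoreline, tube_spacing)
    paths = trace_flowpaths(flow, seeds, direction="reverse")
    dist_shore_land = distance_to_shore(site.shoreline, recharge)
    water = recharge.like(recharge.values * recharge.cell_area, units="m3.yr-1")
    tubes = delineate_flow_tubes(
        paths, pour_points, recharge, dist_shore_land.values, site.inland_extent
    )
    tubes = zone_budget(tubes, water, n_bg, n_anth, p_bg, p_anth)
    # reconcile tube water with the domain budget: streams/withdrawal remove
    # water before the coast; injection enters near the injection well
    total_tube_water = sum(t.water_flux for t in tubes)
    scale = (budget.coastal_discharge - site.injection_volume) / total_tube_water
    for t in tubes:
        t.water_flux *= scale
    if site.injection_volume > 0:
        inj = [f for f in site.sources if f.attributes.get("class") == "injection_well"][0]
        nearest = min(tubes, key=lambda t: abs(t.pour_point.x - inj.geometry.x))
        nearest.water_flux += site.injection_volume

    marine = build_marine_stack(site.bathymetry, site.wave_power, site.shoreline)
    cost = cost_surface(marine["depth"], marine["dist_shore"], marine["wave_power"],
                        plume_weights)
    reef = site.bathymetry
    pour_cells = []
    for t in tubes:
        j = int(np.clip((t.pour_point.x - reef.origin[0]) / reef.cell_size, 0, reef.shape[1] - 1))
        col_valid = np.nonzero(cost.mask[:, j])[0]
        pour_cells.append((int(col_valid.max()), j))  # nearest-to-shore valid cell
    plumes, per_tube, d_c = stack_plumes(
        tubes, cost, marine["dist_shore"], pour_cells,
        mass_conserving=mass_conserving,
    )
    driver_stack = dict(marine)
    for name in ("freshwater", "n_flux", "p_flux"):
        driver_stack[name] = plumes[name]
    return LandSeaStage(
        recharge=recharge, n_clipped=n_clipped, budget=budget, tubes=tubes,
        driver_stack=driver_stack, plumes=plumes, per_tube=per_tube, d_c=float(d_c),
        human_derived_fraction=human_frac,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    rng_root = np.random.default_rng(config.seed)
    sub = {name: int(s) for name, s in zip(
        ("site", "surveys", "fit", "perm"),
        rng_root.integers(0, 2**31 - 1, size=4),
    )}

    site = generate_site(config.preset, config.size, seed=sub["site"])
    stage = run_land_sea(site, config.tube_spacing, config.plume_weights,
                         config.mass_conserving_plumes)
    recharge, budget, tubes = stage.recharge, stage.budget, stage.tubes
    driver_stack, plumes, per_tube = stage.driver_stack, stage.plumes, stage.per_tube
    marine = {k: driver_stack[k] for k in driver_stack
              if k not in ("freshwater", "n_flux", "p_flux")}
    d_c, n_clipped, human_frac = stage.d_c, stage.n_clipped, stage.human_derived_fraction
    reef = site.bathymetry

    # --- surveys and reef models ------------------------------------------
    surveys, truth = generate_surveys(
        driver_stack, n=config.n_surveys, seed=sub["surveys"],
        noise_fraction=config.survey_noise_fraction,
    )
    X_drivers = sample_at_points(driver_stack, surveys["x"].to_numpy(), surveys["y"].to_numpy())
    models: dict[str, object] = {}
    predictions: dict[str, RasterGrid] = {}
    rows = []
    for name in BENTHIC_COLS:
        y_t = transform_response(surveys[name].to_numpy(), "sqrt")
        m = fit_brt(X_drivers, y_t, response=name, transform="sqrt",
                    config=config.brt, response_upper=100.0)
        models[name] = m
        predictions[name] = predict_map(m, driver_stack)
    fish_stack = dict(driver_stack)
    for name in BENTHIC_COLS:
        fish_stack[name] = predictions[name]
    X_fish = X_drivers.copy()
    for name in BENTHIC_COLS:
        X_fish[name] = surveys[name].to_numpy()  # empirical benthic covers at fit time
    for name in FISH_COLS:
        y_t = transform_response(surveys[name].to_numpy(), "fourth_root")
        m = fit_brt(X_fish, y_t, response=name, transform="fourth_root",
                    config=config.brt)
        models[name] = m
        predictions[name] = predict_map(m, fish_stack)

    coords = surveys[["x", "y"]].to_numpy()
    # distance band: 3 reef cells, widened if any survey point would be isolated
    d2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d2, np.inf)
    band = max(3 * reef.cell_size, float(d2.min(axis=1).max()) * 1.01)
    for name in BENTHIC_COLS + FISH_COLS:
        m = models[name]
        kind = m.transform
        y_t = transform_response(surveys[name].to_numpy(), kind)
        resid = y_t - m.predict_transformed(X_fish if name in FISH_COLS else X_drivers)
        i_res, p_res = morans_i(resid, coords, band=band, seed=sub["perm"])
        from .grid import bilinear_sample
        pred_at_pts = bilinear_sample(predictions[name], surveys["x"].to_numpy(),
                                      surveys["y"].to_numpy())
        ok = np.isfinite(pred_at_pts)
        r2, slope, pval = obs_vs_pred(surveys[name].to_numpy()[ok], pred_at_pts[ok])
        rows.append({
            "indicator": name, "lr": m.lr, "tc": m.tc, "bag": m.bag,
            "n_trees": m.n_trees, "pde": m.pde, "cv_pde": m.cv_pde,
            "morans_i_resid": i_res, "morans_p_resid": p_res,
            "obs_vs_pred_r2": r2, "obs_vs_pred_p": pval,
        })
    metrics = pd.DataFrame(rows)

    # --- ordination --------------------------------------------------------
    Y = pd.DataFrame({
        name: transform_response(surveys[name].to_numpy(),
                                 "sqrt" if name in BENTHIC_COLS else "fourth_root")
        for name in BENTHIC_COLS + FISH_COLS
    })
    ordination = dbrda(Y, X_drivers)

    # --- prioritization ----------------------------------------------------
    if config.preset == "wet":
        benthic_rule = [["coral", "macroalgae"], ["turf"]]
        criteria = derive_thresholds(
            predictions, plumes["n_flux"], wave_power=marine["wave_power"],
            benthic_rule=benthic_rule,
        )
        vuln = classify_vulnerable(marine["depth"], predictions, plumes["n_flux"],
                                   criteria, wave_power=marine["wave_power"])
    else:
        benthic_rule = [["coral"], ["cca"], ["turf"]]
        criteria = derive_thresholds(
            predictions, plumes["n_flux"], p_flux=plumes["p_flux"],
            benthic_rule=benthic_rule,
        )
        vuln = classify_vulnerable(marine["depth"], predictions, plumes["n_flux"],
                                   criteria, p_flux=plumes["p_flux"])
    nutrient_plumes = np.nan_to_num(per_tube["n_flux"], nan=0.0) + \
        np.nan_to_num(per_tube["p_flux"], nan=0.0)
    ranking = match_priority_tubes(vuln, tubes, nutrient_plumes)
    vuln.tube_ranking = ranking

    result = PipelineResult(
        config=config, site=site, recharge=recharge, budget=budget, tubes=tubes,
        driver_stack=driver_stack, per_tube_plumes=per_tube, d_c=float(d_c),
        surveys=surveys, truth=truth, models=models, predictions=predictions,
        metrics=metrics, ordination=ordination, vulnerability=vuln,
        ranking=ranking, human_derived_fraction=human_frac, manifest={},
    )
    result.manifest = _build_manifest(result, n_clipped)
    if config.outdir is not None:
        _write_artifacts(result, Path(config.outdir))
    return result


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(np.nan_to_num(a, nan=-9999.0)).tobytes()).hexdigest()[:16]


def _build_manifest(res: PipelineResult, n_clipped: int) -> dict:
    b = res.budget
    tube_water = sum(t.water_flux for t in res.tubes)
    return {
        "version": __version__,
        "seed": res.config.seed,
        "preset": res.config.preset,
        "size": res.config.size,
        "recharge_clipped_cells": n_clipped,
        "budget_m3yr": {
            "recharge": b.recharge, "injection": b.injection,
            "stream_discharge": b.stream_discharge,
            "coastal_discharge": b.coastal_discharge,
        },
        "tube_water_total_m3yr": tube_water,
        "mass_conserving_plumes": res.config.mass_conserving_plumes,
        "human_derived_fraction_pct": res.human_derived_fraction,
        "hashes": {
            "recharge": _hash_array(res.recharge.values),
            "surveys": hashlib.sha256(
                res.surveys.round(9).to_csv(index=False).encode()).hexdigest()[:16],
            **{f"pred_{k}": _hash_array(v.values) for k, v in res.predictions.items()},
        },
    }


def _write_artifacts(res: PipelineResult, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    res.site.write(outdir / "site")
    write_ascii_grid(res.recharge, outdir / "recharge.asc")
    for name, g in res.predictions.items():
        write_ascii_grid(g, outdir / f"pred_{name}.asc")
    write_ascii_grid(res.vulnerability.flags, outdir / "vulnerability.asc")
    write_surveys(res.surveys, outdir / "surveys.csv")
    res.metrics.to_csv(outdir / "model_metrics.csv", index=False)
    pd.DataFrame([{
        "tube_id": t.id, "pour_x": t.pour_point.x, "pour_y": t.pour_point.y,
        "water_flux": t.water_flux,
        "n_flux_background": t.n_flux_background,
        "n_flux_anthropogenic": t.n_flux_anthropogenic,
        "p_flux_background": t.p_flux_background,
        "p_flux_anthropogenic": t.p_flux_anthropogenic,
    } for t in res.tubes]).to_csv(outdir / "tubes.csv", index=False)
    pd.DataFrame(res.ranking).to_csv(outdir / "priority_tubes.csv", index=False)
    influence = pd.DataFrame({k: m.relative_influence for k, m in res.models.items()})
    influence.to_csv(outdir / "relative_influence.csv")
    (outdir / "manifest.json").write_text(json.dumps(res.manifest, indent=1, sort_keys=True))
    return outdir
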