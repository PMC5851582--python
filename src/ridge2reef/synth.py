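"""Synthetic land-sea sites with known ground truth.

Two presets emulate the contrasting study conditions of a wet, high-recharge
windward site and a dry, low-recharge leeward site on a high oceanic island:

* ``wet`` — rainfall around 4 m·yr⁻¹ rising steeply inland, recharge within
  0.11–4.97 m·yr⁻¹, uniform background groundwater concentrations
  (0.50 mg·L⁻¹ N, 0.20 mg·L⁻¹ P), 136 coastal residences (99 cesspools,
  37 septic systems) and 6 ha of lawn, high wave power, perennial-stream
  baseflow loss scaled from 0.26 m³·s⁻¹ by domain area.
* ``dry`` — rainfall 0.26–1.35 m·yr⁻¹, recharge within 0.04–0.69 m·yr⁻¹,
  four background zones (upland/lowland × two aquifer halves) with zone
  concentrations of 2.70/0.25/1.20/0.25 mg·L⁻¹ N and 0.20/0.10/0.15/0.10
  mg·L⁻¹ P, 193 residences, lawn and golf polygons, one injection well
  (160,600 m³·yr⁻¹), low wave power, no streams.

The land surface is a smooth inclined plane; the shoreline optionally bulges
inland as a Gaussian embayment so that groundwater flow lines converge there.
Sources are concentrated in the coastal strip, mimicking coastal development.

Reef surveys are generated from known smooth response functions of a few
named drivers plus Gaussian noise on the transformed scale (where the reef
models fit), then back-transformed and clipped; the truth record stores the
active drivers, coefficients and noise level per indicator so that model
recovery is checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box

from .grid import (
    BENTHIC_COLS,
    FISH_COLS,
    Feature,
    FeatureSet,
    RasterGrid,
    write_ascii_grid,
    write_geojson,
)
from .nutrients import RechargeZoneSpec

__all__ = ["SiteBundle", "SurveyTruth", "generate_site", "generate_surveys", "PRESETS"]

LAND_CELL = 50.0   # m
REEF_CELL = 60.0   # m
SEC_PER_YEAR = 365.25 * 24 * 3600.0

PRESETS = {
    "wet": dict(
        recharge_range=(0.11, 4.97),     # m/yr
        runoff_fraction=0.54,
        ae_range=(0.25, 0.45),           # m/yr actual evapotranspiration
        transmissivity=1.0e6,            # m2/yr
        background=[("domain", 0.50, 0.20)],
        n_cesspool=99, n_septic=37, lawn_ha=6.0, golf_ha=0.0, injection=False,
        stream_m3s=0.26, stream_domain_ha=6975.0,
        wave_mean=21_697.0, wave_sd=4_119.0,
        max_depth=15.0,
        inland_extent=1000.0,
    ),
    "dry": dict(
        recharge_range=(0.04, 0.69),
        runoff_fraction=0.10,
        ae_range=(0.18, 0.50),
        transmissivity=5.0e5,
        background=[
            ("upland_west", 2.70, 0.20),   # high-N upland zone
            ("lowland_west", 0.25, 0.10),
            ("upland_east", 1.20, 0.15),
            ("lowland_east", 0.25, 0.10),
        ],
        n_cesspool=193, n_septic=0, lawn_ha=45.0, golf_ha=190.0, injection=True,
        stream_m3s=0.0, stream_domain_ha=1.0,
        wave_mean=2_756.0, wave_sd=186.0,
        max_depth=22.0,
        inland_extent=3500.0,
    ),
}


@dataclass
class SurveyTruth:
    """Generative record for the synthetic reef surveys."""

    indicators: dict[str, dict]               # name -> {drivers, coefs, intercept, transform}
    normalization: dict[str, tuple[float, float]]  # driver -> (mean, sd)
    noise_sd: dict[str, float]
    seed: int


@dataclass
class SiteBundle:
    """All inputs for one synthetic site, plus its generative parameters."""

    preset: str
    seed: int
    rainfall: RasterGrid            # m/yr, land grid
    actual_et: RasterGrid           # m/yr
    transmissivity: RasterGrid      # m2/yr
    land_mask: np.ndarray           # True on land cells
    sea_mask: np.ndarray            # True on fixed-head (sea) cells of land grid
    bathymetry: RasterGrid          # m (negative below sea level), reef grid
    wave_power: RasterGrid          # kW/m, reef grid
    shoreline: LineString
    recharge_zones: list[RechargeZoneSpec]
    sources: FeatureSet
    runoff_fraction: float
    stream_discharge: float         # m3/yr, domain total
    injection_volume: float         # m3/yr
    inland_extent: float            # m, flow-tube length (clipped to domain)
    truth: SurveyTruth | None = None

    @property
    def domain_area_ha(self) -> float:
        return float(self.land_mask.sum()) * self.rainfall.cell_area / 1e4

    def write(self, outdir: str | Path) -> Path:
        """Write the bundle in the standard formats (ASCII grids, GeoJSON, JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("rainfall", "actual_et", "transmissivity", "bathymetry", "wave_power"):
            write_ascii_grid(getattr(self, name), outdir / f"{name}.asc")
        write_geojson(self.sources, outdir / "sources.geojson")
        write_geojson(
            FeatureSet([Feature(z.polygon, {"name": z.name, "conc_n": z.conc_n, "conc_p": z.conc_p})
                        for z in self.recharge_zones]),
            outdir / "recharge_zones.geojson",
        )
        write_geojson(FeatureSet([Feature(self.shoreline, {})]), outdir / "shoreline.geojson")
        meta = {
            "preset": self.preset, "seed": self.seed,
            "runoff_fraction": self.runoff_fraction,
            "stream_discharge_m3yr": self.stream_discharge,
            "injection_volume_m3yr": self.injection_volume,
            "inland_extent_m": self.inland_extent,
        }
        (outdir / "site.json").write_text(json.dumps(meta, indent=1))
        return outdir


def _smooth(rng: np.random.Generator, shape: tuple[int, int], sd: float, passes: int = 6) -> np.ndarray:
    """Smooth correlated noise field (iterated 3×3 box filter of white noise)."""
    f = rng.normal(0.0, 1.0, shape)
    for _ in range(passes):
        p = np.pad(f, 1, mode="edge")
        f = (
            p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
            + p[1:-1, :-2] + p[1:-1, 1:-1] + p[1:-1, 2:]
            + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:]
        ) / 9.0
    s = f.std()
    return f * (sd / s) if s > 0 else f


def generate_site(
    preset: str,
    size: int = 40,
    seed: int = 0,
    embayment_amplitude_cells: float = 2.0,
) -> SiteBundle:
    """Generate a complete synthetic site; deterministic given (preset, size, seed).

    ``size`` is the land grid dimension in cells (50 m cells); the reef grid
    spans the same alongshore extent at 60 m cells, 1.5 km offshore.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if size < 20:
        raise ValueError("size must be >= 20 land cells")
    p = PRESETS[preset]
    rng = np.random.default_rng(seed)
    cs = LAND_CELL
    L = size * cs

    # shoreline: y = 0 with an optional Gaussian embayment bulging inland
    amp = embayment_amplitude_cells * cs
    xs_dense = np.linspace(0.0, L, 4 * size + 1)
    ys_dense = amp * np.exp(-((xs_dense - 0.55 * L) ** 2) / (2 * (0.12 * L) ** 2))
    shoreline = LineString(np.column_stack([xs_dense, ys_dense]))

    land = RasterGrid(np.zeros((size, size)), cs, (0.0, 0.0), units="m.yr-1")
    X, Y = land.center_mesh()
    y_shore = np.interp(X[0], xs_dense, ys_dense)
    sea_mask = Y <= y_shore[None, :]
    land_mask = ~sea_mask
    # guarantee at least the bottom data row is a fixed-head coast
    sea_mask[0, :] |= Y[0, :] <= max(y_shore.max(), cs)

    # recharge target field: smooth inland ramp within the preset range
    r_lo, r_hi = p["recharge_range"]
    ramp = np.clip((Y - y_shore[None, :]) / (L - y_shore.max()), 0.0, 1.0) ** 2.5
    noise = _smooth(rng, (size, size), sd=0.05 * (r_hi - r_lo))
    margin = 0.02 * (r_hi - r_lo)
    recharge_target = np.clip(r_lo + (r_hi - r_lo) * ramp + noise, r_lo + margin, r_hi - margin)

    ae_lo, ae_hi = p["ae_range"]
    ae = np.clip(
        ae_lo + (ae_hi - ae_lo) * np.clip(Y / L, 0, 1)
        + _smooth(rng, (size, size), sd=0.03 * (ae_hi - ae_lo)),
        0.5 * ae_lo, 1.2 * ae_hi,
    )
    # invert the recharge equation so R = (1 - DR)·P − AE hits the target
    rainfall_vals = (recharge_target + ae) / (1.0 - p["runoff_fraction"])
    rainfall_vals[sea_mask] = np.nan
    ae_vals = ae.copy()
    ae_vals[sea_mask] = np.nan

    rainfall = land.like(rainfall_vals, units="m.yr-1")
    actual_et = land.like(ae_vals, units="m.yr-1")
    tvals = np.full((size, size), p["transmissivity"])
    transmissivity = land.like(tvals, units="m2.yr-1")

    # background recharge zones
    zones: list[RechargeZoneSpec] = []
    pad = 2 * cs
    if len(p["background"]) == 1:
        name, cn, cp = p["background"][0]
        zones.append(RechargeZoneSpec(box(-pad, -pad, L + pad, L + pad), cn, cp, name))
    else:
        y_split = 0.45 * L
        x_split = 0.5 * L
        extents = {
            "upland_west": box(-pad, y_split, x_split, L + pad),
            "lowland_west": box(-pad, -pad, x_split, y_split),
            "upland_east": box(x_split, y_split, L + pad, L + pad),
            "lowland_east": box(x_split, -pad, L + pad, y_split),
        }
        for name, cn, cp in p["background"]:
            zones.append(RechargeZoneSpec(extents[name], cn, cp, name))

    # source inventory, concentrated in the coastal strip
    sources = []
    strip_top = min(0.3 * L + amp, L - cs)

    def _coastal_points(n: int) -> np.ndarray:
        pts = np.empty((n, 2))
        k = 0
        while k < n:
            x = rng.uniform(cs, L - cs)
            y = rng.uniform(y_shore.max() + 0.5 * cs, strip_top)
            pts[k] = (x, y)
            k += 1
        return pts

    for x, y in _coastal_points(p["n_cesspool"]):
        sources.append(Feature(Point(x, y), {"class": "cesspool"}))
    for x, y in _coastal_points(p["n_septic"]):
        sources.append(Feature(Point(x, y), {"class": "septic"}))

    domain_ha = float(land_mask.sum()) * cs * cs / 1e4

    def _strip_polygon(area_ha: float, x_frac: float) -> Polygon:
        side = np.sqrt(area_ha * 1e4)
        x0 = np.clip(x_frac * L - side / 2, 0, L - side)
        y0 = y_shore.max() + cs
        return box(x0, y0, x0 + side, y0 + side)

    if p["lawn_ha"] > 0:
        lawn_ha = min(p["lawn_ha"], 0.1 * domain_ha)
        sources.append(Feature(_strip_polygon(lawn_ha, 0.25), {"class": "lawn"}))
    if p["golf_ha"] > 0:
        golf_ha = min(p["golf_ha"], 0.2 * domain_ha)
        sources.append(Feature(_strip_polygon(golf_ha, 0.7), {"class": "golf"}))
    injection_volume = 0.0
    if p["injection"]:
        sources.append(Feature(Point(0.5 * L, y_shore.max() + 2 * cs), {"class": "injection_well"}))
        injection_volume = 160_600.0

    # reef grid: same alongshore extent, 60 m cells, 1.5 km offshore
    n_cols_reef = int(L // REEF_CELL)
    n_rows_reef = int(1500.0 // REEF_CELL)
    reef = RasterGrid(
        np.zeros((n_rows_reef, n_cols_reef)), REEF_CELL,
        (0.0, -n_rows_reef * REEF_CELL), units="m",
    )
    Xr, Yr = reef.center_mesh()
    y_shore_r = np.interp(Xr[0], xs_dense, ys_dense)
    doff = np.maximum(y_shore_r[None, :] - Yr, 0.0)  # offshore distance proxy
    dmax = doff.max()
    depth = -(p["max_depth"] * (doff / dmax) ** 0.9)
    depth += _smooth(rng, depth.shape, sd=0.04 * p["max_depth"])
    depth = np.minimum(depth, -0.2)
    bathymetry = reef.like(depth, units="m")

    wave = p["wave_mean"] * (0.75 + 0.5 * doff / dmax) + _smooth(rng, depth.shape, sd=p["wave_sd"])
    wave_power = reef.like(np.maximum(wave, 0.0), units="kW.m-1")

    stream = p["stream_m3s"] * SEC_PER_YEAR * (domain_ha / p["stream_domain_ha"])

    return SiteBundle(
        preset=preset,
        seed=seed,
        rainfall=rainfall,
        actual_et=actual_et,
        transmissivity=transmissivity,
        land_mask=land_mask,
        sea_mask=sea_mask,
        bathymetry=bathymetry,
        wave_power=wave_power,
        shoreline=shoreline,
        recharge_zones=zones,
        sources=FeatureSet(sources),
        runoff_fraction=p["runoff_fraction"],
        stream_discharge=stream,
        injection_volume=injection_volume,
        inland_extent=min(p["inland_extent"], L - 2 * cs),
    )


# -- survey generation ------------------------------------------------------

#: Truth response functions on the transformed scale: intercept + Σ coef·z(driver).
#: Benthic on sqrt(% cover) scale, fish on fourth-root(g·m⁻²) scale.
TRUTH_SPECS: dict[str, dict] = {
    "coral": dict(transform="sqrt", intercept=5.5,
                  coefs={"freshwater": -1.2, "wave_power": -1.0, "rugosity": 0.8}),
    "cca": dict(transform="sqrt", intercept=4.5,
                coefs={"wave_power": 1.3, "dist_shore": 0.8, "freshwater": -0.6}),
    "turf": dict(transform="sqrt", intercept=5.0,
                 coefs={"n_flux": 1.2, "freshwater": 0.9}),
    "macroalgae": dict(transform="sqrt", intercept=3.0,
                       coefs={"n_flux": 1.1, "dist_shore": -0.7}),
    "grazer": dict(transform="fourth_root", intercept=1.5,
                   coefs={"turf": 0.25, "coral": 0.15}),
    "browser": dict(transform="fourth_root", intercept=1.4,
                    coefs={"n_flux": -0.2, "macroalgae": 0.2}),
    "scraper": dict(transform="fourth_root", intercept=1.45,
                    coefs={"wave_power": 0.2, "macroalgae": -0.15}),
    "piscivore": dict(transform="fourth_root", intercept=1.3,
                      coefs={"dist_shore": 0.2, "n_flux": -0.2}),
}


def _truth_fields(
    stack: dict[str, RasterGrid],
) -> tuple[dict[str, np.ndarray], dict[str, tuple[float, float]]]:
    """Transformed-scale truth fields per indicator, plus normalization stats."""
    norm: dict[str, tuple[float, float]] = {}
    zfields: dict[str, np.ndarray] = {}
    needed = {d for spec in TRUTH_SPECS.values() for d in spec["coefs"]
              if d not in TRUTH_SPECS}
    for d in needed:
        v = stack[d].values
        mu, sd = float(np.nanmean(v)), float(np.nanstd(v))
        norm[d] = (mu, sd)
        zfields[d] = (v - mu) / sd if sd > 0 else np.zeros_like(v)
    fields: dict[str, np.ndarray] = {}
    for name, spec in TRUTH_SPECS.items():
        t = np.full(next(iter(stack.values())).shape, spec["intercept"], dtype=float)
        for d, c in spec["coefs"].items():
            if d in TRUTH_SPECS:  # benthic indicator as a fish driver
                v = fields[d]
                mu, sd = float(np.nanmean(v)), float(np.nanstd(v))
                norm[f"{name}:{d}"] = (mu, sd)
                z = (v - mu) / sd if sd > 0 else np.zeros_like(v)
            else:
                z = zfields[d]
            t = t + c * z
        fields[name] = np.maximum(t, 0.0)
    return fields, norm


def generate_surveys(
    stack: dict[str, RasterGrid],
    n: int,
    seed: int = 0,
    noise_fraction: float = 0.25,
) -> tuple[pd.DataFrame, SurveyTruth]:
    """Synthetic reef survey table from known driver-response functions.

    Sites are sampled without replacement at reef cell centers where every
    stack layer is valid; each indicator is its truth function plus Gaussian
    noise with SD = ``noise_fraction`` × the truth field's SD, applied on the
    transformed scale, then back-transformed and clipped to the valid range.
    """
    if n < 30:
        raise ValueError("need n >= 30 survey sites")
    ref = next(iter(stack.values()))
    valid = np.ones(ref.shape, dtype=bool)
    for g in stack.values():
        valid &= g.mask
    idx = np.argwhere(valid)
    if n > len(idx):
        raise ValueError(f"n = {n} exceeds the {len(idx)} available reef cells")
    rng = np.random.default_rng(seed)
    chosen = idx[rng.choice(len(idx), size=n, replace=False)]
    xs = ref.origin[0] + (chosen[:, 1] + 0.5) * ref.cell_size
    ys = ref.origin[1] + (chosen[:, 0] + 0.5) * ref.cell_size

    fields, norm = _truth_fields(stack)
    table = {"x": xs, "y": ys}
    noise_sd: dict[str, float] = {}
    for name, spec in TRUTH_SPECS.items():
        t = fields[name][chosen[:, 0], chosen[:, 1]]
        sd = noise_fraction * float(np.nanstd(fields[name][valid]))
        noise_sd[name] = sd
        obs_t = t + rng.normal(0.0, sd, size=n) if sd > 0 else t
        if spec["transform"] == "sqrt":
            obs = np.clip(np.maximum(obs_t, 0.0) ** 2, 0.0, 100.0)
        else:
            obs = np.maximum(obs_t, 0.0) ** 4
        table[name] = obs
    df = pd.DataFrame(table)[["x", "y"] + BENTHIC_COLS + FISH_COLS]
    truth = SurveyTruth(
        indicators={
            name: {"drivers": list(spec["coefs"]), "coefs": dict(spec["coefs"]),
                   "intercept": spec["intercept"], "transform": spec["transform"]}
            for name, spec in TRUTH_SPECS.items()
        },
        normalization=norm,
        noise_sd=noise_sd,
        seed=seed,
    )
    return df, truth
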