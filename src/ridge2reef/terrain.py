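"""Bathymetric terrain drivers at the reef-model resolution (60 m).

Habitat topography (slope, bathymetric position index), complexity (rugosity,
plan/profile curvature) and exposure (aspect circular statistics) are derived
from the bathymetry raster; geography is depth itself plus Euclidean distance
to the shoreline; wave power is an input layer (hindcast wave modeling is out
of scope).  All window operations treat NaN as nodata and propagate it.

Conventions: bathymetry is in meters, negative below sea level.  Aspect is
the downslope compass azimuth in degrees, [0, 360), 0 = north (+y), 90 = east
(+x); it is nodata on flat cells.  Curvatures follow the quadratic-surface
(Zevenbergen–Thorne) fit: profile curvature is the negated second directional
derivative along the gradient, plan curvature the corresponding across-slope
term; both are 0 where the gradient vanishes.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy.ndimage import convolve
from shapely.geometry import LineString

from .grid import RasterGrid

__all__ = [
    "slope_aspect",
    "bpi",
    "curvatures",
    "rugosity",
    "circular_stats",
    "distance_to_shore",
    "neighborhood_mean",
    "aggregate_mean",
    "build_marine_stack",
]


def _horn_gradient(z: np.ndarray, cs: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3×3 finite-difference gradient (∂z/∂x, ∂z/∂y); NaN propagates."""
    zp = np.pad(z, 1, mode="edge")
    # neighbours: rows increase with +y (north), cols with +x (east)
    sw, s, se = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    nw, n_, ne = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cs)
    dzdy = ((ne + 2 * n_ + nw) - (se + 2 * s + sw)) / (8 * cs)
    return dzdx, dzdy


def slope_aspect(bathy: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope (degrees) and downslope aspect (compass degrees) per cell."""
    zx, zy = _horn_gradient(bathy.values, bathy.cell_size)
    grad = np.hypot(zx, zy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(-zx, -zy)) % 360.0
    aspect[grad == 0] = np.nan  # aspect undefined on flat cells
    slope[~bathy.mask] = np.nan
    aspect[~bathy.mask] = np.nan
    return bathy.like(slope, units="degrees"), bathy.like(aspect, units="degrees")


def _circular_kernel(radius: float, cs: float, exclude_center: bool) -> np.ndarray:
    r_cells = int(np.floor(radius / cs))
    if r_cells < 1:
        raise ValueError(f"radius {radius} m smaller than cell size {cs} m")
    idx = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(idx, idx, indexing="ij")
    k = (np.hypot(dx, dy) * cs <= radius).astype(float)
    if exclude_center:
        k[r_cells, r_cells] = 0.0
    return k


def _masked_convolve(v: np.ndarray, kernel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sum of valid neighbours, count of valid neighbours) under the kernel."""
    mask = np.isfinite(v)
    filled = np.where(mask, v, 0.0)
    s = convolve(filled, kernel, mode="constant", cval=0.0)
    c = convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    return s, c


def neighborhood_mean(grid: RasterGrid, radius: float, exclude_center: bool = False) -> RasterGrid:
    """Mean over a circular neighborhood of the given radius (nodata-aware)."""
    k = _circular_kernel(radius, grid.cell_size, exclude_center)
    s, c = _masked_convolve(grid.values, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = s / c
    m[c == 0] = np.nan
    m[~grid.mask] = np.nan
    return grid.like(m)


def bpi(bathy: RasterGrid, radius: float) -> RasterGrid:
    """Bathymetric position index: center depth minus neighborhood mean depth.

    Positive values are ridges/pinnacles, negative are depressions.  The
    neighborhood is circular by center distance and excludes the center cell.
    """
    m = neighborhood_mean(bathy, radius, exclude_center=True)
    return bathy.like(bathy.values - m.values, units="m")


def curvatures(bathy: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """(plan, profile) curvature from a 3×3 quadratic-surface fit.

    Profile curvature (along the gradient) indicates flow acceleration;
    plan curvature (across the gradient) indicates flow convergence.  Both
    are zero where the gradient vanishes.
    """
    z = bathy.values
    cs = bathy.cell_size
    zp = np.pad(z, 1, mode="edge")
    s, n_ = zp[:-2, 1:-1], zp[2:, 1:-1]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, se = zp[:-2, :-2], zp[:-2, 2:]
    nw, ne = zp[2:, :-2], zp[2:, 2:]
    D = ((w_ + e_) / 2 - z) / cs**2          # ½ ∂²z/∂x²
    E = ((n_ + s) / 2 - z) / cs**2           # ½ ∂²z/∂y²
    F = (sw + ne - nw - se) / (4 * cs**2)    # ∂²z/∂x∂y
    G = (e_ - w_) / (2 * cs)                 # ∂z/∂x
    H = (n_ - s) / (2 * cs)                  # ∂z/∂y
    g2 = G**2 + H**2
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = -2 * (D * G**2 + E * H**2 + F * G * H) / g2
        plan = 2 * (D * H**2 + E * G**2 - F * G * H) / g2
    profile = np.where(g2 == 0, 0.0, profile)
    plan = np.where(g2 == 0, 0.0, plan)
    profile[~bathy.mask] = np.nan
    plan[~bathy.mask] = np.nan
    return bathy.like(plan, units="rad.m-1"), bathy.like(profile, units="rad.m-1")


def rugosity(bathy: RasterGrid) -> RasterGrid:
    """Surface-area / planimetric-area ratio per cell (1 = flat).

    Computed as sec(slope) = √(1 + |∇z|²) from the Horn gradient, the area
    ratio of the local tangent plane; exact for a tilted plane.
    """
    zx, zy = _horn_gradient(bathy.values, bathy.cell_size)
    r = np.sqrt(1.0 + zx**2 + zy**2)
    r[~bathy.mask] = np.nan
    return bathy.like(r, units="ratio")


def circular_stats(
    aspect: RasterGrid, radius: float
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Neighborhood circular statistics of aspect: (northness, eastness, sd).

    The circular mean μ is taken via the mean resultant vector over the
    neighborhood; northness = cos μ, eastness = sin μ, and the circular
    standard deviation is √(−2 ln R̄) (radians), large for uniform aspects.
    """
    a = np.radians(aspect.values)
    k = _circular_kernel(radius, aspect.cell_size, exclude_center=False)
    sin_s, c1 = _masked_convolve(np.sin(a), k)
    cos_s, _ = _masked_convolve(np.cos(a), k)
    with np.errstate(invalid="ignore", divide="ignore"):
        ms, mc = sin_s / c1, cos_s / c1
        rbar = np.hypot(ms, mc)
        mu = np.arctan2(ms, mc)  # compass convention: sin = east, cos = north
        sd = np.sqrt(-2.0 * np.log(np.clip(rbar, 1e-12, 1.0)))
    bad = c1 == 0
    for arr in (ms, mc, sd):
        arr[bad] = np.nan
    northness = np.cos(mu)
    eastness = np.sin(mu)
    northness[bad] = np.nan
    eastness[bad] = np.nan
    return (
        aspect.like(northness, units="unitless"),
        aspect.like(eastness, units="unitless"),
        aspect.like(sd, units="radians"),
    )


def distance_to_shore(shoreline: LineString, grid: RasterGrid) -> RasterGrid:
    """Euclidean distance (m) from each cell center to the shoreline."""
    if shoreline.is_empty or shoreline.length == 0:
        raise ValueError("empty shoreline")
    xs, ys = grid.center_mesh()
    pts = shapely.points(xs, ys)
    d = shapely.distance(shoreline, pts)
    return grid.like(d, units="m")


def aggregate_mean(grid: RasterGrid, factor: int) -> RasterGrid:
    """Block-mean aggregation by an integer factor (e.g. fine bathymetry → 60 m)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nrows, ncols = grid.shape
    nr, nc = nrows // factor, ncols // factor
    v = grid.values[: nr * factor, : nc * factor].reshape(nr, factor, nc, factor)
    with np.errstate(invalid="ignore"):
        m = np.nanmean(v, axis=(1, 3))
    return RasterGrid(m, grid.cell_size * factor, grid.origin, units=grid.units)


def build_marine_stack(
    bathy: RasterGrid,
    wave_power: RasterGrid,
    shoreline: LineString,
    exposure_radius: float = 240.0,
) -> dict[str, RasterGrid]:
    """Assemble the full marine driver stack on the reef grid.

    Layers: wave_power, depth, dist_shore, slope_60, slope_240, bpi_60,
    bpi_240, plan_curv, prof_curv, rugosity, northness, eastness, aspect_sd.
    The *_60 metrics use the native 60 m cell scale (3×3 window / 60 m radius);
    the *_240 metrics a 240 m neighborhood radius.
    """
    slope, aspect = slope_aspect(bathy)
    plan, prof = curvatures(bathy)
    northness, eastness, aspect_sd = circular_stats(aspect, exposure_radius)
    stack = {
        "wave_power": wave_power,
        "depth": bathy,
        "dist_shore": distance_to_shore(shoreline, bathy),
        "slope_60": slope,
        "slope_240": neighborhood_mean(slope, 240.0),
        "bpi_60": bpi(bathy, 60.0),
        "bpi_240": bpi(bathy, 240.0),
        "plan_curv": plan,
        "prof_curv": prof,
        "rugosity": rugosity(bathy),
        "northness": northness,
        "eastness": eastness,
        "aspect_sd": aspect_sd,
    }
    return stack
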