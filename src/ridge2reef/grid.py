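"""Shared grid data model and file I/O.

All spatial data live on planar metric coordinates (projected meters); the
package never does geodesy.  Gridded fields are square-celled, row-major from
the lower-left corner, with cell centers at ``origin + (index + 0.5) * cell_size``.
In memory, nodata is represented as NaN so that arithmetic propagates it; the
``nodata`` sentinel is only used on disk (ESRI ASCII grid, a plain-text format
that natively carries cell size, origin and nodata).

Vector layers (source inventories, shoreline, recharge zones) are GeoJSON,
parsed with :mod:`shapely`.  Reef survey tables are CSV with a header.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "RasterGrid",
    "Feature",
    "FeatureSet",
    "RegistrationError",
    "require_registered",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geojson",
    "write_geojson",
    "read_surveys",
    "write_surveys",
    "BENTHIC_COLS",
    "FISH_COLS",
]

BENTHIC_COLS = ["cca", "coral", "turf", "macroalgae"]
FISH_COLS = ["browser", "grazer", "scraper", "piscivore"]


class RegistrationError(ValueError):
    """Raised when rasters entering a pipeline stage are not co-registered."""


@dataclass
class RasterGrid:
    """A co-registered 2D field on a square grid.

    Parameters
    ----------
    values
        2D float array, row 0 at the *bottom* (southern edge); NaN is nodata.
    cell_size
        Cell edge length in meters (> 0).
    origin
        (x, y) of the lower-left *corner* of the grid, meters.
    units
        Free-text unit tag, e.g. ``"m.yr-1"``, ``"kg.yr-1"``, ``"%"``.
    nodata
        Sentinel written to disk in place of NaN.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    units: str = "unknown"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2D, got shape {self.values.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        # normalize on-disk sentinel to NaN in memory
        self.values[self.values == self.nodata] = np.nan

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.shape[1]) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.shape[0]) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, shaped like ``values``."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; half-open cell intervals."""
        col = int(math.floor((x - self.origin[0]) / self.cell_size))
        row = int(math.floor((y - self.origin[1]) / self.cell_size))
        if not (0 <= row < self.shape[0] and 0 <= col < self.shape[1]):
            raise IndexError(f"point ({x}, {y}) outside grid extent")
        return row, col

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    # -- registration -------------------------------------------------------
    def registered_with(self, other: "RasterGrid", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=rtol)
            and math.isclose(self.origin[0], other.origin[0], abs_tol=rtol * max(1.0, self.cell_size))
            and math.isclose(self.origin[1], other.origin[1], abs_tol=rtol * max(1.0, self.cell_size))
        )

    def like(self, values: np.ndarray, units: str | None = None) -> "RasterGrid":
        """A new grid with the same geometry and the given values."""
        return replace(self, values=np.asarray(values, dtype=float).copy(),
                       units=self.units if units is None else units)

    def copy(self) -> "RasterGrid":
        return self.like(self.values)

    def sum(self) -> float:
        return float(np.nansum(self.values))


def require_registered(*grids: RasterGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.registered_with(g):
            raise RegistrationError(
                f"grids not co-registered: shape/cell/origin "
                f"{first.shape}/{first.cell_size}/{first.origin} vs "
                f"{g.shape}/{g.cell_size}/{g.origin}"
            )


# -- raster I/O (ESRI ASCII grid + unit sidecar line) -----------------------

def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write a grid as an ESRI ASCII raster.

    The unit tag is stored as a comment-like trailing header line ``units``
    which standard readers ignore and :func:`read_ascii_grid` recovers.
    """
    path = Path(path)
    vals = grid.values.copy()
    vals[~np.isfinite(vals)] = grid.nodata
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {grid.origin[1]!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
        f"units {grid.units}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids are written top row first
        for row in vals[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


def read_ascii_grid(path: str | Path) -> RasterGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not rows and key in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "units",
            }:
                header[key] = parts[1] if len(parts) > 1 else ""
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing required header field {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(rows) != nrows or any(len(r) != ncols for r in rows):
        raise ValueError(f"{path}: non-rectangular data block ({len(rows)} rows)")
    units = header.get("units")
    if units is None:
        logger.warning("%s: no unit tag; tagging 'unknown'", path)
        units = "unknown"
    return RasterGrid(
        values=np.array(rows[::-1], dtype=float),
        cell_size=float(header["cellsize"]),
        origin=(float(header.get("xllcorner", 0.0)), float(header.get("yllcorner", 0.0))),
        nodata=float(header.get("nodata_value", -9999.0)),
        units=units,
    )


def bilinear_sample(grid: RasterGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the 4 nearest cell centers at point(s) (x, y).

    Nodata neighbors have their weights renormalized over the valid ones; if
    all four neighbors are nodata the sample is NaN.  Points outside the
    cell-center hull are clamped to it (nearest-edge extrapolation).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    cs = grid.cell_size
    # fractional index relative to cell centers
    fx = (x - grid.origin[0]) / cs - 0.5
    fy = (y - grid.origin[1]) / cs - 0.5
    nrows, ncols = grid.shape
    fx = np.clip(fx, 0.0, ncols - 1.0)
    fy = np.clip(fy, 0.0, nrows - 1.0)
    j0 = np.clip(np.floor(fx).astype(int), 0, max(ncols - 2, 0))
    i0 = np.clip(np.floor(fy).astype(int), 0, max(nrows - 2, 0))
    tx = fx - j0
    ty = fy - i0
    v = grid.values
    i1 = np.minimum(i0 + 1, nrows - 1)
    j1 = np.minimum(j0 + 1, ncols - 1)
    corners = np.stack([v[i0, j0], v[i0, j1], v[i1, j0], v[i1, j1]])
    weights = np.stack([(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty])
    valid = np.isfinite(corners)
    weights = np.where(valid, weights, 0.0)
    wsum = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.nansum(weights * np.where(valid, corners, 0.0), axis=0) / wsum
    out[wsum == 0] = np.nan
    return out


# -- vector I/O -------------------------------------------------------------

@dataclass
class Feature:
    geometry: BaseGeometry
    attributes: dict = field(default_factory=dict)


@dataclass
class FeatureSet:
    """An ordered collection of (geometry, attributes) records."""

    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i: int) -> Feature:
        return self.features[i]

    def where(self, **attrs) -> "FeatureSet":
        """Subset of features whose attributes match all given key=value pairs."""
        return FeatureSet([
            f for f in self.features
            if all(f.attributes.get(k) == v for k, v in attrs.items())
        ])

    def validate(self) -> None:
        for i, f in enumerate(self.features):
            if not f.geometry.is_valid:
                raise ValueError(f"feature {i}: invalid geometry ({shapely.is_valid_reason(f.geometry)})")


def read_geojson(path: str | Path) -> FeatureSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    fs = FeatureSet([
        Feature(shape(f["geometry"]), dict(f.get("properties") or {}))
        for f in doc["features"]
    ])
    fs.validate()
    return fs


def write_geojson(features: FeatureSet, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(f.geometry), "properties": f.attributes}
            for f in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path


# -- survey tables ----------------------------------------------------------

def validate_surveys(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Validate a reef survey table, dropping invalid records.

    Benthic covers must lie in [0, 100] %; fish biomass must be >= 0.
    Returns the accepted rows and a list of human-readable rejection reasons.
    """
    required = ["x", "y"] + BENTHIC_COLS + FISH_COLS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"survey table missing required columns: {missing}")
    reasons: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    for col in BENTHIC_COLS:
        bad = ~df[col].between(0.0, 100.0) | df[col].isna()
        for idx in df.index[bad]:
            reasons.append(f"row {idx}: {col}={df.at[idx, col]} outside [0, 100]")
        keep &= ~bad.to_numpy()
    for col in FISH_COLS:
        bad = (df[col] < 0.0) | df[col].isna()
        for idx in df.index[bad]:
            reasons.append(f"row {idx}: {col}={df.at[idx, col]} negative")
        keep &= ~bad.to_numpy()
    for r in reasons:
        logger.warning("survey record rejected: %s", r)
    return df.loc[keep].reset_index(drop=True), reasons


def read_surveys(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df, _ = validate_surveys(pd.read_csv(path))
    return df


def write_surveys(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
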