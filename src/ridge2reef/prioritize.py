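"""Vulnerability overlay and flow-tube prioritization.

Reef cells are flagged as vulnerable to land-based nutrients where a set of
per-site criteria overlap: shallow depth (< 5 m, where bleaching risk is
highest), above-site-mean predicted benthic cover for the site's benthic
rule, nutrient plume exposure above the upper tercile, and (where active)
wave power below the lower tercile (poor mixing).  Benthic rules differ by
site and are expressed as an AND of OR-groups, e.g. the wet site uses
(coral OR macroalgae) AND turf, the dry site coral AND cca AND turf.

Flagged cells are attributed to the flow tube contributing the largest share
of their nutrient plume, and tubes are ranked by (anthropogenic nutrient
flux, flagged-cell count) lexicographically — the ranked tubes are the
priority land areas for nutrient management.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid, require_registered
from .flowtubes import FlowTube

logger = logging.getLogger(__name__)

__all__ = [
    "CriteriaConfig",
    "VulnerabilityMap",
    "WET_PRINTED_THRESHOLDS",
    "DRY_PRINTED_THRESHOLDS",
    "derive_thresholds",
    "classify_vulnerable",
    "match_priority_tubes",
]

#: Published per-site criterion values (benthic % cover, N/P kg·yr⁻¹, wave kW·m⁻¹).
WET_PRINTED_THRESHOLDS = {
    "benthic": {"coral": 11.4, "macroalgae": 9.4, "turf": 50.0},
    "n_flux": 1322.7,
    "wave_power": 19860.0,
}
DRY_PRINTED_THRESHOLDS = {
    "benthic": {"coral": 18.4, "cca": 4.1, "turf": 44.4},
    "n_flux": 2940.8,
    "p_flux": 325.2,
}


@dataclass
class CriteriaConfig:
    """Threshold set and boolean structure of the vulnerability criteria.

    ``benthic_rule`` is a list of OR-groups that are ANDed, each group a list
    of indicator names compared against ``benthic_thresholds`` (cover strictly
    above threshold).  ``p_threshold`` / ``wave_threshold`` are None when that
    criterion is inactive at the site.
    """

    depth_max: float = 5.0  # m; cells shallower than this (depth >= -depth_max)
    benthic_thresholds: dict[str, float] = field(default_factory=dict)
    benthic_rule: list[list[str]] = field(default_factory=list)
    n_threshold: float | None = None
    p_threshold: float | None = None
    wave_threshold: float | None = None

    def __post_init__(self) -> None:
        active = sum(
            1 for v in (self.benthic_rule or None, self.n_threshold,
                        self.p_threshold, self.wave_threshold)
            if v is not None
        ) + 1  # depth criterion is always active
        if active < 2:
            raise ValueError("need at least two active criteria")


def _tercile(values: np.ndarray, upper: bool) -> float:
    v = values[np.isfinite(values)]
    if v.size == 0:
        raise ValueError("no valid cells to derive a tercile from")
    return float(np.percentile(v, 200.0 / 3.0 if upper else 100.0 / 3.0))


def derive_thresholds(
    predictions: dict[str, RasterGrid],
    n_flux: RasterGrid,
    wave_power: RasterGrid | None = None,
    p_flux: RasterGrid | None = None,
    benthic_rule: list[list[str]] | None = None,
    depth_max: float = 5.0,
    overrides: dict | None = None,
) -> CriteriaConfig:
    """Site criteria from the prediction maps and driver rasters.

    Benthic thresholds are the site means of the predicted cover maps;
    nutrient thresholds the upper tercile of the plume rasters; the wave
    threshold the lower tercile of wave power.  ``overrides`` (e.g. the
    published per-site values) replace any derived entry.
    """
    benthic_rule = benthic_rule or [[k] for k in predictions]
    thresholds = {
        name: float(np.nanmean(predictions[name].values))
        for group in benthic_rule for name in group
    }
    cfg = CriteriaConfig(
        depth_max=depth_max,
        benthic_thresholds=thresholds,
        benthic_rule=benthic_rule,
        n_threshold=_tercile(n_flux.values, upper=True),
        p_threshold=_tercile(p_flux.values, upper=True) if p_flux is not None else None,
        wave_threshold=_tercile(wave_power.values, upper=False) if wave_power is not None else None,
    )
    if overrides:
        cfg.benthic_thresholds.update(overrides.get("benthic", {}))
        for key, attr in (("n_flux", "n_threshold"), ("p_flux", "p_threshold"),
                          ("wave_power", "wave_threshold")):
            if key in overrides:
                setattr(cfg, attr, overrides[key])
    return cfg


@dataclass
class VulnerabilityMap:
    flags: RasterGrid          # 1 = vulnerable, 0 = not, NaN = outside reef
    criteria: CriteriaConfig
    tube_ranking: list[dict] = field(default_factory=list)


def classify_vulnerable(
    depth: RasterGrid,
    predictions: dict[str, RasterGrid],
    n_flux: RasterGrid,
    criteria: CriteriaConfig,
    wave_power: RasterGrid | None = None,
    p_flux: RasterGrid | None = None,
) -> VulnerabilityMap:
    """Flag reef cells where every active criterion is satisfied."""
    grids = [depth, n_flux] + list(predictions.values())
    if wave_power is not None:
        grids.append(wave_power)
    if p_flux is not None:
        grids.append(p_flux)
    require_registered(*grids)
    ok = depth.mask
    flag = depth.values >= -criteria.depth_max  # shallower than depth_max
    for group in criteria.benthic_rule:
        missing = [g for g in group if g not in predictions]
        if missing:
            raise KeyError(f"criterion references missing prediction layer(s): {missing}")
        group_any = np.zeros(depth.shape, dtype=bool)
        for name in group:
            group_any |= predictions[name].values > criteria.benthic_thresholds[name]
        flag &= group_any
    if criteria.n_threshold is not None:
        flag &= n_flux.values > criteria.n_threshold
    if criteria.p_threshold is not None:
        if p_flux is None:
            raise KeyError("P criterion active but no P flux layer given")
        flag &= p_flux.values > criteria.p_threshold
    if criteria.wave_threshold is not None:
        if wave_power is None:
            raise KeyError("wave criterion active but no wave power layer given")
        flag &= wave_power.values < criteria.wave_threshold
    out = np.where(ok, flag.astype(float), np.nan)
    return VulnerabilityMap(flags=depth.like(out, units="flag"), criteria=criteria)


def match_priority_tubes(
    vuln: VulnerabilityMap,
    tubes: list[FlowTube],
    per_tube_nutrient_plumes: np.ndarray,
) -> list[dict]:
    """Rank flow tubes upstream of the flagged reef cells.

    ``per_tube_nutrient_plumes`` is the (n_tubes, nrows, ncols) array of
    per-tube nutrient plume rasters retained by the plume stage.  Each
    flagged cell is attributed to the tube with the largest plume share
    there; tubes are ranked by (anthropogenic nutrient flux, flagged-cell
    count) descending, with tube id as a stable tiebreak.
    """
    flags = vuln.flags.values == 1.0
    ranking: list[dict] = []
    counts = np.zeros(len(tubes), dtype=int)
    if flags.any():
        plumes = np.nan_to_num(per_tube_nutrient_plumes[:, flags], nan=0.0)
        reached = plumes.sum(axis=0) > 0
        winner = np.argmax(plumes, axis=0)
        for k in range(len(tubes)):
            counts[k] = int(np.sum(reached & (winner == k)))
    else:
        logger.info("no flagged cells; empty priority ranking")
        return []
    for t, c in zip(tubes, counts):
        ranking.append({
            "tube_id": t.id,
            "flagged_cells": int(c),
            "anthropogenic_flux": t.n_flux_anthropogenic + t.p_flux_anthropogenic,
            "n_flux_anthropogenic": t.n_flux_anthropogenic,
            "p_flux_anthropogenic": t.p_flux_anthropogenic,
        })
    ranking = [r for r in ranking if r["flagged_cells"] > 0]
    ranking.sort(key=lambda r: (-r["anthropogenic_flux"], -r["flagged_cells"], r["tube_id"]))
    return ranking
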