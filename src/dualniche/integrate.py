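"""Minimum-rule suitability integration, binarization, and threshold
sensitivity.

A habitat is only as suitable as its least suitable requirement (the
"barrel effect"): the joint climate-soil suitability of a cell is the
cellwise minimum of the two surfaces, and an obligate parasite is further
capped by its host's suitability. Binary maps use the >= convention at
the threshold boundary throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import RasterGrid, require_coregistered


@dataclass
class BinaryMap:
    """0/1 suitability map plus the threshold and rule that produced it."""

    grid: RasterGrid
    threshold: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.valid_mask]
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("binary map must contain only 0/1 on valid cells")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def suitable(self) -> np.ndarray:
        return (self.grid.values == 1) & self.grid.valid_mask

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())


def min_overlay(surfaces: list[RasterGrid]) -> RasterGrid:
    """Cellwise minimum of co-registered suitability surfaces; nodata where
    any input is nodata."""
    if len(surfaces) < 2:
        raise ValueError("min_overlay needs at least 2 surfaces")
    require_coregistered(surfaces)
    vals = np.minimum.reduce([s.values for s in surfaces])
    mask = np.logical_or.reduce([s.nodata_mask for s in surfaces])
    vals = np.where(mask, 0, vals)
    return RasterGrid(vals, surfaces[0].geometry, nodata_mask=mask)


def host_constrained_suitability(parasite_climate: RasterGrid,
                                 parasite_soil: RasterGrid,
                                 host_final: RasterGrid) -> RasterGrid:
    """Parasite suitability capped by the least suitable of its climate, its
    soil, and host availability."""
    return min_overlay([parasite_climate, parasite_soil, host_final])


def binarize(surface: RasterGrid, threshold: float,
             provenance: dict | None = None) -> BinaryMap:
    """Suitable (1) where HSI >= threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    vals = (surface.values >= threshold).astype(np.int32)
    vals[surface.nodata_mask] = 0
    grid = RasterGrid(vals, surface.geometry, nodata_mask=surface.nodata_mask.copy(),
                      is_categorical=True)
    return BinaryMap(grid, threshold, provenance or {})


def co_suitable_map(binary_maps: list[BinaryMap]) -> BinaryMap:
    """Cellwise logical AND of binary maps — the dual-threshold co-suitable
    area, each constituent map binarized at its own species-specific
    threshold."""
    if len(binary_maps) < 2:
        raise ValueError("need at least 2 binary maps")
    require_coregistered([b.grid for b in binary_maps])
    vals = np.logical_and.reduce([b.grid.values.astype(bool) for b in binary_maps])
    mask = np.logical_or.reduce([b.grid.nodata_mask for b in binary_maps])
    out = np.where(mask, 0, vals.astype(np.int32))
    grid = RasterGrid(out, binary_maps[0].grid.geometry, nodata_mask=mask,
                      is_categorical=True)
    return BinaryMap(grid, min(b.threshold for b in binary_maps),
                     {"rule": "co_suitable_and",
                      "thresholds": [b.threshold for b in binary_maps]})


def threshold_sensitivity(surface: RasterGrid, threshold: float,
                          delta: float = 0.05,
                          region_mask: RasterGrid | None = None) -> pd.DataFrame:
    """Suitable area at t*(1-delta), t, t*(1+delta).

    Returns a table of threshold, suitable area (10^3 km^2, latitude-aware
    cell areas) and relative change vs the central threshold. Perturbed
    thresholds falling outside (0, 1) are clipped with a warning.
    """
    from .nichestats import suitable_area

    rows = []
    areas = {}
    for t in (threshold * (1 - delta), threshold, threshold * (1 + delta)):
        t_eff = t
        if not (0 < t_eff < 1):
            warnings.warn(f"perturbed threshold {t:.4f} outside (0,1); clipped")
            t_eff = min(max(t_eff, 1e-9), 1 - 1e-9)
        areas[t] = suitable_area(binarize(surface, t_eff), region_mask)
    base = areas[threshold]
    for t, a in areas.items():
        rows.append({"threshold": t, "area_1e3_km2": a,
                     "relative_change": (a - base) / base if base > 0 else np.nan})
    return pd.DataFrame(rows)
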