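"""Niche overlap (Schoener's D) and suitable-area accounting.

Schoener's D = 1 - (1/2) * sum_i |pX_i - pY_i| over shared grid cells,
ranging from 0 (fully separated niches) to 1 (identical niches). By
default the two habitat-suitability surfaces are normalised to unit sum
before comparison, which guarantees D stays in [0, 1]; raw mode applies
the formula to the HSI values directly and may leave that range (the
report flags it).

Areas use a spherical Earth: a cell of angular size cs degrees at row
latitude phi covers (pi/180 * R)^2 * cs^2 * cos(phi) km^2 with
R = 6371.0088 km, reported in 10^3 km^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import GeometryMismatchError, GridGeometry, RasterGrid
from .integrate import BinaryMap

EARTH_RADIUS_KM = 6371.0088

OVERLAP_BANDS = [
    (0.0, 0.2, "very low"),
    (0.2, 0.4, "low"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "high"),
    (0.8, 1.0, "very high"),
]


@dataclass
class OverlapReport:
    D: float
    category: str | None
    n_cells: int
    normalized: bool


def classify_overlap(D: float) -> str:
    """Band label for D: half-open intervals, the top band closed at 1."""
    if not (0 <= D <= 1):
        raise ValueError("D must lie in [0, 1]")
    for lo, hi, name in OVERLAP_BANDS:
        if lo <= D < hi:
            return name
    return OVERLAP_BANDS[-1][2]  # D == 1.0


def schoeners_d(surface_x: RasterGrid, surface_y: RasterGrid,
                normalize: bool = True) -> OverlapReport:
    """Schoener's D between two co-registered suitability surfaces over the
    cells valid in both."""
    if not surface_x.same_geometry(surface_y):
        raise GeometryMismatchError("surfaces are not co-registered")
    shared = surface_x.valid_mask & surface_y.valid_mask
    n = int(shared.sum())
    if n == 0:
        raise ValueError("no shared valid cells")
    px = surface_x.values[shared].astype(float)
    py = surface_y.values[shared].astype(float)
    if normalize:
        sx, sy = px.sum(), py.sum()
        if sx == 0 or sy == 0:
            raise ValueError("zero-sum surface: D undefined under normalization")
        px, py = px / sx, py / sy
    d = 1.0 - 0.5 * np.abs(px - py).sum()
    if normalize:
        d = float(min(max(d, 0.0), 1.0))  # guard float round-off only
        category = classify_overlap(d)
    else:
        d = float(d)
        category = classify_overlap(d) if 0 <= d <= 1 else None
    return OverlapReport(D=d, category=category, n_cells=n, normalized=normalize)


def cell_areas(geometry: GridGeometry) -> RasterGrid:
    """Per-cell area in km^2; constant along each row (latitude band)."""
    rows = np.arange(geometry.n_rows)
    lat_center = geometry.origin_lat - (rows + 0.5) * geometry.cell_size
    if np.any(np.abs(lat_center) > 90):
        raise ValueError("cell-centre latitude outside [-90, 90]")
    row_area = ((np.pi / 180.0 * EARTH_RADIUS_KM) ** 2
                * geometry.cell_size ** 2 * np.cos(np.radians(lat_center)))
    values = np.repeat(row_area[:, None], geometry.n_cols, axis=1)
    return RasterGrid(values, geometry)


def suitable_area(binary: BinaryMap, region_mask: RasterGrid | None = None) -> float:
    """Total suitable area in 10^3 km^2, optionally restricted to a region
    mask (nonzero = in region)."""
    areas = cell_areas(binary.grid.geometry)
    sel = binary.suitable
    if region_mask is not None:
        if not binary.grid.same_geometry(region_mask):
            raise GeometryMismatchError("region mask not co-registered")
        sel = sel & (region_mask.values != 0) & region_mask.valid_mask
    return float(areas.values[sel].sum() / 1000.0)


def area_change(current_area: float, future_area: float) -> float:
    """Percent reduction from current to future; negative = expansion."""
    if current_area <= 0:
        raise ValueError("current_area must be positive")
    return (current_area - future_area) / current_area * 100.0


def build_area_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a suitable-area table (species, scenario, region, area in
    10^3 km^2) and add percent change vs each species/region's 'current'
    row."""
    df = pd.DataFrame(rows)
    changes = []
    for _, r in df.iterrows():
        cur = df[(df["species"] == r["species"]) & (df["region"] == r["region"])
                 & (df["scenario"] == "current")]
        if len(cur) and cur["area_1e3_km2"].iloc[0] > 0 and r["scenario"] != "current":
            changes.append(area_change(cur["area_1e3_km2"].iloc[0], r["area_1e3_km2"]))
        else:
            changes.append(0.0 if r["scenario"] == "current" else np.nan)
    df["percent_change"] = changes
    return df
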