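"""Raster and occurrence-point plumbing shared by every pipeline stage.

Rasters live on a geographic (lon/lat, EPSG:4326-style) grid with square
cells. Cell (row, col) covers the half-open box
``[origin_lon + col*cs, origin_lon + (col+1)*cs)`` in longitude and
``(origin_lat - (row+1)*cs, origin_lat - row*cs]`` in latitude, so a point
lying exactly on a cell edge belongs to the lower-index cell. GeoTIFF I/O
goes through :mod:`tifffile` using the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

FLOAT_NODATA = -9999.0
INT_NODATA = np.iinfo(np.int32).min


class RasterFormatError(ValueError):
    """Raised for malformed raster files or missing georeferencing."""


class GeometryMismatchError(ValueError):
    """Raised when co-registered grids are required but geometries differ."""


@dataclass(frozen=True)
class GridGeometry:
    """Georeference of a regular lon/lat grid: upper-left corner and cell size."""

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Index of the cell containing (lon, lat); edge points go to the
        lower-index cell."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((self.origin_lat - lat) / self.cell_size))
        # top / left boundary belongs to row 0 / col 0
        if row == -1 and np.isclose(lat, self.origin_lat):
            row = 0
        if col == self.n_cols and np.isclose(
            lon, self.origin_lon + self.n_cols * self.cell_size
        ):
            col = self.n_cols - 1
        if row == self.n_rows and np.isclose(
            lat, self.origin_lat - self.n_rows * self.cell_size
        ):
            row = self.n_rows - 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside grid bounds")
        return row, col

    def cells_of(self, lons: np.ndarray, lats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised :meth:`cell_of` (no boundary snapping beyond floor)."""
        cols = np.floor((np.asarray(lons) - self.origin_lon) / self.cell_size).astype(int)
        rows = np.floor((self.origin_lat - np.asarray(lats)) / self.cell_size).astype(int)
        rows = np.where((rows == -1) & np.isclose(lats, self.origin_lat), 0, rows)
        if np.any((rows < 0) | (rows >= self.n_rows) | (cols < 0) | (cols >= self.n_cols)):
            raise ValueError("one or more points outside grid bounds")
        return rows, cols

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat


@dataclass
class RasterGrid:
    """A single georeferenced layer: values + nodata mask + geometry.

    ``nodata_mask`` is True where the cell carries no data. Continuous
    layers hold floats; categorical layers hold integer codes and are
    flagged ``is_categorical`` so that resampling uses nearest-neighbour.
    """

    values: np.ndarray
    geometry: GridGeometry
    nodata_mask: np.ndarray | None = None
    is_categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != self.geometry.shape:
            raise ValueError("values shape does not match geometry")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape does not match values")
        valid = self.values[~self.nodata_mask]
        if valid.size and np.issubdtype(self.values.dtype, np.floating):
            if not np.all(np.isfinite(valid)):
                raise ValueError("valid cells must hold finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, *, nodata_mask: np.ndarray | None = None,
                    is_categorical: bool | None = None) -> "RasterGrid":
        return RasterGrid(
            values=values,
            geometry=self.geometry,
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
            is_categorical=self.is_categorical if is_categorical is None else is_categorical,
        )

    def same_geometry(self, other: "RasterGrid") -> bool:
        g, h = self.geometry, other.geometry
        return (
            g.shape == h.shape
            and np.isclose(g.origin_lon, h.origin_lon)
            and np.isclose(g.origin_lat, h.origin_lat)
            and np.isclose(g.cell_size, h.cell_size)
        )


def require_coregistered(grids: Sequence[RasterGrid]) -> None:
    if not grids:
        raise ValueError("no grids supplied")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise GeometryMismatchError("grids are not co-registered")


@dataclass
class EnvStack:
    """Ordered, co-registered set of named environmental layers."""

    layers: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvStack requires at least one layer")
        require_coregistered(list(self.layers.values()))

    @property
    def geometry(self) -> GridGeometry:
        return next(iter(self.layers.values())).geometry

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def continuous_names(self) -> list[str]:
        return [n for n, g in self.layers.items() if not g.is_categorical]

    def combined_nodata(self) -> np.ndarray:
        """Union of the member nodata masks."""
        mask = np.zeros(self.geometry.shape, dtype=bool)
        for g in self.layers.values():
            mask |= g.nodata_mask
        return mask

    def subset(self, names: Sequence[str]) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names})

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers


@dataclass
class OccurrenceSet:
    """Labelled presence / pseudo-absence points in lon/lat degrees."""

    lon: np.ndarray
    lat: np.ndarray
    label: np.ndarray  # strings from {presence, pseudo_absence}
    species_id: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        self.species_id = np.asarray(self.species_id, dtype=object)
        n = len(self.lon)
        if not (len(self.lat) == len(self.label) == len(self.species_id) == n):
            raise ValueError("field lengths differ")
        bad = set(self.label) - {PRESENCE, PSEUDO_ABSENCE}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def __len__(self) -> int:
        return len(self.lon)

    @classmethod
    def from_records(cls, records: Iterable[tuple[float, float, str, str]]) -> "OccurrenceSet":
        recs = list(records)
        if not recs:
            return cls.empty()
        lon, lat, label, sp = zip(*recs)
        return cls(np.array(lon), np.array(lat), np.array(label, object), np.array(sp, object))

    @classmethod
    def empty(cls) -> "OccurrenceSet":
        z = np.empty(0)
        return cls(z, z.copy(), np.empty(0, object), np.empty(0, object))

    def presences(self) -> "OccurrenceSet":
        return self.select(self.label == PRESENCE)

    def select(self, mask: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.lon[mask], self.lat[mask], self.label[mask],
                             self.species_id[mask])

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(
            np.concatenate([self.lon, other.lon]),
            np.concatenate([self.lat, other.lat]),
            np.concatenate([self.label, other.label]),
            np.concatenate([self.species_id, other.species_id]),
        )

    def cell_indices(self, geometry: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
        if len(self) == 0:
            return np.empty(0, int), np.empty(0, int)
        return geometry.cells_of(self.lon, self.lat)


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(grid: RasterGrid, path) -> None:
    """Write a single-band GeoTIFF (float32 continuous / int32 categorical)."""
    if grid.is_categorical:
        nodata = INT_NODATA
        data = grid.values.astype(np.int32).copy()
    else:
        nodata = FLOAT_NODATA
        data = grid.values.astype(np.float32).copy()
    data[grid.nodata_mask] = nodata
    g = grid.geometry
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_lon, g.origin_lat, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_raster(path, *, is_categorical: bool | None = None) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    TIFF carrying ModelPixelScale/ModelTiepoint tags)."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = page.tags
            scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
            nodata_tag = tags.get(_TAG_GDAL_NODATA)
            scale = None if scale is None else tuple(scale.value)
            tiepoint = None if tiepoint is None else tuple(tiepoint.value)
            nodata_tag = None if nodata_tag is None else str(nodata_tag.value)
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise RasterFormatError(f"cannot read raster {path!r}: {exc}") from exc
    if data.ndim != 2:
        raise RasterFormatError("expected a single-band raster")
    if scale is None or tiepoint is None:
        raise RasterFormatError("missing GeoTIFF georeferencing tags")
    cs = float(scale[0])
    _, _, _, origin_lon, origin_lat, _ = tiepoint[:6]
    categorical = np.issubdtype(data.dtype, np.integer) if is_categorical is None else is_categorical
    if nodata_tag is not None:
        nodata = float(nodata_tag)
        mask = data == (int(nodata) if np.issubdtype(data.dtype, np.integer) else np.float32(nodata))
    else:
        mask = ~np.isfinite(data) if np.issubdtype(data.dtype, np.floating) else np.zeros(data.shape, bool)
    geometry = GridGeometry(data.shape[0], data.shape[1], float(origin_lon),
                            float(origin_lat), cs)
    clean = data.astype(np.int32 if categorical else np.float64)
    clean[mask] = 0
    return RasterGrid(clean, geometry, nodata_mask=mask, is_categorical=categorical)


def write_occurrences(points: OccurrenceSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species_id", "lon", "lat", "label"])
        for i in range(len(points)):
            w.writerow([points.species_id[i], f"{points.lon[i]:.10f}",
                        f"{points.lat[i]:.10f}", points.label[i]])


def read_occurrences(path) -> OccurrenceSet:
    df = pd.read_csv(path)
    required = {"species_id", "lon", "lat", "label"}
    if not required.issubset(df.columns):
        raise RasterFormatError(f"occurrence CSV must have columns {sorted(required)}")
    return OccurrenceSet(df["lon"].to_numpy(float), df["lat"].to_numpy(float),
                         df["label"].to_numpy(object), df["species_id"].to_numpy(object))


# ---------------------------------------------------------------------------
# Alignment, thinning, extraction


def align_stack(layers: dict[str, RasterGrid], target: GridGeometry) -> EnvStack:
    """Resample named layers onto ``target``: bilinear for continuous layers,
    nearest-neighbour for categorical ones. A target cell becomes nodata if
    any source cell contributing to its value is nodata, or if its centre
    falls outside the source extent."""
    if not layers:
        raise ValueError("empty layer list")
    out: dict[str, RasterGrid] = {}
    for name, grid in layers.items():
        out[name] = _align_one(grid, target)
    return EnvStack(out)


def _align_one(grid: RasterGrid, target: GridGeometry) -> RasterGrid:
    g = grid.geometry
    if (g.shape == target.shape and np.isclose(g.origin_lon, target.origin_lon)
            and np.isclose(g.origin_lat, target.origin_lat)
            and np.isclose(g.cell_size, target.cell_size)):
        return RasterGrid(grid.values.copy(), target, grid.nodata_mask.copy(),
                          grid.is_categorical)
    rows = np.arange(target.n_rows)
    cols = np.arange(target.n_cols)
    lon, lat = np.meshgrid(
        target.origin_lon + (cols + 0.5) * target.cell_size,
        target.origin_lat - (rows + 0.5) * target.cell_size,
    )
    # fractional source indices of the target cell centres
    fc = (lon - g.origin_lon) / g.cell_size - 0.5
    fr = (g.origin_lat - lat) / g.cell_size - 0.5
    outside = (fr < -0.5) | (fr > g.n_rows - 0.5) | (fc < -0.5) | (fc > g.n_cols - 0.5)
    coords = np.stack([fr.ravel(), fc.ravel()])
    order = 0 if grid.is_categorical else 1
    vals = ndimage.map_coordinates(grid.values.astype(float), coords, order=order,
                                   mode="nearest").reshape(target.shape)
    touched = ndimage.map_coordinates(grid.nodata_mask.astype(float), coords,
                                      order=order, mode="nearest").reshape(target.shape)
    mask = outside | (touched > 0)
    if grid.is_categorical:
        vals = np.round(vals).astype(np.int32)
    vals = np.where(mask, 0, vals)
    if np.all(mask):
        raise GeometryMismatchError("no overlap between layer and target geometry")
    return RasterGrid(vals, target, nodata_mask=mask, is_categorical=grid.is_categorical)


def thin_occurrences(points: OccurrenceSet, geometry: GridGeometry, seed: int) -> OccurrenceSet:
    """Keep at most one record per grid cell, chosen uniformly at random
    within each multiply-occupied cell (seeded). Idempotent."""
    if len(points) == 0:
        return points
    rows, cols = points.cell_indices(geometry)
    cell_key = rows * geometry.n_cols + cols
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for key in np.unique(cell_key):
        idx = np.flatnonzero(cell_key == key)
        keep.append(int(idx[rng.integers(len(idx))]) if len(idx) > 1 else int(idx[0]))
    keep.sort()
    return points.select(np.isin(np.arange(len(points)), keep))


def extract_env(points: OccurrenceSet, stack: EnvStack) -> tuple[pd.DataFrame, int]:
    """Sample every layer at the cell containing each point.

    Returns (table, n_dropped): one row per point falling on a valid cell,
    columns = layer names plus lon/lat/label/species_id/row/col; points on
    nodata cells are dropped and counted.
    """
    geometry = stack.geometry
    rows, cols = points.cell_indices(geometry)
    nodata = stack.combined_nodata()
    on_valid = ~nodata[rows, cols]
    n_dropped = int((~on_valid).sum())
    if not on_valid.any():
        raise ValueError("all points fall on nodata cells")
    r, c = rows[on_valid], cols[on_valid]
    data = {name: grid.values[r, c] for name, grid in stack.layers.items()}
    df = pd.DataFrame(data)
    df["lon"] = points.lon[on_valid]
    df["lat"] = points.lat[on_valid]
    df["label"] = points.label[on_valid]
    df["species_id"] = points.species_id[on_valid]
    df["row"] = r
    df["col"] = c
    return df, n_dropped
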