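"""Synthetic desert landscapes with known truth suitability.

Stands in for real bioclim/soil raster downloads: spatially autocorrelated
continuous climate fields, a clumped categorical soil-type field, a
continuous available-water-capacity (AWC) layer, and a host-nested
parasite truth. Truth composition follows the minimum-suitability
("barrel effect") rule: the final suitability of a cell is the least of
its component suitabilities, and the parasite is additionally capped by
host suitability (obligate parasitism).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .geodata import EnvStack, GridGeometry, OccurrenceSet, RasterGrid, PRESENCE

SOIL_CLASS_LAYER = "soil_class"
AWC_LAYER = "awc"


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(z / np.sqrt(2.0)))


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Defaults describe a 100x100-cell arid landscape with four climate
    fields (one dominant driver), six clumped soil units, and a unimodal
    AWC response peaking at moderate water capacity — the regime the
    host/parasite pair occupies.
    """

    n_rows: int = 100
    n_cols: int = 100
    autocorr_length: float = 6.0
    n_climate: int = 4
    n_soil_classes: int = 6
    climate_intercept: float = -2.0
    climate_effects: tuple[float, ...] = (2.0, -1.2, 0.8, 0.0)
    parasite_climate_effects: tuple[float, ...] | None = None
    soil_class_suitability: tuple[float, ...] = (0.95, 0.85, 0.6, 0.4, 0.2, 0.1)
    awc_optimum: float = 0.6
    awc_width: float = 0.25
    origin_lon: float = 80.0
    origin_lat: float = 48.0
    cell_size: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.n_climate <= 0:
            raise ValueError("counts must be positive")
        if self.n_soil_classes <= 0:
            raise ValueError("n_soil_classes must be positive")
        if len(self.climate_effects) != self.n_climate:
            raise ValueError("climate_effects length must equal n_climate")
        if self.parasite_climate_effects is not None and len(
                self.parasite_climate_effects) != self.n_climate:
            raise ValueError("parasite_climate_effects length must equal n_climate")
        if len(self.soil_class_suitability) != self.n_soil_classes:
            raise ValueError("soil_class_suitability length must equal n_soil_classes")
        if not all(0 <= s <= 1 for s in self.soil_class_suitability):
            raise ValueError("soil_class_suitability values must lie in [0, 1]")
        if self.awc_width <= 0:
            raise ValueError("awc_width must be positive")

    def resolved_parasite_effects(self) -> np.ndarray:
        """Parasite climate coefficients: shifted relative to the host so the
        two niches overlap but differ (half the host vector blended with a
        rotation of it)."""
        if self.parasite_climate_effects is not None:
            return np.asarray(self.parasite_climate_effects, float)
        host = np.asarray(self.climate_effects, float)
        return 0.6 * host + 0.4 * np.roll(host, 1)


@dataclass
class TruthSet:
    """Known suitability surfaces the generator composed the landscape from."""

    climate_truth_host: RasterGrid
    soil_truth_host: RasterGrid
    climate_truth_parasite: RasterGrid
    soil_truth_parasite: RasterGrid
    host_final_truth: RasterGrid
    parasite_final_truth: RasterGrid


def _gaussian_field(rng: np.random.Generator, shape: tuple[int, int],
                    sigma: float) -> np.ndarray:
    """Smoothed white noise standardised to mean 0, sd 1."""
    noise = rng.standard_normal(shape)
    fld = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    return (fld - fld.mean()) / fld.std()


def _clumped_classes(rng: np.random.Generator, shape: tuple[int, int],
                     n_classes: int) -> np.ndarray:
    """Voronoi tessellation of seeded points, codes cycling over classes,
    giving contiguous soil units. Soil units are mapped at much finer
    spatial grain than climatic gradients (as in harmonized soil
    databases), so every class intersects a range of climates."""
    n_seeds = max(12 * n_classes, 24)
    sr = rng.uniform(0, shape[0], n_seeds)
    sc = rng.uniform(0, shape[1], n_seeds)
    codes = np.arange(n_seeds) % n_classes
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
    return codes[np.argmin(d2, axis=-1)].astype(np.int32)


def generate_landscape(config: LandscapeConfig) -> tuple[EnvStack, TruthSet]:
    """Build the predictor stack and its truth surfaces.

    Climate layers ``clim1..n`` are standardised Gaussian random fields;
    ``soil_class`` is a clumped integer field; ``awc`` is a smoothed field
    rescaled to [0, 1]. Truths: climate suitability is the logistic of the
    linear combination of climate layers; soil suitability multiplies the
    per-class base value by a Gaussian response in AWC; finals are cellwise
    minima, the parasite additionally capped by the host's final truth.
    """
    rng = np.random.default_rng(config.seed)
    geometry = GridGeometry(config.n_rows, config.n_cols, config.origin_lon,
                            config.origin_lat, config.cell_size)
    shape = geometry.shape

    climate = [_gaussian_field(rng, shape, config.autocorr_length)
               for _ in range(config.n_climate)]
    soil_codes = _clumped_classes(rng, shape, config.n_soil_classes)
    awc_raw = _gaussian_field(rng, shape, config.autocorr_length)
    awc = _norm_cdf(awc_raw)  # uniform [0,1] marginal

    layers: dict[str, RasterGrid] = {}
    for i, fld in enumerate(climate, start=1):
        layers[f"clim{i}"] = RasterGrid(fld, geometry)
    layers[SOIL_CLASS_LAYER] = RasterGrid(soil_codes, geometry, is_categorical=True)
    layers[AWC_LAYER] = RasterGrid(awc, geometry)
    stack = EnvStack(layers)

    host_eff = np.asarray(config.climate_effects, float)
    par_eff = config.resolved_parasite_effects()
    clim_stack = np.stack(climate)
    climate_host = _logistic(config.climate_intercept
                             + np.tensordot(host_eff, clim_stack, axes=1))
    climate_par = _logistic(config.climate_intercept
                            + np.tensordot(par_eff, clim_stack, axes=1))

    class_suit = np.asarray(config.soil_class_suitability, float)[soil_codes]
    awc_resp = np.exp(-((awc - config.awc_optimum) ** 2) / (2 * config.awc_width ** 2))
    soil_truth = class_suit * awc_resp

    host_final = np.minimum(climate_host, soil_truth)
    parasite_final = np.minimum.reduce([climate_par, soil_truth, host_final])

    def surf(v: np.ndarray) -> RasterGrid:
        return RasterGrid(v, geometry)

    truth = TruthSet(
        climate_truth_host=surf(climate_host),
        soil_truth_host=surf(soil_truth),
        climate_truth_parasite=surf(climate_par),
        soil_truth_parasite=surf(soil_truth.copy()),
        host_final_truth=surf(host_final),
        parasite_final_truth=surf(parasite_final),
    )
    return stack, truth


def sample_occurrences(truth: RasterGrid, n_target: int, seed: int,
                       species_id: str = "species") -> OccurrenceSet:
    """Draw presence points with per-cell acceptance probability equal to the
    truth habitat-suitability index, jittering coordinates uniformly within
    the accepted cell."""
    if n_target == 0:
        return OccurrenceSet.empty()
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    valid_rows, valid_cols = np.nonzero(truth.valid_mask)
    if valid_rows.size == 0:
        raise ValueError("truth surface has no valid cells")
    probs = truth.values[valid_rows, valid_cols].astype(float)
    if probs.max() <= 0:
        raise ValueError("truth suitability is identically zero; sampling impossible")
    rng = np.random.default_rng(seed)
    g = truth.geometry
    out_r: list[np.ndarray] = []
    out_c: list[np.ndarray] = []
    accepted = 0
    while accepted < n_target:
        batch = max(4 * (n_target - accepted), 64)
        pick = rng.integers(0, valid_rows.size, batch)
        keep = rng.random(batch) < probs[pick]
        r, c = valid_rows[pick[keep]], valid_cols[pick[keep]]
        if r.size > n_target - accepted:
            r, c = r[: n_target - accepted], c[: n_target - accepted]
        out_r.append(r)
        out_c.append(c)
        accepted += r.size
    rows = np.concatenate(out_r)
    cols = np.concatenate(out_c)
    # jitter kept strictly interior so the point indexes back to its cell
    lon = g.origin_lon + (cols + rng.uniform(0.01, 0.99, n_target)) * g.cell_size
    lat = g.origin_lat - (rows + rng.uniform(0.01, 0.99, n_target)) * g.cell_size
    return OccurrenceSet(lon, lat, np.full(n_target, PRESENCE, object),
                         np.full(n_target, species_id, object))
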