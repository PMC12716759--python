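"""End-to-end orchestration: dual climate/soil niche models for a host
species and its obligate parasite, future-scenario projection, and
area/overlap reporting.

Per species the flow is: thin occurrences -> collinearity screen ->
repeated spatially blocked iterations (balanced dual-filtered
pseudo-absences, 4-member ensemble fit, validation metrics, optimal
thresholds) -> mean climate and soil surfaces -> minimum-rule dual
surface -> binarization at the mean optimal thresholds. The parasite's
final suitability is additionally capped by the host's dual surface.

Future scenarios are additive shifts to the standardized climate layers;
soil layers are held static and the already-fitted ensembles re-predict
(no re-training, since future occurrences cannot exist). Thresholds
derived from the current period are applied to future maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import (ModelConfig, PseudoAbsenceSettings, RunResult,
                       default_model_configs, run_iterations)
from .geodata import EnvStack, OccurrenceSet, RasterGrid, thin_occurrences, extract_env
from .integrate import BinaryMap, binarize, co_suitable_map, min_overlay
from .nichestats import build_area_table, schoeners_d, suitable_area
from .spatialcv import make_blocks, split_blocks
from .synthland import AWC_LAYER, SOIL_CLASS_LAYER
from .varselect import correlation_filter


@dataclass
class ScenarioConfig:
    """A named climate scenario as additive deltas on standardized climate
    layers; soil is held fixed. The 'current' scenario has zero shifts."""

    name: str
    climate_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name == "current" and any(v != 0 for v in self.climate_shift.values()):
            raise ValueError("'current' scenario must have zero shifts")


def apply_scenario(stack: EnvStack, scenario: ScenarioConfig) -> EnvStack:
    """Shift the named climate layers; everything else is shared unchanged."""
    layers = {}
    for name, grid in stack.layers.items():
        if name in scenario.climate_shift:
            shifted = grid.values + scenario.climate_shift[name]
            layers[name] = grid.with_values(np.where(grid.nodata_mask, 0, shifted))
        else:
            layers[name] = grid
    return EnvStack(layers)


def default_scenarios(climate_names: list[str]) -> list[ScenarioConfig]:
    """Current plus three increasingly severe warming/drying shifts applied
    to the first two climate layers (in standardized units)."""
    a, b = climate_names[0], climate_names[1] if len(climate_names) > 1 else climate_names[0]
    return [
        ScenarioConfig("current"),
        ScenarioConfig("SSP126", {a: -0.4, b: 0.3}),
        ScenarioConfig("SSP245", {a: -0.7, b: 0.5}),
        ScenarioConfig("SSP585", {a: -1.2, b: 0.9}),
    ]


def default_region_masks(geometry) -> dict[str, RasterGrid]:
    """Three nested rectangular regions exercising regional accounting."""
    full = np.ones(geometry.shape, dtype=np.int32)
    inner = np.zeros_like(full)
    r2, c2 = geometry.n_rows // 2, geometry.n_cols // 2
    inner[geometry.n_rows // 8: geometry.n_rows - geometry.n_rows // 8,
          geometry.n_cols // 8: geometry.n_cols - geometry.n_cols // 8] = 1
    core = np.zeros_like(full)
    core[r2 - geometry.n_rows // 4: r2 + geometry.n_rows // 4,
         c2 - geometry.n_cols // 4: c2 + geometry.n_cols // 4] = 1
    return {
        "world": RasterGrid(full, geometry, is_categorical=True),
        "mainland": RasterGrid(inner, geometry, is_categorical=True),
        "core": RasterGrid(core, geometry, is_categorical=True),
    }


@dataclass
class SpeciesArtifacts:
    """Everything a single-species run produces."""

    species: str
    climate_run: RunResult
    soil_run: RunResult
    climate_surface: RasterGrid
    soil_surface: RasterGrid
    dual_surface: RasterGrid
    climate_threshold: float
    soil_threshold: float
    climate_binary: BinaryMap
    soil_binary: BinaryMap
    dual_binary: BinaryMap
    kept_climate_features: list[str]
    n_presences: int


def _stack_checksum(stack: EnvStack) -> float:
    return float(sum(np.nansum(g.values.astype(float)) for g in stack.layers.values()))


def run_species(stack: EnvStack, occurrences: OccurrenceSet, species: str,
                climate_features: list[str], soil_features: list[str],
                *, n_iterations: int = 10, block_size: int | None = None,
                seed: int = 0, configs: list[ModelConfig] | None = None,
                pa_settings: PseudoAbsenceSettings | None = None,
                corr_threshold: float = 0.8,
                host_dual_surface: RasterGrid | None = None,
                host_threshold: float | None = None) -> SpeciesArtifacts:
    """Full single-species run. For a parasite, pass the host's dual surface
    (and threshold) to cap the final suitability by host availability."""
    geometry = stack.geometry
    checksum = _stack_checksum(stack)
    presences = thin_occurrences(occurrences.presences(), geometry, seed)

    # collinearity screen on the presence environment (continuous climate only)
    table, _ = extract_env(presences, stack.subset(climate_features))
    continuous = [n for n in climate_features if not stack[n].is_categorical]
    report = correlation_filter(table[continuous], threshold=corr_threshold)
    kept_climate = [n for n in climate_features
                    if n in report.kept or stack[n].is_categorical]

    if block_size is None:
        block_size = max(min(geometry.n_rows, geometry.n_cols) // 5, 2)
    blocks = make_blocks(geometry, block_size)
    configs = configs or default_model_configs(seed)
    pa_settings = pa_settings or PseudoAbsenceSettings()

    # one balanced presence/pseudo-absence set per iteration (eligibility
    # assessed over the full environmental space); the climate and soil
    # ensembles are fitted on their feature subsets of the same points
    plan = split_blocks(blocks, n_iterations=n_iterations, seed=seed + 11)
    runs = run_iterations(stack, presences, plan, configs,
                          {"climate": kept_climate, "soil": soil_features},
                          pa_settings, seed=seed + 13)
    climate_run, soil_run = runs["climate"], runs["soil"]

    climate_surface = climate_run.mean_surface
    soil_surface = soil_run.mean_surface
    parts = [climate_surface, soil_surface]
    if host_dual_surface is not None:
        parts.append(host_dual_surface)
    dual_surface = min_overlay(parts)

    thr_c = climate_run.mean_threshold
    thr_s = soil_run.mean_threshold
    climate_binary = binarize(climate_surface, thr_c, {"model": "climate"})
    soil_binary = binarize(soil_surface, thr_s, {"model": "soil"})
    bins = [climate_binary, soil_binary]
    if host_dual_surface is not None and host_threshold is not None:
        bins.append(binarize(host_dual_surface, host_threshold, {"model": "host_dual"}))
    dual_binary = co_suitable_map(bins)

    if not np.isclose(_stack_checksum(stack), checksum):
        raise RuntimeError("pipeline stage mutated its input stack")

    return SpeciesArtifacts(
        species=species, climate_run=climate_run, soil_run=soil_run,
        climate_surface=climate_surface, soil_surface=soil_surface,
        dual_surface=dual_surface, climate_threshold=thr_c, soil_threshold=thr_s,
        climate_binary=climate_binary, soil_binary=soil_binary,
        dual_binary=dual_binary, kept_climate_features=kept_climate,
        n_presences=len(presences),
    )


def _scenario_surface(run: RunResult, stack: EnvStack, features: list[str]) -> RasterGrid:
    """Mean re-prediction of all fitted per-iteration ensembles on a
    (possibly shifted) stack."""
    from .ensemble import predict_surface

    acc = None
    for it in run.iterations:
        s = predict_surface(it.ensemble, stack, features)
        acc = s.values.copy() if acc is None else acc + s.values
    vals = acc / len(run.iterations)
    mask = stack.subset(features).combined_nodata()
    return RasterGrid(np.where(mask, 0, vals), stack.geometry, nodata_mask=mask)


def run_scenarios(stack: EnvStack, host: SpeciesArtifacts,
                  parasite: SpeciesArtifacts | None,
                  scenarios: list[ScenarioConfig],
                  region_masks: dict[str, RasterGrid] | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project every scenario with the already-fitted ensembles.

    Returns (area table, overlap table). Areas are binarized at the
    current-period thresholds; overlaps are the three Schoener's D values
    per scenario: host climate vs soil, parasite final vs host final, and
    parasite climate vs soil.
    """
    region_masks = region_masks or default_region_masks(stack.geometry)
    area_rows: list[dict] = []
    overlap_rows: list[dict] = []
    for scen in scenarios:
        shifted = apply_scenario(stack, scen)
        if scen.name == "current":
            h_clim = host.climate_surface
            p_clim = parasite.climate_surface if parasite else None
        else:
            h_clim = _scenario_surface(host.climate_run, shifted,
                                       host.kept_climate_features)
            p_clim = (_scenario_surface(parasite.climate_run, shifted,
                                        parasite.kept_climate_features)
                      if parasite else None)
        h_dual = min_overlay([h_clim, host.soil_surface])
        h_bin = co_suitable_map([
            binarize(h_clim, host.climate_threshold),
            binarize(host.soil_surface, host.soil_threshold),
        ])
        for region, mask in region_masks.items():
            area_rows.append({"species": host.species, "scenario": scen.name,
                              "region": region,
                              "area_1e3_km2": suitable_area(h_bin, mask)})
        overlap_rows.append({
            "scenario": scen.name, "pair": f"{host.species} climate-soil",
            "D": schoeners_d(h_clim, host.soil_surface).D})

        if parasite is not None:
            p_dual = min_overlay([p_clim, parasite.soil_surface, h_dual])
            p_bin = co_suitable_map([
                binarize(p_clim, parasite.climate_threshold),
                binarize(parasite.soil_surface, parasite.soil_threshold),
                h_bin,
            ])
            for region, mask in region_masks.items():
                area_rows.append({"species": parasite.species, "scenario": scen.name,
                                  "region": region,
                                  "area_1e3_km2": suitable_area(p_bin, mask)})
            overlap_rows.append({
                "scenario": scen.name,
                "pair": f"{parasite.species} climate-{host.species}",
                "D": schoeners_d(p_clim, h_dual).D})
            overlap_rows.append({
                "scenario": scen.name, "pair": f"{parasite.species} climate-soil",
                "D": schoeners_d(p_clim, parasite.soil_surface).D})

    return build_area_table(area_rows), pd.DataFrame(overlap_rows)
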