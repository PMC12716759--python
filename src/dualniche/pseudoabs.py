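"""Dual-filtered pseudo-absence generation.

Pseudo-absences contrast presence records when true absences are
unavailable. Random background sampling risks labelling genuinely
suitable cells as absent, so eligibility is restricted by two filters
applied jointly:

* an environmental-profile filter — cells whose continuous-layer values
  all fall inside the presence envelope (between the presence quantiles)
  are too similar to presences and are excluded;
* a K-means filter — the landscape is clustered in standardised
  environmental space over several seeded runs; cells are eligible when a
  majority of runs place them in a presence-poor cluster.

Sampling then draws uniformly without replacement from the intersection
of the masks, optionally balanced per spatial block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .geodata import (EnvStack, OccurrenceSet, RasterGrid, PSEUDO_ABSENCE,
                      require_coregistered)


@dataclass
class EligibilityMask:
    """Boolean eligibility grid plus the parameters that produced it."""

    mask: RasterGrid  # values: bool, True = eligible
    provenance: dict = field(default_factory=dict)

    @property
    def eligible(self) -> np.ndarray:
        return self.mask.values.astype(bool) & self.mask.valid_mask

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())


def _presence_cells(stack: EnvStack, presences: OccurrenceSet) -> np.ndarray:
    occupied = np.zeros(stack.geometry.shape, dtype=bool)
    if len(presences):
        r, c = presences.cell_indices(stack.geometry)
        occupied[r, c] = True
    return occupied


def _standardized_matrix(stack: EnvStack) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(n_valid, n_continuous_layers) z-scored matrix over valid cells,
    plus the valid mask. Categorical layers are excluded."""
    names = stack.continuous_names()
    if not names:
        raise ValueError("no continuous layers to work in")
    valid = ~stack.combined_nodata()
    cols = []
    for n in names:
        v = stack[n].values[valid].astype(float)
        sd = v.std()
        if np.isclose(sd, 0):
            raise ValueError(f"layer {n!r} is constant over valid cells")
        cols.append((v - v.mean()) / sd)
    return np.column_stack(cols), valid, names


def environmental_profile_mask(stack: EnvStack, presences: OccurrenceSet,
                               envelope_quantiles: tuple[float, float] = (0.05, 0.95),
                               ) -> EligibilityMask:
    """Cells environmentally similar to presences (inside the presence
    [q_low, q_high] envelope on EVERY continuous layer) are ineligible;
    everything else valid and unoccupied is eligible."""
    if len(presences) < 5:
        raise ValueError("need at least 5 presences to profile the envelope")
    q_low, q_high = envelope_quantiles
    valid = ~stack.combined_nodata()
    pr, pc = presences.cell_indices(stack.geometry)
    inside_all = np.ones(stack.geometry.shape, dtype=bool)
    for name in stack.continuous_names():
        vals = stack[name].values
        pvals = vals[pr, pc].astype(float)
        lo, hi = np.quantile(pvals, [q_low, q_high])
        inside_all &= (vals >= lo) & (vals <= hi)
    eligible = valid & ~inside_all & ~_presence_cells(stack, presences)
    if not eligible.any():
        raise ValueError("no eligible cells: presence envelope covers the "
                         "whole landscape; widen it or the landscape")
    grid = RasterGrid(eligible.astype(np.int32), stack.geometry,
                      nodata_mask=~valid, is_categorical=True)
    return EligibilityMask(grid, provenance={
        "filter": "environmental_profile", "envelope_quantiles": envelope_quantiles})


def kmeans_eligibility(stack: EnvStack, presences: OccurrenceSet, k: int = 8,
                       runs: int = 5, presence_poor_quantile: float = 0.25,
                       seed: int = 0) -> EligibilityMask:
    """Majority vote over seeded K-means runs: per run, flag the clusters in
    the lowest ``presence_poor_quantile`` of presence density (presences per
    member cell); a cell is eligible when flagged in more than half of the
    runs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    X, valid, _ = _standardized_matrix(stack)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of valid cells")
    pr, pc = presences.cell_indices(stack.geometry)
    # map presence cells to their row position within the valid-cell vector
    flat_index = np.full(stack.geometry.shape, -1, dtype=int)
    flat_index[valid] = np.arange(X.shape[0])
    pres_pos = flat_index[pr, pc]
    pres_pos = pres_pos[pres_pos >= 0]

    rng = np.random.default_rng(seed)
    votes = np.zeros(X.shape[0], dtype=int)
    for _ in range(runs):
        km = KMeans(n_clusters=k, n_init=1,
                    random_state=int(rng.integers(2**31 - 1))).fit(X)
        labels = km.labels_
        sizes = np.bincount(labels, minlength=k)
        pres_counts = np.bincount(labels[pres_pos], minlength=k)
        density = pres_counts / np.maximum(sizes, 1)
        cut = np.quantile(density, presence_poor_quantile)
        flagged = density <= cut
        votes += flagged[labels]
    eligible_flat = votes > runs / 2
    eligible = np.zeros(stack.geometry.shape, dtype=bool)
    eligible[valid] = eligible_flat
    eligible &= ~_presence_cells(stack, presences)
    grid = RasterGrid(eligible.astype(np.int32), stack.geometry,
                      nodata_mask=~valid, is_categorical=True)
    return EligibilityMask(grid, provenance={
        "filter": "kmeans", "k": k, "runs": runs,
        "presence_poor_quantile": presence_poor_quantile, "seed": seed})


def sample_pseudo_absences(masks: list[EligibilityMask], n, seed: int,
                           block_ids: RasterGrid | None = None,
                           restrict_blocks=None,
                           species_id: str = "species") -> OccurrenceSet:
    """Sample pseudo-absence points uniformly without replacement from the
    intersection of the eligibility masks.

    ``n`` is either a total count, or — with ``block_ids`` supplied — a
    mapping {block_id: count} to balance pseudo-absences against presences
    per spatial block. With an integer ``n`` and ``restrict_blocks`` (an
    iterable of block ids, requires ``block_ids``), sampling is confined to
    the union of those blocks — the partition-level balanced draw used by
    spatial cross-validation.
    """
    if not masks:
        raise ValueError("at least one mask required")
    require_coregistered([m.mask for m in masks])
    inter = masks[0].eligible.copy()
    for m in masks[1:]:
        inter &= m.eligible
    geometry = masks[0].mask.geometry
    rng = np.random.default_rng(seed)

    def draw(cells_r, cells_c, count):
        if count > cells_r.size:
            raise ValueError(
                f"insufficient eligible cells: need {count}, have {cells_r.size}")
        pick = rng.choice(cells_r.size, size=count, replace=False)
        return cells_r[pick], cells_c[pick]

    if block_ids is not None and isinstance(n, dict):
        require_coregistered([masks[0].mask, block_ids])
        rows, cols = [], []
        for bid in sorted(n):
            in_block = inter & (block_ids.values == bid)
            br, bc = np.nonzero(in_block)
            r, c = draw(br, bc, n[bid])
            rows.append(r)
            cols.append(c)
        rows = np.concatenate(rows) if rows else np.empty(0, int)
        cols = np.concatenate(cols) if cols else np.empty(0, int)
    else:
        if not isinstance(n, (int, np.integer)) or n < 1:
            raise ValueError("n must be a positive integer (or a per-block dict)")
        pool = inter
        if restrict_blocks is not None:
            if block_ids is None:
                raise ValueError("restrict_blocks requires block_ids")
            require_coregistered([masks[0].mask, block_ids])
            pool = inter & np.isin(block_ids.values, np.asarray(list(restrict_blocks)))
        ir, ic = np.nonzero(pool)
        rows, cols = draw(ir, ic, int(n))

    total = rows.size
    lon = geometry.origin_lon + (cols + rng.uniform(0.01, 0.99, total)) * geometry.cell_size
    lat = geometry.origin_lat - (rows + rng.uniform(0.01, 0.99, total)) * geometry.cell_size
    return OccurrenceSet(lon, lat, np.full(total, PSEUDO_ABSENCE, object),
                         np.full(total, species_id, object))
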