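"""Contiguous spatial-block partitioning and repeated 70/30 block splits.

Splitting train/validation at the level of contiguous map blocks (rather
than individual points) blunts spatial autocorrelation: nearby, nearly
duplicate cells cannot straddle the partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geodata import GridGeometry, RasterGrid


@dataclass
class CVIteration:
    train_blocks: np.ndarray
    valid_blocks: np.ndarray
    seed: int


@dataclass
class CVPlan:
    block_ids: RasterGrid
    iterations: list[CVIteration]

    def to_dict(self) -> dict:
        return {
            "n_blocks": int(self.block_ids.values.max()) + 1,
            "iterations": [
                {"train": it.train_blocks.tolist(), "valid": it.valid_blocks.tolist(),
                 "seed": it.seed}
                for it in self.iterations
            ],
        }


def make_blocks(geometry: GridGeometry, block_size_cells: int) -> RasterGrid:
    """Regular tiling into square blocks of ``block_size_cells`` per side
    (edge blocks may be smaller); ids row-major from 0."""
    if block_size_cells < 1:
        raise ValueError("block_size_cells must be >= 1")
    if block_size_cells >= max(geometry.n_rows, geometry.n_cols):
        warnings.warn("block size spans the whole grid; a single block results")
    rows = np.arange(geometry.n_rows)[:, None] // block_size_cells
    cols = np.arange(geometry.n_cols)[None, :] // block_size_cells
    n_block_cols = -(-geometry.n_cols // block_size_cells)
    ids = rows * n_block_cols + cols
    return RasterGrid(ids.astype(np.int32), geometry, is_categorical=True)


def split_blocks(block_ids: RasterGrid, train_frac: float = 0.7,
                 n_iterations: int = 10, seed: int = 0) -> CVPlan:
    """Per iteration, a fresh seeded permutation allocates round(train_frac*B)
    blocks to training and the rest to validation (round-half-up)."""
    ids = np.unique(block_ids.values[block_ids.valid_mask])
    n_blocks = ids.size
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks to split")
    n_train = int(np.floor(train_frac * n_blocks + 0.5))
    n_train = min(max(n_train, 1), n_blocks - 1)
    rng = np.random.default_rng(seed)
    iterations = []
    for _ in range(n_iterations):
        it_seed = int(rng.integers(2**31 - 1))
        perm = np.random.default_rng(it_seed).permutation(ids)
        iterations.append(CVIteration(
            train_blocks=np.sort(perm[:n_train]),
            valid_blocks=np.sort(perm[n_train:]),
            seed=it_seed,
        ))
    return CVPlan(block_ids=block_ids, iterations=iterations)
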