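"""Spatially structured variant: replacement only by a lattice neighbour.

Cells sit on a 2-D or 3-D square (simple-cubic) lattice with periodic
boundaries.  Damage events are resolved exactly as in the well-mixed model
except that the cell dividing to replace an apoptotic one is drawn
uniformly from the von Neumann neighbourhood (4 neighbours in 2-D, 6 in
3-D) of the vacated site, and its mutation count is copied in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._kernels import run_engine
from .model import (LATTICE_2D, LATTICE_3D, ModelParams, StepEvent,
                    Trajectory, _SEED_MOD, _check_run_args, _occupancy_width,
                    _wrap_trajectory, repair_probability)

__all__ = ["LatticeGrid", "neighbors", "neighbor_table",
            "complete_graph_table", "step_lattice", "run_lattice"]


@dataclass
class LatticeGrid:
    """Per-site mutation counts on a periodic square lattice."""

    levels: np.ndarray  # shape = lattice extents, dtype int64

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.ndim not in (2, 3):
            raise ValueError("lattice must be 2- or 3-dimensional")
        if (self.levels < 0).any():
            raise ValueError("mutation counts must be non-negative")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.levels.shape

    @property
    def n_cells(self) -> int:
        return self.levels.size

    def occupancy_counts(self) -> np.ndarray:
        return np.bincount(self.levels.ravel())


def init_grid(params: ModelParams) -> LatticeGrid:
    """All sites start undamaged."""
    if params.lattice_shape is None:
        raise ValueError("params must specify a lattice topology")
    return LatticeGrid(np.zeros(params.lattice_shape, np.int64))


def neighbors(site: Tuple[int, ...], grid: LatticeGrid) -> List[Tuple[int, ...]]:
    """Von Neumann neighbourhood of ``site`` with periodic wrap."""
    shape = grid.shape
    if len(site) != len(shape) or any(not 0 <= s < e for s, e in zip(site, shape)):
        raise ValueError(f"site {site} outside lattice of shape {shape}")
    out = []
    for axis in range(len(shape)):
        for step in (-1, 1):
            nb = list(site)
            nb[axis] = (nb[axis] + step) % shape[axis]
            out.append(tuple(nb))
    return out


def neighbor_table(shape: Tuple[int, ...]) -> np.ndarray:
    """(N, 2*ndim) flat-index neighbour table for the compiled engine."""
    grid = LatticeGrid(np.zeros(shape, np.int64))
    n = grid.n_cells
    k = 2 * len(shape)
    table = np.empty((n, k), np.int64)
    for flat in range(n):
        site = np.unravel_index(flat, shape)
        for col, nb in enumerate(neighbors(tuple(int(s) for s in site), grid)):
            table[flat, col] = np.ravel_multi_index(nb, shape)
    return table


def complete_graph_table(n: int) -> np.ndarray:
    """Every site neighbours all others: reduces the lattice engine to well-mixed."""
    table = np.empty((n, n - 1), np.int64)
    for c in range(n):
        table[c, :c] = np.arange(c)
        table[c, c:] = np.arange(c + 1, n)
    return table


def step_lattice(grid: LatticeGrid, params: ModelParams,
                 rng: np.random.Generator) -> Tuple[LatticeGrid, StepEvent]:
    """Resolve one damage event in place; reference (non-compiled) path."""
    flat = grid.levels.ravel()
    c = int(rng.integers(0, flat.size))
    i = int(flat[c])
    if rng.random() < repair_probability(i, params):
        return grid, StepEvent("repair", i)
    if rng.random() < params.apoptosis_prob:
        site = tuple(int(s) for s in np.unravel_index(c, grid.shape))
        nbs = neighbors(site, grid)
        d = nbs[int(rng.integers(0, len(nbs)))]
        j = int(grid.levels[d])
        flat[c] = j
        return grid, StepEvent("apoptosis", i, j)
    flat[c] = i + 1
    return grid, StepEvent("mutation", i)


def run_lattice(params: ModelParams, max_sweeps: float,
                sample_every: float = 1.0,
                stop_on_undamaged_extinction: bool = False,
                record_occupancy: bool = False,
                nbrs: Optional[np.ndarray] = None) -> Trajectory:
    """Run the lattice dynamics; same protocol as :func:`run_well_mixed`.

    ``nbrs`` overrides the neighbour table (e.g. a complete graph for the
    well-mixed equivalence check); by default it is the von Neumann table
    of ``params.lattice_shape``.
    """
    _check_run_args(max_sweeps, sample_every)
    if nbrs is None:
        if params.lattice_shape is None:
            raise ValueError("params must specify a lattice topology")
        nbrs = neighbor_table(params.lattice_shape)
    n = params.n_cells
    if nbrs.shape[0] != n:
        raise ValueError("neighbour table does not match n_cells")
    n_steps = int(round(max_sweeps * n))
    stride = max(1, int(round(sample_every * n)))
    levels = np.zeros(n, np.int64)
    occ_width = _occupancy_width(params) if record_occupancy else 0
    out = run_engine(levels, np.ascontiguousarray(nbrs, np.int64), params.r0,
                     params.delta, params.apoptosis_prob, n_steps, stride,
                     stop_on_undamaged_extinction,
                     params.seed % _SEED_MOD, occ_width)
    traj = _wrap_trajectory(params, params.seed, params.topology, out,
                            record_occupancy)
    traj.final_counts = np.bincount(levels)
    return traj
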