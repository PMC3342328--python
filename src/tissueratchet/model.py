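"""Core stochastic model of DNA-repair decline under tissue homeostasis.

A fixed population of ``N`` cells receives genotoxic damage one event at a
time.  A damaged cell repairs with probability ``R = R0 - i*delta`` (``i``
is the number of mutations it carries, clamped to [0, 1]); failing that it
goes apoptotic with probability ``a`` and is replaced by a dividing peer
(the daughter inherits the parent's mutation count); otherwise the damage
fixes as one more mutation, permanently lowering the cell's repair rate.

The well-mixed population state is summarised by the occupancy vector
``n_i`` = number of cells carrying exactly ``i`` mutations.  ``run_well_mixed``
executes long runs through a compiled kernel; ``step_well_mixed`` is the
plain-Python single-step reference used as an independent path in tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from ._kernels import lifetime_engine, run_engine

WELL_MIXED = "well_mixed"
LATTICE_2D = "lattice_2d"
LATTICE_3D = "lattice_3d"
TOPOLOGIES = (WELL_MIXED, LATTICE_2D, LATTICE_3D)

# numba seeds its Mersenne Twister with a uint32
_SEED_MOD = 2**31


@dataclass(frozen=True)
class ModelParams:
    """All model constants plus topology and run controls.

    Parameters
    ----------
    n_cells : int
        Population size N (constant; every apoptosis triggers one division).
    r0 : float
        Initial repair probability R0 shared by all cells, in [0, 1].
    delta : float
        Fragility of the repair mechanism: repair-rate penalty per mutation.
    apoptosis_prob : float
        Probability a of apoptosis given a failed repair, in [0, 1].
    topology : str
        "well_mixed", "lattice_2d" or "lattice_3d".
    lattice_shape : tuple of int, optional
        Lattice extents; required for lattice topologies, product must
        equal ``n_cells``.
    seed : int
        Base seed for the run's random stream.
    """

    n_cells: int
    r0: float
    delta: float
    apoptosis_prob: float
    topology: str = WELL_MIXED
    lattice_shape: Optional[Tuple[int, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.n_cells, (int, np.integer)) or self.n_cells < 2:
            raise ValueError(f"n_cells must be an integer >= 2, got {self.n_cells!r}")
        if not 0.0 <= self.r0 <= 1.0:
            raise ValueError(f"r0 must lie in [0, 1], got {self.r0!r}")
        if self.delta < 0.0:
            raise ValueError(f"delta must be >= 0, got {self.delta!r}")
        if not 0.0 <= self.apoptosis_prob <= 1.0:
            raise ValueError(
                f"apoptosis_prob must lie in [0, 1], got {self.apoptosis_prob!r}")
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"topology must be one of {TOPOLOGIES}, got {self.topology!r}")
        if self.seed < 0:
            raise ValueError(f"seed must be >= 0, got {self.seed!r}")
        if self.topology == WELL_MIXED:
            if self.lattice_shape is not None:
                raise ValueError("lattice_shape given but topology is well_mixed")
        else:
            ndim = 2 if self.topology == LATTICE_2D else 3
            if self.lattice_shape is None:
                raise ValueError(
                    f"lattice_shape is required for topology {self.topology}")
            shape = tuple(int(s) for s in self.lattice_shape)
            if len(shape) != ndim or any(s < 1 for s in shape):
                raise ValueError(
                    f"lattice_shape must be {ndim} positive extents, got {shape}")
            if math.prod(shape) != self.n_cells:
                raise ValueError(
                    f"product of lattice_shape {shape} is {math.prod(shape)}, "
                    f"which does not equal n_cells={self.n_cells}")
            object.__setattr__(self, "lattice_shape", shape)

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclass
class OccupancyVector:
    """Counts ``n_i`` of cells carrying exactly ``i`` mutations; grows on demand."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or (self.counts < 0).any():
            raise ValueError("counts must be a 1-D vector of non-negative integers")

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())

    def ensure_level(self, i: int) -> None:
        if i >= self.counts.size:
            self.counts = np.concatenate(
                [self.counts, np.zeros(i + 1 - self.counts.size, np.int64)])

    def copy(self) -> "OccupancyVector":
        return OccupancyVector(self.counts.copy())


@dataclass(frozen=True)
class StepEvent:
    """Outcome of one damage event."""

    kind: str  # "repair" | "apoptosis" | "mutation"
    damaged_level: int
    replaced_by_level: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("repair", "apoptosis", "mutation"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if (self.replaced_by_level is not None) != (self.kind == "apoptosis"):
            raise ValueError("replaced_by_level is present iff kind == apoptosis")


@dataclass
class Trajectory:
    """Time-sampled observables of a single run.

    Times are in sweeps (steps / N): one sweep is one expected damage
    event per cell.  Event counters are cumulative; the division count
    equals the apoptosis count because each apoptosis triggers exactly
    one replacement division.
    """

    sample_times: np.ndarray
    mean_repair_rate: np.ndarray
    undamaged_count: np.ndarray
    cum_repairs: np.ndarray
    cum_apoptoses: np.ndarray
    cum_mutations: np.ndarray
    final_counts: np.ndarray
    params: ModelParams
    seed: int
    topology: str
    extinction_time: Optional[float] = None
    occupancy: Optional[np.ndarray] = None  # (n_samples, width) if recorded

    @property
    def cum_divisions(self) -> np.ndarray:
        return self.cum_apoptoses

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_sweeps": self.sample_times,
            "mean_repair_rate": self.mean_repair_rate,
            "undamaged_count": self.undamaged_count,
            "cum_repairs": self.cum_repairs,
            "cum_apoptoses": self.cum_apoptoses,
            "cum_mutations": self.cum_mutations,
            "cum_divisions": self.cum_divisions,
        })


def repair_probability(i: int, params: ModelParams) -> float:
    """Repair probability of a cell with ``i`` mutations: R0 - i*delta, clamped to [0, 1]."""
    if i < 0:
        raise ValueError(f"mutation count must be >= 0, got {i}")
    return min(1.0, max(0.0, params.r0 - i * params.delta))


def init_state(params: ModelParams) -> OccupancyVector:
    """All cells start undamaged, sharing the initial repair rate R0."""
    return OccupancyVector(np.array([params.n_cells], np.int64))


def mean_repair_rate(state: OccupancyVector, params: ModelParams) -> float:
    """Population mean repair rate R-bar = sum_i n_i * r_i / N."""
    rates = np.array([repair_probability(i, params)
                      for i in range(state.counts.size)])
    return float(np.dot(state.counts, rates) / params.n_cells)


def _draw_level(counts: np.ndarray, m: int) -> int:
    """Level of the m-th cell (0-indexed) when cells are ordered by level."""
    return int(np.searchsorted(np.cumsum(counts), m, side="right"))


def step_well_mixed(state: OccupancyVector, params: ModelParams,
                    rng: np.random.Generator) -> Tuple[OccupancyVector, StepEvent]:
    """Resolve one damage event in place; reference (non-compiled) path.

    At most three random decisions: damaged level ~ n_i/N; repair with
    probability r_i; else apoptosis with probability a (replacement level
    drawn from the post-removal counts over the N-1 survivors), else
    mutation (level i -> i+1).
    """
    n = params.n_cells
    counts = state.counts
    i = _draw_level(counts, int(rng.integers(0, n)))
    r = repair_probability(i, params)
    if rng.random() < r:
        return state, StepEvent("repair", i)
    if rng.random() < params.apoptosis_prob:
        counts[i] -= 1
        j = _draw_level(counts, int(rng.integers(0, n - 1)))
        counts[j] += 1
        return state, StepEvent("apoptosis", i, j)
    counts[i] -= 1
    state.ensure_level(i + 1)
    state.counts[i + 1] += 1
    return state, StepEvent("mutation", i)


def _occupancy_width(params: ModelParams) -> int:
    """Histogram width: past the clamp point i = R0/delta plus slack."""
    if params.delta > 0:
        return min(int(math.ceil(params.r0 / params.delta)) + 48, 4096)
    return 512


def _wrap_trajectory(params, seed, topology, kernel_out, record_occupancy):
    (steps, rbar, n0s, crep, capo, cmut, occ, ext_step) = kernel_out
    n = params.n_cells
    return Trajectory(
        sample_times=steps / n,
        mean_repair_rate=rbar,
        undamaged_count=n0s,
        cum_repairs=crep,
        cum_apoptoses=capo,
        cum_mutations=cmut,
        final_counts=None,  # set by caller
        params=params,
        seed=seed,
        topology=topology,
        extinction_time=None if ext_step < 0 else float(ext_step) / n,
        occupancy=occ if record_occupancy else None,
    )


def _check_run_args(max_sweeps, sample_every):
    if max_sweeps <= 0:
        raise ValueError(f"max_sweeps must be > 0, got {max_sweeps!r}")
    if sample_every <= 0:
        raise ValueError(f"sample_every must be > 0, got {sample_every!r}")


def run_well_mixed(params: ModelParams, max_sweeps: float,
                   sample_every: float = 1.0,
                   stop_on_undamaged_extinction: bool = False,
                   record_occupancy: bool = False) -> Trajectory:
    """Run the well-mixed dynamics for ``max_sweeps`` sweeps (steps/N).

    Observables are sampled every ``sample_every`` sweeps (plus at t=0 and,
    with the stop flag, at the extinction step of the undamaged class).
    Deterministic given (params, params.seed).
    """
    _check_run_args(max_sweeps, sample_every)
    n = params.n_cells
    n_steps = int(round(max_sweeps * n))
    stride = max(1, int(round(sample_every * n)))
    levels = np.zeros(n, np.int64)
    occ_width = _occupancy_width(params) if record_occupancy else 0
    out = run_engine(levels, np.zeros((1, 0), np.int64), params.r0,
                     params.delta, params.apoptosis_prob, n_steps, stride,
                     stop_on_undamaged_extinction,
                     params.seed % _SEED_MOD, occ_width)
    traj = _wrap_trajectory(params, params.seed, WELL_MIXED, out,
                            record_occupancy)
    traj.final_counts = np.bincount(levels)
    return traj


def measure_lifetimes(params: ModelParams, n_deaths: int = 2000,
                      burn_in_sweeps: float = 500.0,
                      margin_sweeps: Optional[float] = None) -> np.ndarray:
    """Per-cell lifetimes in damage events, measured at apoptosis.

    Uses a small agent-list run.  The sample is the complete cohort of
    cells born inside a steady-state window sized for about ``n_deaths``
    births, followed by a drain margin long enough that essentially every
    cohort member has died — recording a fixed number of deaths instead
    would under-sample long-lived cells.  The theoretical mean is
    1/(1 - R0) events, independent of a and delta.
    """
    if params.r0 >= 1.0:
        raise ValueError("r0 = 1 means no cell ever dies; lifetime is infinite")
    if params.apoptosis_prob <= 0.0:
        raise ValueError("a = 0 means no cell ever dies; lifetime is infinite")
    n = params.n_cells
    # births occur at rate ~(1 - R0) per step in steady state
    window_steps = int(math.ceil(n_deaths / (1.0 - params.r0)))
    if margin_sweeps is None:
        # slowest survival tail decays at rate a*(1 - R0) per damage event
        margin_sweeps = 50.0 / (params.apoptosis_prob * (1.0 - params.r0))
    return lifetime_engine(n, params.r0, params.delta, params.apoptosis_prob,
                           int(round(burn_in_sweeps * n)), window_steps,
                           int(round(margin_sweeps * n)),
                           params.seed % _SEED_MOD)
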