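"""Replicated studies: persistence time T*, parameter sweeps, size scaling,
distribution comparison, and the apoptosis-rate invariance.

T* is the first-passage time (in sweeps) of the undamaged class n0 to
zero.  Once n0 hits zero it can never recover — new undamaged cells would
require stem-cell influx, which the model deliberately lacks — so T*
marks the end of the temporary steady state and the onset of collapse.

All studies are pure functions of (params, seeds): replicate ``r`` of a
study runs with seed ``base_seed + offset + r``, so re-running reproduces
identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (LATTICE_2D, LATTICE_3D, WELL_MIXED, ModelParams,
                    Trajectory, run_well_mixed)
from .lattice import run_lattice
from . import theory

__all__ = [
    "TstarEstimate", "estimate_tstar", "sweep_tstar", "scaling_study",
    "distribution_comparison", "DistributionComparison",
    "apoptosis_invariance_study", "median_trajectory", "lattice_params",
]


def _run(params: ModelParams, max_sweeps: float, **kw) -> Trajectory:
    if params.topology == WELL_MIXED:
        return run_well_mixed(params, max_sweeps, **kw)
    return run_lattice(params, max_sweeps, **kw)


@dataclass
class TstarEstimate:
    """Per-replicate persistence times with explicit censoring.

    Replicates that reach ``max_sweeps`` with n0 > 0 are censored: their
    T* is only known to exceed ``max_sweeps``.  They enter the median at
    that lower bound; if the median itself lands on a censored value it is
    reported as a lower bound (``median_is_lower_bound``), never as a
    plain number.
    """

    per_replicate_tstar: np.ndarray  # censored entries hold max_sweeps
    censored: np.ndarray             # boolean mask
    median_tstar: float
    median_is_lower_bound: bool
    n_replicates: int
    censored_count: int
    max_sweeps: float
    params: ModelParams
    base_seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(self.n_replicates),
            "seed": self.base_seed + np.arange(self.n_replicates),
            "tstar_sweeps": self.per_replicate_tstar,
            "censored": self.censored,
        })


def _median_with_censoring(values: np.ndarray, censored: np.ndarray,
                           max_sweeps: float) -> Tuple[float, bool]:
    med = float(np.median(values))
    # the median is a bound whenever censored mass reaches it
    is_bound = bool(censored.any()) and med >= float(np.min(values[censored], initial=np.inf))
    return med, is_bound


def estimate_tstar(params: ModelParams, n_replicates: int, max_sweeps: float,
                   base_seed: int) -> TstarEstimate:
    """Median first-passage time of n0 to zero over independent replicates."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    times = np.empty(n_replicates)
    cens = np.zeros(n_replicates, bool)
    for r in range(n_replicates):
        p = params.replace(seed=base_seed + r)
        traj = _run(p, max_sweeps, sample_every=max(1.0, max_sweeps),
                    stop_on_undamaged_extinction=True)
        if traj.extinction_time is None:
            times[r] = max_sweeps
            cens[r] = True
        else:
            times[r] = traj.extinction_time
    med, bound = _median_with_censoring(times, cens, max_sweeps)
    return TstarEstimate(
        per_replicate_tstar=times, censored=cens, median_tstar=med,
        median_is_lower_bound=bound, n_replicates=n_replicates,
        censored_count=int(cens.sum()), max_sweeps=max_sweeps,
        params=params, base_seed=base_seed)


_SWEEPABLE = ("r0", "apoptosis_prob", "delta", "n_cells")


def sweep_tstar(params: ModelParams, vary: str, values: Sequence,
                n_replicates: int, max_sweeps: float,
                base_seed: int) -> pd.DataFrame:
    """Median T* as one parameter is varied, all others held fixed.

    Returns a tidy table with one row per replicate; the first value's
    replicates use exactly the seeds of ``estimate_tstar(params, ...)``.
    """
    if vary not in _SWEEPABLE:
        raise ValueError(f"vary must be one of {_SWEEPABLE}, got {vary!r}")
    rows = []
    for idx, v in enumerate(values):
        p = params.replace(**{vary: type(getattr(params, vary))(v)})
        est = estimate_tstar(p, n_replicates, max_sweeps,
                             base_seed + idx * n_replicates)
        frame = est.to_frame()
        frame.insert(0, "varied", vary)
        frame.insert(1, "value", v)
        frame["median_tstar"] = est.median_tstar
        frame["median_is_lower_bound"] = est.median_is_lower_bound
        frame["topology"] = p.topology
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def lattice_params(params: ModelParams, topology: str, n: int) -> ModelParams:
    """Rebuild params for size ``n`` on the given topology.

    2-D lattices require a perfect square, 3-D a perfect cube.
    """
    if topology == WELL_MIXED:
        return params.replace(n_cells=n, topology=topology, lattice_shape=None)
    if topology == LATTICE_2D:
        side = round(math.isqrt(n))
        if side * side != n:
            raise ValueError(f"N={n} is not a perfect square")
        return params.replace(n_cells=n, topology=topology,
                              lattice_shape=(side, side))
    if topology == LATTICE_3D:
        side = round(n ** (1.0 / 3.0))
        if side ** 3 != n:
            raise ValueError(f"N={n} is not a perfect cube")
        return params.replace(n_cells=n, topology=topology,
                              lattice_shape=(side, side, side))
    raise ValueError(f"unknown topology {topology!r}")


def scaling_study(params: ModelParams, n_values: Sequence[int],
                  topologies: Sequence[str], n_replicates: int,
                  max_sweeps: float, base_seed: int
                  ) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Median T* versus system size N, with a log-log slope per topology.

    The slope is a least-squares fit of log(median T*) on log(N), using
    only sizes whose median is uncensored; censoring is reported per row.
    """
    rows = []
    slopes: Dict[str, float] = {}
    offset = 0
    for topo in topologies:
        meds, ns = [], []
        for n in n_values:
            p = lattice_params(params, topo, int(n))
            est = estimate_tstar(p, n_replicates, max_sweeps,
                                 base_seed + offset)
            offset += n_replicates
            rows.append({
                "topology": topo, "n_cells": int(n),
                "median_tstar": est.median_tstar,
                "median_is_lower_bound": est.median_is_lower_bound,
                "censored_count": est.censored_count,
                "n_replicates": n_replicates,
            })
            if not est.median_is_lower_bound:
                meds.append(est.median_tstar)
                ns.append(n)
        if len(ns) >= 2:
            slopes[topo] = float(np.polyfit(np.log(ns), np.log(meds), 1)[0])
        else:
            slopes[topo] = float("nan")
    return pd.DataFrame(rows), slopes


@dataclass
class DistributionComparison:
    """Time-averaged empirical occupancy versus the analytic profile."""

    empirical: np.ndarray          # mean cells per class over the window
    theoretical: np.ndarray        # analytic n_i*, same length (padded)
    tv_distance: float             # 0.5 * sum |p_emp - p_theory|
    standardized_residuals: np.ndarray
    n_samples: int
    window_truncated: bool         # extinction occurred inside the window
    burn_in_gap: float             # |time-avg R-bar - R*| over the window
    params: ModelParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mutations": np.arange(self.empirical.size),
            "empirical_mean_cells": self.empirical,
            "theory_cells": self.theoretical,
            "standardized_residual": self.standardized_residuals,
        })


def distribution_comparison(params: ModelParams, burn_in: float,
                            window: float, base_seed: int,
                            sample_every: float = 1.0) -> DistributionComparison:
    """Compare the steady-state occupancy histogram with the closed form.

    One run of ``burn_in + window`` sweeps; samples inside the window are
    averaged, conditioned on n0 > 0 throughout (the window is truncated
    and flagged if the undamaged class dies out inside it).
    """
    p = params.replace(seed=base_seed)
    traj = _run(p, burn_in + window, sample_every=sample_every,
                record_occupancy=True)
    t = traj.sample_times
    in_window = t > burn_in
    # condition on survival of the undamaged class
    truncated = False
    dead = np.flatnonzero((traj.undamaged_count == 0) & in_window)
    if dead.size:
        truncated = True
        in_window &= np.arange(t.size) < dead[0]
    n_samples = int(in_window.sum())
    if n_samples == 0:
        raise RuntimeError("no usable samples: extinction before the window")
    emp = traj.occupancy[in_window].mean(axis=0)

    theo_full = theory.occupancy_distribution(params)
    width = max(emp.size, theo_full.size)
    empirical = np.zeros(width)
    empirical[:emp.size] = emp
    theoretical = np.zeros(width)
    theoretical[:theo_full.size] = theo_full

    n = params.n_cells
    tv = 0.5 * float(np.abs(empirical - theoretical).sum()) / n
    # binomial-scale spread of a single snapshot; descriptive only because
    # successive sweeps are correlated
    pth = np.clip(theoretical / n, 0.0, 1.0)
    sd = np.sqrt(np.maximum(n * pth * (1.0 - pth), 1.0))
    resid = (empirical - theoretical) / sd

    rbar_window = float(traj.mean_repair_rate[in_window].mean())
    gap = abs(rbar_window - theory.steady_state_mean_repair(params))
    return DistributionComparison(
        empirical=empirical, theoretical=theoretical, tv_distance=tv,
        standardized_residuals=resid, n_samples=n_samples,
        window_truncated=truncated, burn_in_gap=gap, params=params)


def apoptosis_invariance_study(params: ModelParams, a_values: Sequence[float],
                               n_replicates: int, burn_in: float,
                               window: float, base_seed: int) -> pd.DataFrame:
    """Steady-state apoptosis-event rate for several apoptosis probabilities.

    In the temporary steady state the per-step apoptosis probability is
    a (1 - R*) = 1 - R0, independent of a: raising a is exactly offset by
    the higher steady-state repair rate, so homeostatic divisions (and
    implicit Hayflick usage) do not accelerate.  Rates are events per
    step; the expected common value is (1 - R0).
    """
    rows = []
    for idx, a in enumerate(a_values):
        if a <= 1.0 - params.r0:
            raise ValueError(
                f"a={a} is outside the valid regime (need a > 1 - r0 = "
                f"{1.0 - params.r0:g})")
        rates = np.empty(n_replicates)
        for r in range(n_replicates):
            p = params.replace(apoptosis_prob=float(a),
                               seed=base_seed + idx * n_replicates + r)
            traj = _run(p, burn_in + window, sample_every=1.0)
            start = int(np.searchsorted(traj.sample_times, burn_in))
            steps = (traj.sample_times[-1] - traj.sample_times[start]) * p.n_cells
            events = traj.cum_apoptoses[-1] - traj.cum_apoptoses[start]
            rates[r] = events / steps
        mean = float(rates.mean())
        se = float(rates.std(ddof=1) / math.sqrt(n_replicates)) \
            if n_replicates > 1 else float("nan")
        rows.append({
            "apoptosis_prob": a,
            "events_per_step": mean,
            "se": se,
            "ci_low": mean - 1.96 * se if n_replicates > 1 else float("nan"),
            "ci_high": mean + 1.96 * se if n_replicates > 1 else float("nan"),
            "expected": 1.0 - params.r0,
            "n_replicates": n_replicates,
        })
    return pd.DataFrame(rows)


def median_trajectory(params: ModelParams, n_replicates: int,
                      max_sweeps: float, base_seed: int,
                      sample_every: float = 1.0
                      ) -> Tuple[np.ndarray, np.ndarray, List[Trajectory]]:
    """Median of R-bar(t) over replicates on a common time grid.

    Reproduces the characteristic ageing curve: an initial dip from R0,
    an extended plateau near R*, and a collapse after the undamaged class
    dies out.  Replicates keep running after extinction so the collapse
    is visible.
    """
    trajs = [
        _run(params.replace(seed=base_seed + r), max_sweeps,
             sample_every=sample_every)
        for r in range(n_replicates)
    ]
    times = trajs[0].sample_times
    stack = np.vstack([t.mean_repair_rate for t in trajs])
    return times, np.median(stack, axis=0), trajs
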