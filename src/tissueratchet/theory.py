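"""Mean-field theory of the temporary steady state.

Write ``n_i`` for the expected number of cells carrying ``i`` mutations and
``R_i = R0 - i*delta`` for their repair rate.  Per simulation step a cell
of class ``i`` is damaged with probability ``n_i/N``; it leaves the class
on any failed repair and the class gains when a class-``i`` cell divides
after an apoptosis elsewhere (rate ``a (1 - R-bar)`` per step, landing in
class ``i`` with probability ``n_i/N``).  The resulting master equations,
with time measured in steps, are

    dn_0/dt = (n_0/N) [ a (1 - R-bar) - (1 - R_0) ]
    dn_i/dt = (n_{i-1}/N) (1-a)(1 - R_{i-1})
              + (n_i/N) [ a (1 - R-bar) - (1 - R_i) ],      i >= 1.

Stationarity of the undamaged class fixes the steady-state mean repair
rate ``R* = 1 - (1 - R0)/a``; substituting back gives the recurrence

    n_i * i * delta = n_{i-1} (1 - a) (1 - R0 + (i-1) delta)

whose solution is a negative-binomial-shaped profile

    n_i* = n0 * (1-a)^i * C(beta + i - 1, i),   beta = (1 - R0)/delta,

with normalisation ``n0* = N a^beta`` (so the undamaged fraction is
``a^beta``).  The per-damage-event apoptosis probability of an average
cell is ``a (1 - R*) = 1 - R0``, giving a mean lifetime of ``1/(1 - R0)``
damage events regardless of ``a`` and ``delta``.

The closed forms use unclamped rates, as the normalising sum runs over all
``i``; classes past the clamp point ``i > R0/delta`` hold virtually no
cells in the regimes of interest, and the reported tail mass quantifies
the approximation.  The dynamical right-hand side clamps rates, matching
the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import gammaln

from .model import ModelParams

__all__ = [
    "TheoryResult", "steady_state_mean_repair", "beta_parameter",
    "valid_regime", "occupancy_recurrence", "occupancy_distribution",
    "steady_state", "expected_lifetime", "mean_field_rhs",
    "integrate_mean_field", "MeanFieldTrajectory", "perturbation_decay_rate",
]


@dataclass(frozen=True)
class TheoryResult:
    """Analytic description of the temporary steady state."""

    r_star: float
    beta: float
    n0_star: float
    occupancy: np.ndarray
    expected_lifetime_events: float  # inf when r0 == 1
    valid_regime: bool
    clamp_tail_mass: float  # expected cells past the clamp point i > r0/delta


def steady_state_mean_repair(params: ModelParams) -> float:
    """Steady-state mean repair rate R* = 1 - (1 - R0)/a.

    Derived from stationarity of the undamaged class: its per-step loss
    (n0/N)(1 - R0) must balance its replacement gain (n0/N) a (1 - R-bar).
    Negative values (a < 1 - R0) mean no positive steady state exists;
    ``valid_regime`` flags this.
    """
    if params.apoptosis_prob == 0.0:
        raise ValueError("a = 0 admits no steady state (cells are never replaced)")
    return 1.0 - (1.0 - params.r0) / params.apoptosis_prob


def beta_parameter(params: ModelParams) -> float:
    """Shape parameter beta = (1 - R0)/delta of the occupancy profile."""
    if params.delta == 0.0:
        if params.r0 == 1.0:
            return 0.0
        raise ValueError("beta is undefined for delta = 0 with r0 < 1")
    return (1.0 - params.r0) / params.delta


def valid_regime(params: ModelParams) -> bool:
    """True iff a positive steady state with a proper occupancy profile exists."""
    return (params.apoptosis_prob > 1.0 - params.r0
            and (params.delta > 0.0 or params.r0 == 1.0
                 or params.apoptosis_prob == 1.0))


def occupancy_recurrence(n_prev: float, i: int, params: ModelParams) -> float:
    """One step of the stationary recurrence:

    n_i = n_{i-1} (1 - a) (1 - R0 + (i-1) delta) / (i delta).
    """
    if i < 1:
        raise ValueError("recurrence starts at i = 1")
    if params.delta == 0.0:
        raise ValueError("recurrence is degenerate for delta = 0")
    a = params.apoptosis_prob
    return n_prev * (1.0 - a) * (1.0 - params.r0 + (i - 1) * params.delta) \
        / (i * params.delta)


def _log_binom(beta: float, i: np.ndarray) -> np.ndarray:
    """log C(beta + i - 1, i) for real beta > 0 via log-gamma."""
    return gammaln(beta + i) - gammaln(i + 1.0) - gammaln(beta)


def occupancy_distribution(params: ModelParams,
                           tail_tol: float = 1e-12) -> np.ndarray:
    """Expected steady-state occupancies n_i* = N a^beta (1-a)^i C(beta+i-1, i).

    Truncated at the smallest length whose remaining tail mass is below
    ``tail_tol * N`` (the untruncated sum is exactly N).
    """
    if tail_tol <= 0:
        raise ValueError("tail_tol must be positive")
    n = params.n_cells
    a = params.apoptosis_prob
    if not valid_regime(params):
        raise ValueError(
            "no steady-state occupancy outside the valid regime "
            "(need a > 1 - r0 and delta > 0, or r0 == 1)")
    if params.r0 == 1.0 or a == 1.0:
        return np.array([float(n)])
    beta = beta_parameter(params)
    occ = [n * a**beta]
    cum = occ[0]
    i = 1
    while n - cum > tail_tol * n and i < 100_000:
        occ.append(occupancy_recurrence(occ[-1], i, params))
        cum += occ[-1]
        i += 1
    return np.asarray(occ)


def closed_form_occupancy(params: ModelParams, n_classes: int) -> np.ndarray:
    """First ``n_classes`` occupancies from the product (closed) form."""
    n = params.n_cells
    a = params.apoptosis_prob
    beta = beta_parameter(params)
    i = np.arange(n_classes, dtype=float)
    if a == 1.0 or beta == 0.0:
        out = np.zeros(n_classes)
        out[0] = n
        return out
    log_n0 = math.log(n) + beta * math.log(a)
    return np.exp(log_n0 + i * math.log1p(-a) + _log_binom(beta, i))


def expected_lifetime(params: ModelParams) -> Tuple[float, float]:
    """Mean cell lifetime: (damage events, sweeps), both 1/(1 - R0).

    In steady state an average cell dies on a given damage event with
    probability a (1 - R*) = 1 - R0, so the lifetime is geometric with
    mean 1/(1 - R0) events; each cell is damaged once per sweep on
    average, so the two numbers coincide.
    """
    if params.r0 >= 1.0:
        raise ValueError("r0 = 1: cells never die, lifetime is infinite")
    if not valid_regime(params):
        raise ValueError("lifetime formula holds only in the valid regime")
    t = 1.0 / (1.0 - params.r0)
    return t, t


def steady_state(params: ModelParams, tail_tol: float = 1e-12) -> TheoryResult:
    """Bundle all closed-form steady-state quantities."""
    r_star = steady_state_mean_repair(params)
    ok = valid_regime(params)
    occ = occupancy_distribution(params, tail_tol) if ok else np.array([])
    if params.delta > 0 and ok:
        beta = beta_parameter(params)
        clamp = int(math.floor(params.r0 / params.delta)) + 1
        tail = float(occ[clamp:].sum()) if clamp < occ.size else 0.0
    else:
        beta = beta_parameter(params) if params.r0 == 1.0 else float("nan")
        tail = 0.0
    life = 1.0 / (1.0 - params.r0) if params.r0 < 1.0 else float("inf")
    return TheoryResult(
        r_star=r_star,
        beta=beta,
        n0_star=float(occ[0]) if occ.size else float("nan"),
        occupancy=occ,
        expected_lifetime_events=life,
        valid_regime=ok,
        clamp_tail_mass=tail,
    )


def _clamped_rates(n_classes: int, params: ModelParams) -> np.ndarray:
    r = params.r0 - params.delta * np.arange(n_classes)
    return np.clip(r, 0.0, 1.0)


def mean_field_rhs(occupancy: np.ndarray, params: ModelParams,
                   rbar: Optional[float] = None) -> np.ndarray:
    """Right-hand side of the master equations, time in steps.

    Returns a vector one longer than the input: the last entry is the
    mutation flux out of the top represented class, so the total sums to
    zero exactly (cell-number conservation) for any truncation length.

    ``rbar`` freezes the mean repair rate in the replacement-gain term
    (linear-response probe: the analytic per-class decay rate -i*delta/N
    is defined with R-bar held fixed); by default it is computed from the
    state.
    """
    n_vec = np.asarray(occupancy, dtype=float)
    if n_vec.ndim != 1 or (n_vec < 0).any():
        raise ValueError("occupancy must be a non-negative 1-D vector")
    n = params.n_cells
    a = params.apoptosis_prob
    rates = _clamped_rates(n_vec.size, params)
    if rbar is None:
        rbar = float(np.dot(n_vec, rates)) / n
    fail = 1.0 - rates
    out = np.zeros(n_vec.size + 1)
    out[:-1] = (n_vec / n) * (a * (1.0 - rbar) - fail)
    out[1:] += (n_vec / n) * (1.0 - a) * fail
    return out


@dataclass
class MeanFieldTrajectory:
    """Deterministic mean-field trajectory (fixed-step RK4)."""

    times: np.ndarray          # steps
    occupancy: np.ndarray      # (n_times, n_classes)
    params: ModelParams
    dt: float                  # converged step size, in steps

    def stationarity_gap(self) -> np.ndarray:
        """|a (1 - R-bar) - (1 - R0)| along the trajectory."""
        rates = _clamped_rates(self.occupancy.shape[1], self.params)
        rbar = self.occupancy @ rates / self.params.n_cells
        a = self.params.apoptosis_prob
        return np.abs(a * (1.0 - rbar) - (1.0 - self.params.r0))


def _rhs_absorbing(state: np.ndarray, params: ModelParams,
                   rbar: Optional[float] = None) -> np.ndarray:
    # top class absorbs its own mutation outflow -> exact conservation
    d = mean_field_rhs(state, params, rbar=rbar)
    d[-2] += d[-1]
    return d[:-1]


def integrate_mean_field(params: ModelParams, t_end: float,
                         initial: Optional[np.ndarray] = None,
                         n_samples: int = 200,
                         rel_tol: float = 1e-6,
                         max_halvings: int = 14,
                         rbar: Optional[float] = None) -> MeanFieldTrajectory:
    """Integrate the master equations from ``initial`` for ``t_end`` steps.

    RK4 with a fixed step, halved until the endpoint moves by less than
    ``rel_tol`` (relative, infinity norm).  The state vector is padded so
    the top class stays essentially empty; it absorbs its own mutation
    outflow, keeping the total exactly N.
    """
    n = params.n_cells
    if initial is None:
        initial = np.array([float(n)])
    initial = np.asarray(initial, dtype=float)
    if initial.ndim != 1 or (initial < -1e-9).any():
        raise ValueError("initial occupancy must be a non-negative 1-D vector")
    if rbar is None and abs(initial.sum() - n) > 1e-6 * n:
        raise ValueError("initial occupancy must sum to n_cells")
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    # pad: far enough past the theory profile (or clamp point) to hold
    # any transient mass
    if params.delta > 0:
        width = int(math.ceil(params.r0 / params.delta)) + 32
    else:
        width = 64
    width = max(width, initial.size + 8)
    y0 = np.zeros(width)
    y0[:initial.size] = initial

    def run(dt: float) -> np.ndarray:
        steps = max(1, int(math.ceil(t_end / dt)))
        h = t_end / steps
        y = y0.copy()
        snap_every = max(1, steps // n_samples)
        snaps = [y.copy()]
        times = [0.0]
        for s in range(1, steps + 1):
            k1 = _rhs_absorbing(y, params, rbar)
            k2 = _rhs_absorbing(np.maximum(y + 0.5 * h * k1, 0.0), params, rbar)
            k3 = _rhs_absorbing(np.maximum(y + 0.5 * h * k2, 0.0), params, rbar)
            k4 = _rhs_absorbing(np.maximum(y + h * k3, 0.0), params, rbar)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if y.min() < -1e-6 * n:
                raise RuntimeError(
                    f"mean-field integration unstable at dt={h:g} "
                    f"(occupancy {y.min():.3g}); reduce the step")
            np.clip(y, 0.0, None, out=y)
            if s % snap_every == 0 or s == steps:
                snaps.append(y.copy())
                times.append(s * h)
        return np.asarray(times), np.asarray(snaps), h

    # natural time scale of the dynamics is N steps
    dt = 0.1 * n
    times, snaps, h = run(dt)
    for _ in range(max_halvings):
        t2, s2, h2 = run(h / 2.0)
        delta_end = np.abs(s2[-1] - snaps[-1]).max() / max(1.0, np.abs(s2[-1]).max())
        times, snaps, h = t2, s2, h2
        if delta_end < rel_tol:
            break
    return MeanFieldTrajectory(times=times, occupancy=snaps, params=params, dt=h)


def perturbation_decay_rate(i: int, params: ModelParams) -> float:
    """First-order self-decay rate of a class-``i`` perturbation, per step.

    Linearising dn_i/dt in n_i at the fixed point with R-bar held fixed
    gives [a (1 - R*) - (1 - R_i)]/N = -i delta / N; the undamaged class
    (i = 0) is marginally stable.
    """
    if i < 0:
        raise ValueError("class index must be >= 0")
    if i == 0:
        return 0.0
    return -i * params.delta / params.n_cells
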