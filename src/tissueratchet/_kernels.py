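"""Numba-compiled inner loops for the stochastic engines.

Both the well-mixed and lattice engines operate on a per-cell array of
mutation levels.  Picking a uniformly random cell selects mutation level
``i`` with probability ``n_i / N``, so this is the same law as the
count-vector formulation but with O(1) work per step.

The kernels use numba's own Mersenne-Twister stream seeded at entry, so a
run is fully deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_engine", "lifetime_engine"]


@njit(cache=True)
def _record(levels, r0, delta, rbar_out, n0_out, occ_out, k, occ_width):
    """Compute R-bar, n0 and (optionally) the occupancy histogram from scratch."""
    n = levels.shape[0]
    s = 0.0
    n0 = 0
    for c in range(n):
        i = levels[c]
        r = r0 - i * delta
        if r < 0.0:
            r = 0.0
        s += r
        if i == 0:
            n0 += 1
        if occ_width > 0:
            j = i
            if j >= occ_width:
                j = occ_width - 1
            occ_out[k, j] += 1
    rbar_out[k] = s / n
    n0_out[k] = n0


@njit(cache=True)
def run_engine(levels, nbrs, r0, delta, a, n_steps, stride, stop_on_extinct,
               seed, occ_width):
    """Run the per-damage-event dynamics in place on ``levels``.

    nbrs: (N, k) flat neighbor indices for lattice replacement, or a
    (1, 0) array for well-mixed replacement (uniform over the N-1 survivors).
    Returns sampled observables and the extinction step (-1 if none).
    """
    np.random.seed(seed)
    n = levels.shape[0]
    use_nbrs = nbrs.shape[1] > 0
    n_nbrs = nbrs.shape[1]

    n_max = n_steps // stride + 2
    sample_steps = np.zeros(n_max, np.int64)
    rbar = np.zeros(n_max, np.float64)
    n0s = np.zeros(n_max, np.int64)
    crep = np.zeros(n_max, np.int64)
    capo = np.zeros(n_max, np.int64)
    cmut = np.zeros(n_max, np.int64)
    if occ_width > 0:
        occ = np.zeros((n_max, occ_width), np.int64)
    else:
        occ = np.zeros((1, 1), np.int64)

    # initial sample at t = 0
    _record(levels, r0, delta, rbar, n0s, occ, 0, occ_width)
    n0 = n0s[0]
    k = 1

    rep = 0
    apo = 0
    mut = 0
    ext_step = np.int64(-1)

    step = 0
    while step < n_steps:
        step += 1
        c = np.random.randint(0, n)
        i = levels[c]
        r = r0 - i * delta
        if r < 0.0:
            r = 0.0
        if np.random.random() < r:
            rep += 1
        elif np.random.random() < a:
            apo += 1
            if use_nbrs:
                d = nbrs[c, np.random.randint(0, n_nbrs)]
            else:
                d = np.random.randint(0, n - 1)
                if d >= c:
                    d += 1
            j = levels[d]
            if i == 0 and j != 0:
                n0 -= 1
            elif i != 0 and j == 0:
                n0 += 1
            levels[c] = j
        else:
            mut += 1
            if i == 0:
                n0 -= 1
            levels[c] = i + 1

        extinct = stop_on_extinct and n0 == 0
        if step % stride == 0 or extinct:
            _record(levels, r0, delta, rbar, n0s, occ, k, occ_width)
            sample_steps[k] = step
            crep[k] = rep
            capo[k] = apo
            cmut[k] = mut
            k += 1
            if extinct:
                ext_step = step
                break

    return (sample_steps[:k], rbar[:k], n0s[:k], crep[:k], capo[:k],
            cmut[:k], occ[:k] if occ_width > 0 else occ[:0], ext_step)


@njit(cache=True)
def lifetime_engine(n, r0, delta, a, burn_in_steps, window_steps,
                    margin_steps, seed):
    """Per-cell bookkeeping of damage events survived before apoptosis.

    Each cell carries a counter of damage events it has experienced
    (including the lethal one).  To avoid length-biased sampling, the
    recorded cohort is exactly the cells *born* during the window
    ``(burn_in, burn_in + window]``; the run then continues for
    ``margin_steps`` so that (virtually) every cohort member has died and
    been recorded, whatever its lifetime.
    """
    np.random.seed(seed)
    levels = np.zeros(n, np.int64)
    events = np.zeros(n, np.int64)
    in_cohort = np.zeros(n, np.bool_)
    out = np.zeros(window_steps, np.int64)  # <= one birth per step
    recorded = 0
    alive_cohort = 0
    cutoff = burn_in_steps + window_steps
    total = cutoff + margin_steps
    step = 0
    while step < total:
        step += 1
        if step > cutoff and alive_cohort == 0:
            break
        c = np.random.randint(0, n)
        i = levels[c]
        events[c] += 1
        r = r0 - i * delta
        if r < 0.0:
            r = 0.0
        if np.random.random() < r:
            pass
        elif np.random.random() < a:
            if in_cohort[c]:
                out[recorded] = events[c]
                recorded += 1
                alive_cohort -= 1
            d = np.random.randint(0, n - 1)
            if d >= c:
                d += 1
            levels[c] = levels[d]
            events[c] = 0
            if step > burn_in_steps and step <= cutoff:
                in_cohort[c] = True
                alive_cohort += 1
            else:
                in_cohort[c] = False
        else:
            levels[c] = i + 1
    return out[:recorded]
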