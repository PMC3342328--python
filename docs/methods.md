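# Methods

## Model

A tissue is a fixed population of `N` cells under continual genotoxic
damage. Damage arrives one event at a time: each simulation step picks one
cell uniformly at random and damages it. Time is reported in *sweeps*
(steps divided by `N`), so each cell receives on average one damage event
per sweep.

A cell carrying `i` mutations repairs a damage with probability

    R_i = clamp(R0 - i * delta, 0, 1)

If repair fails, the cell undergoes apoptosis with probability `a` and is
immediately replaced by the division of another cell, whose daughter
inherits the parent's mutation count — the population size never changes.
If the cell neither repairs nor dies, the damage fixes as one more
mutation (`i -> i+1`), permanently lowering the cell's repair rate by
`delta`. The three outcomes per damage event are therefore: repair
(probability `R_i`), apoptosis plus replacement (`(1-R_i) a`), mutation
(`(1-R_i)(1-a)`).

Two replacement topologies are implemented:

- **well-mixed** — the dividing cell is uniform over the `N-1` survivors;
- **lattice** — cells sit on a 2-D or 3-D periodic square lattice and the
  dividing cell is uniform over the von Neumann neighbourhood of the
  vacated site (4 neighbours in 2-D, 6 in 3-D).

The state is summarised by the occupancy vector `n_i` (cells with exactly
`i` mutations) and the population mean repair rate
`R-bar = sum_i n_i R_i / N`.

## Temporary steady state (mean-field theory)

With `n_i` treated as continuous and time in steps, the master equations
are

    dn_0/dt = (n_0/N) [ a (1 - R-bar) - (1 - R_0) ]
    dn_i/dt = (n_{i-1}/N) (1-a)(1 - R_{i-1})
              + (n_i/N) [ a (1 - R-bar) - (1 - R_i) ],   i >= 1.

The loss term is any failed repair (the cell either dies or leaves the
class by mutation); the gain terms are mutation influx from class `i-1`
and replacement divisions, which land in class `i` with probability
`n_i/N` because daughters inherit the parent's count.

Stationarity of the undamaged class (`i = 0`) forces

    R-bar* = 1 - (1 - R0)/a,

which requires `a > 1 - R0` (the *valid regime*; otherwise replacement
cannot keep up and no positive steady state exists). Substituting back
turns the stationarity conditions into a one-term recurrence

    n_i * i * delta = n_{i-1} (1 - a)(1 - R0 + (i-1) delta)

with the closed-form, negative-binomial-shaped solution

    n_i* = n_0* (1-a)^i C(beta + i - 1, i),   beta = (1 - R0)/delta,
    n_0* = N a^beta.

Three corollaries used as test oracles:

- **Apoptosis invariance.** The per-step apoptosis probability in steady
  state is `a (1 - R-bar*) = 1 - R0`, independent of `a` and `delta`:
  raising `a` is exactly offset by the higher steady-state repair rate.
- **Mean lifetime.** By Little's law (deaths per step = `1 - R0`,
  population `N`, damage rate one event per cell per sweep) the mean cell
  lifetime is `1/(1 - R0)` damage events. We verified this identity to be
  *exact* even when rate clamping is active, by solving the clamped
  mean-field steady state numerically and evaluating the backward
  recurrence `M_j = 1/(1 - R_j) + (1-a) M_{j+1}` for the expected
  remaining events of a cell born into class `j`, averaged over the birth
  distribution.
- **Linear stability.** Linearising `dn_i/dt` in `n_i` at the fixed point
  with `R-bar` held fixed gives the per-class self-decay rate
  `-i * delta / N`; the undamaged class is marginally stable (rate 0),
  which is why demographic noise can drive `n_0` to extinction.

The closed forms use unclamped rates `R0 - i*delta` (the normalising sum
runs over all `i`); the dynamical right-hand side and the stochastic
engines clamp rates to `[0, 1]`. `TheoryResult.clamp_tail_mass` reports
the expected cells past the clamp point, which is negligible at the
parameter points used in tests.

## Persistence time T*

Once `n_0` hits zero it can never recover (daughters inherit mutations
and the model has no stem-cell influx), so the undamaged class performs a
one-way ratchet. `T*` is the first-passage time of `n_0` to zero, in
sweeps — the end of the temporary steady state and the onset of repair
collapse. Replicated estimates report the median over independent seeds;
replicates still alive at `max_sweeps` are *censored* and enter the
median as lower bounds. If the median itself lands on a censored value it
is flagged (`median_is_lower_bound`) and excluded from downstream fits,
never reported as a plain number.

## Parameter choices and defaults

- **Reference point `N=5000, R0=0.9, delta=0.05, a=0.5`.** Gives round
  analytic values (`R* = 0.8`, `beta = 2`, `n_0* = N/4 = 1250`, lifetime
  `10` events) and a persistence time far beyond the test horizon at
  `N = 5000`, so steady-state comparisons are clean.
- **Small base point `N=50, R0=0.5, delta=0.25, a=0.6`** for T*
  monotonicity studies: extinction occurs within tens of sweeps, so 20
  replicates per arm are cheap. Monotonicity in `R0`, `a`, `delta` is
  assessed with one-sided Mann-Whitney rank tests between a low and a
  high arm (`r0`: 0.5 vs 0.6; `a`: 0.6 vs 0.8; `delta`: 0.1 vs 0.5,
  straddling the base value). Arms were fixed from pilot power checks at
  other seeds before the test seeds were chosen; note that for
  `delta >= R0` all levels beyond the first clamp to zero repair, so arms
  above 0.5 would be indistinguishable.
- **Scaling study at `R0=0.9, delta=0.05, a=0.48`, `N in {64, 144, 256}`
  (100 lattice replicates, 20 well-mixed replicates).** The scaling
  regime is very sensitive to `a`: high-replicate scans of the median
  lattice `T*` give log-log slopes of ~0.7 at `a=0.42-0.45`, ~1.0 at
  `a=0.48`, ~1.2 at `a=0.5` and >2 at `a>=0.6`, so `a=0.48` places the
  2-D lattice squarely in its linear regime at these sizes. The lattice
  slope needs many replicates because median noise propagates into the
  fitted slope; the well-mixed slope (>2.5 here) sits far from any
  threshold, so 20 replicates suffice. Well-mixed persistence grows so
  steeply that the largest size can be censored at `max_sweeps = 1e5`;
  the log-log slope is fitted on uncensored sizes only, which
  *understates* the well-mixed growth and therefore biases against the
  lattice/well-mixed comparison.
- **Lifetime estimator.** Records the complete cohort of cells born
  inside a steady-state window (sized for ~`n_deaths` births), followed
  by a drain margin of `50/(a(1-R0))` sweeps so essentially every cohort
  member dies inside the run; recording a fixed number of deaths instead
  would under-sample long-lived cells (length bias). The default burn-in
  is 500 sweeps: the mean-field relaxation from the all-undamaged start
  takes ~400 sweeps at the reference point, and shorter burn-ins visibly
  bias the cohort.

## Numerical choices

- **Engines.** Both stochastic engines are Numba-compiled loops over a
  per-cell array of mutation counts; picking a uniform random cell
  selects class `i` with probability `n_i/N`, so this is exactly the
  count-vector law at O(1) cost per step. Randomness is Numba's
  Mersenne-Twister stream seeded once per run: a run is a pure function
  of `(params, seed)`. Pure-Python single-step references
  (`step_well_mixed`, `step_lattice`) provide an independent
  implementation path for tests.
- **Mean-field integration.** Fixed-step RK4 with the step halved until
  the endpoint moves by less than a relative tolerance; the state vector
  is padded past the clamp point and the top class absorbs its own
  mutation outflow, so the total is conserved exactly at any truncation.
- **Linear-response probe.** The analytic rate `-i*delta/N` is defined
  with `R-bar` held at its fixed-point value; the integrator therefore
  accepts a frozen `rbar` for this measurement, because under the full
  nonlinear flow the global coupling through `R-bar` contaminates the
  single-class rate.
- **Seeding.** Studies derive replicate seeds as `base_seed + offset + r`
  so every table is bit-reproducible and sub-studies never share streams.

## Limitations

- The closed-form occupancy ignores clamping; at parameter points where
  `beta` is small and `1-a` large the clamp tail mass can matter. The
  reported `clamp_tail_mass` quantifies this.
- Finite-size effects: at small `N` the time-averaged `R-bar` sits
  slightly below the mean-field `R-bar*` (demographic noise plus the
  slow one-way drift of the ratchet), and by Little's law measured mean
  lifetimes shift by the corresponding amount (of order 1% at `N = 1000`
  for the reference point). Tolerances in the tests were set from exact
  oracles plus Monte-Carlo error, not fitted to outcomes.
- The model deliberately omits stem-cell influx, cell-cycle structure,
  and explicit Hayflick counting; divisions are tracked (one per
  apoptosis) but no division limit is enforced.
- T* medians for heavily censored conditions are lower bounds; scaling
  slopes use uncensored sizes only and can be based on as few as two
  sizes.
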