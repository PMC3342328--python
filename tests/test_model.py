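"""Unit and property tests for the well-mixed stochastic engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tissueratchet import (ModelParams, OccupancyVector, init_state,
                           mean_repair_rate, measure_lifetimes,
                           repair_probability, run_well_mixed,
                           step_well_mixed, steady_state_mean_repair)


class TestModelParams:
    @pytest.mark.parametrize("kw", [
        dict(n_cells=1),
        dict(r0=1.2),
        dict(r0=-0.1),
        dict(delta=-0.01),
        dict(apoptosis_prob=1.5),
        dict(topology="hexagonal"),
        dict(seed=-1),
    ])
    def test_invalid_fields_rejected(self, kw):
        base = dict(n_cells=100, r0=0.9, delta=0.05, apoptosis_prob=0.5)
        base.update(kw)
        with pytest.raises(ValueError):
            ModelParams(**base)

    def test_lattice_shape_must_match_n_cells(self):
        with pytest.raises(ValueError, match="lattice_shape"):
            ModelParams(n_cells=100, r0=0.9, delta=0.05, apoptosis_prob=0.5,
                        topology="lattice_2d", lattice_shape=(10, 12))
        p = ModelParams(n_cells=120, r0=0.9, delta=0.05, apoptosis_prob=0.5,
                        topology="lattice_2d", lattice_shape=(10, 12))
        assert p.lattice_shape == (10, 12)

    def test_lattice_topology_requires_shape(self):
        with pytest.raises(ValueError, match="lattice_shape"):
            ModelParams(n_cells=100, r0=0.9, delta=0.05, apoptosis_prob=0.5,
                        topology="lattice_2d")


class TestRepairProbability:
    def test_arithmetic_and_clamp(self):
        p = ModelParams(100, 0.9, 0.05, 0.5)
        assert repair_probability(0, p) == pytest.approx(0.9)
        assert repair_probability(2, p) == pytest.approx(0.8)
        # past the clamp point the rate is 0, not negative
        assert repair_probability(30, p) == 0.0

    def test_negative_level_is_contract_violation(self):
        p = ModelParams(100, 0.9, 0.05, 0.5)
        with pytest.raises(ValueError):
            repair_probability(-1, p)


class TestStateObservables:
    def test_init_state_all_undamaged(self):
        p = ModelParams(5000, 0.9, 0.05, 0.5)
        s = init_state(p)
        assert s.counts.tolist() == [5000]
        assert mean_repair_rate(s, p) == pytest.approx(p.r0)

    def test_mean_repair_rate_mixture(self):
        p = ModelParams(5000, 0.9, 0.05, 0.5)
        s = OccupancyVector(np.array([2500, 0, 2500]))
        assert mean_repair_rate(s, p) == pytest.approx(0.85)

    def test_zero_fragility_pins_mean_rate_at_r0(self):
        p = ModelParams(100, 0.7, 0.0, 0.5)
        s = OccupancyVector(np.array([10, 20, 30, 40]))
        assert mean_repair_rate(s, p) == pytest.approx(0.7)


class TestStepWellMixed:
    def test_certain_repair_freezes_state(self, rng):
        p = ModelParams(50, 1.0, 0.05, 0.5)
        s = init_state(p)
        for _ in range(200):
            s, ev = step_well_mixed(s, p, rng)
            assert ev.kind == "repair"
        assert s.counts.tolist() == [50]

    def test_certain_apoptosis_blocks_mutation(self, rng):
        # a=1: every failed repair is lethal, so no mutation can ever occur
        p = ModelParams(50, 0.5, 0.25, 1.0)
        s = init_state(p)
        for _ in range(2000):
            s, ev = step_well_mixed(s, p, rng)
            assert ev.kind in ("repair", "apoptosis")
        assert s.counts[0] == 50
        assert mean_repair_rate(s, p) == pytest.approx(p.r0)

    def test_conservation_over_many_steps(self, small_params, rng):
        s = init_state(small_params)
        events = {"repair": 0, "apoptosis": 0, "mutation": 0}
        for _ in range(100_000):
            s, ev = step_well_mixed(s, small_params, rng)
            events[ev.kind] += 1
            assert s.counts.sum() == small_params.n_cells
            assert (s.counts >= 0).all()
        assert events["apoptosis"] > 0 and events["mutation"] > 0

    def test_event_fractions_match_sampled_mean_rate(self):
        """Fraction of repair events tracks the time-average of R-bar."""
        p = ModelParams(500, 0.9, 0.05, 0.5, seed=3)
        rng = np.random.default_rng(3)
        s = init_state(p)
        n_steps = 200_000
        repairs = 0
        rbar_sum = 0.0
        for _ in range(n_steps):
            rbar_sum += mean_repair_rate(s, p)
            s, ev = step_well_mixed(s, p, rng)
            repairs += ev.kind == "repair"
        frac = repairs / n_steps
        expected = rbar_sum / n_steps
        # 3-sigma binomial band around the time-averaged repair probability
        sigma = np.sqrt(expected * (1 - expected) / n_steps)
        assert abs(frac - expected) < 3 * sigma


class TestRunWellMixed:
    def test_certain_repair_run(self):
        p = ModelParams(100, 1.0, 0.05, 0.5, seed=1)
        traj = run_well_mixed(p, 10)
        assert np.allclose(traj.mean_repair_rate, 1.0)
        assert traj.cum_apoptoses[-1] == 0
        assert traj.cum_mutations[-1] == 0

    def test_determinism_same_seed(self, small_params):
        t1 = run_well_mixed(small_params, 50)
        t2 = run_well_mixed(small_params, 50)
        assert np.array_equal(t1.mean_repair_rate, t2.mean_repair_rate)
        assert np.array_equal(t1.undamaged_count, t2.undamaged_count)
        assert np.array_equal(t1.final_counts, t2.final_counts)

    def test_different_seed_differs(self, small_params):
        t1 = run_well_mixed(small_params, 50)
        t2 = run_well_mixed(small_params.replace(seed=8), 50)
        assert not np.array_equal(t1.undamaged_count, t2.undamaged_count)

    def test_divisions_equal_apoptoses(self, small_params):
        traj = run_well_mixed(small_params, 100)
        assert np.array_equal(traj.cum_divisions, traj.cum_apoptoses)

    def test_zero_fragility_keeps_rate_at_r0(self):
        p = ModelParams(200, 0.7, 0.0, 0.5, seed=5)
        traj = run_well_mixed(p, 100)
        assert np.allclose(traj.mean_repair_rate, 0.7)
        # mutations do occur, they are just neutral
        assert traj.cum_mutations[-1] > 0

    def test_long_run_mean_matches_analytic_steady_state(self, base_params):
        """Time-averaged R-bar equals 1 - (1-R0)/a after burn-in."""
        traj = run_well_mixed(base_params, 2000)
        mask = traj.sample_times > 500
        avg = traj.mean_repair_rate[mask].mean()
        assert avg == pytest.approx(steady_state_mean_repair(base_params),
                                    abs=0.01)

    def test_apoptosis_rate_independent_of_a(self):
        """In steady state the per-step apoptosis probability is 1 - R0,
        whatever a > 1 - R0 is: a higher a is offset by a higher R*."""
        rates = []
        for a in (0.5, 0.9):
            p = ModelParams(2000, 0.9, 0.05, a, seed=11)
            traj = run_well_mixed(p, 1200)
            i0 = int(np.searchsorted(traj.sample_times, 200))
            steps = (traj.sample_times[-1] - traj.sample_times[i0]) * p.n_cells
            rates.append((traj.cum_apoptoses[-1] - traj.cum_apoptoses[i0]) / steps)
        sigma = np.sqrt(0.1 * 0.9 / (1000 * 2000))
        assert abs(rates[0] - rates[1]) < 3 * np.sqrt(2) * sigma
        for r in rates:
            assert r == pytest.approx(0.1, abs=3 * sigma)

    def test_invalid_run_arguments_rejected(self, small_params):
        with pytest.raises(ValueError):
            run_well_mixed(small_params, 0)
        with pytest.raises(ValueError):
            run_well_mixed(small_params, 10, sample_every=0)

    def test_extinction_stop_records_time(self):
        p = ModelParams(30, 0.5, 0.25, 0.6, seed=2)
        traj = run_well_mixed(p, 100_000, stop_on_undamaged_extinction=True)
        assert traj.extinction_time is not None
        assert traj.undamaged_count[-1] == 0
        assert traj.sample_times[-1] == pytest.approx(traj.extinction_time)


class TestLifetimes:
    def test_mean_lifetime_is_inverse_failure_probability(self):
        """Cells survive ~1/(1-R0) damage events regardless of a."""
        means = []
        for a in (0.6, 0.9):
            p = ModelParams(200, 0.5, 0.25, a, seed=21)
            lt = measure_lifetimes(p, n_deaths=20_000, burn_in_sweeps=500)
            means.append(lt.mean())
        for m in means:
            # geometric with mean 2 and sd ~sqrt(2): generous 3-sigma band
            assert m == pytest.approx(2.0, abs=0.1)
        assert abs(means[0] - means[1]) < 0.1

    def test_lifetime_requires_mortality(self):
        p = ModelParams(100, 1.0, 0.05, 0.5)
        with pytest.raises(ValueError):
            measure_lifetimes(p)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    r0=st.floats(0.2, 1.0),
    delta=st.floats(0.0, 0.5),
    a=st.floats(0.0, 1.0),
    n=st.integers(2, 60),
    seed=st.integers(0, 2**20),
)
def test_conservation_and_event_algebra_property(r0, delta, a, n, seed):
    """N is conserved and divisions == apoptoses for arbitrary parameters."""
    p = ModelParams(n, r0, delta, a, seed=seed)
    traj = run_well_mixed(p, 20)
    assert traj.final_counts.sum() == n
    assert (traj.undamaged_count >= 0).all()
    assert np.array_equal(traj.cum_divisions, traj.cum_apoptoses)
    total = traj.cum_repairs + traj.cum_apoptoses + traj.cum_mutations
    assert total[-1] == round(20 * n)
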