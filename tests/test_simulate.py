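"""The stochastic S-phase event loop: loading, firing, forks, conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oridyn as od
from oridyn.simulate import advance_forks, attempt_firings, new_state


def _point_genome(positions, length=100.0):
    df = pd.DataFrame({"chrom": ["chr1"] * len(positions),
                       "position": list(positions),
                       "status": ["Synthetic"] * len(positions)})
    return od.GenomeSpec((od.Chromosome("chr1", length),), df)


class TestFactorLoading:
    def test_loaded_fraction_at_tau_is_one_minus_inv_e(self):
        rng = np.random.default_rng(0)
        arr = np.concatenate([od.sample_factor_arrivals(187, 3.0, rng)
                              for _ in range(300)])
        frac = np.mean(arr <= 3.0)
        assert frac == pytest.approx(1 - np.exp(-1), abs=0.01)

    def test_zero_tau_loads_instantly(self):
        arr = od.sample_factor_arrivals(100, 0.0, np.random.default_rng(0))
        assert np.array_equal(arr, np.zeros(100))

    def test_mean_arrival_equals_tau(self):
        arr = od.sample_factor_arrivals(1000, 10.0, np.random.default_rng(1))
        assert arr.mean() == pytest.approx(10.0, rel=0.1)


class TestFiringProbability:
    def test_matches_direct_evaluation(self):
        # 1 - (1 - 6e-5)**840, evaluated independently at high precision
        from decimal import Decimal, getcontext
        getcontext().prec = 40
        exact = float(1 - (1 - Decimal("6e-5")) ** 840)
        assert od.firing_probability(6e-3, 0.01, 840) == pytest.approx(exact, rel=1e-12)
        assert exact == pytest.approx(0.0491524289, abs=1e-9)

    def test_edge_cases(self):
        assert od.firing_probability(6e-3, 0.01, 0) == 0.0
        assert od.firing_probability(0.0, 0.01, 500) == 0.0
        with pytest.raises(ValueError):
            od.firing_probability(2.0, 1.0, 5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(kon=st.floats(1e-6, 0.1), dt=st.floats(1e-4, 1.0),
           n=st.integers(0, 5000))
    def test_probability_valid_and_monotone_in_n(self, kon, dt, n):
        if kon * dt > 1:
            return
        p = od.firing_probability(kon, dt, n)
        assert 0.0 <= p <= 1.0
        assert p <= od.firing_probability(kon, dt, n + 1)


class TestFiring:
    def test_no_free_factors_is_noop(self):
        params = od.SimParams(genome=_point_genome([50.0]), v=0.5, kon=0.1,
                              ndt=1, dt=0.1)
        state = new_state(params)
        attempt_firings(state, params, np.random.default_rng(0))
        assert state.n_fired == 0 and state.n_forks == 0

    def test_single_firing_creates_divergent_fork_pair(self):
        params = od.SimParams(genome=_point_genome([50.0]), v=0.5, kon=1.0,
                              ndt=1, dt=1.0)
        state = new_state(params)
        state.pool.n_loaded = state.pool.n_free = 1
        attempt_firings(state, params, np.random.default_rng(0))
        assert state.n_fired == 1
        assert state.pool.n_free == 0 and state.pool.n_bound_halves == 2
        forks = state.forks()
        assert sorted(forks["direction"]) == ["left", "right"]
        assert (forks["position"] == 50.0).all()
        assert state.ori_status[0] == 1  # fired

    def test_firing_frequency_matches_probability(self):
        # 1 free factor, 840 origins, kon=6e-3, dt=0.01: empirical firing
        # frequency of the step operation over many independent trials
        # approaches the closed-form per-step probability (~0.0492).
        rng = np.random.default_rng(7)
        genome = od.periodic_genome(3000.0, 0.28, rng)
        params = od.SimParams(genome=genome, v=0.6, kon=6e-3, ndt=1, dt=0.01)
        p_expect = od.firing_probability(6e-3, 0.01, 840)
        state = new_state(params)
        state.pool.n_loaded = state.pool.n_free = 1
        snap = (state.pot_pos.copy(), state.pot_idx.copy(),
                state.ori_status.copy())
        n_trials, fired = 20_000, 0
        for _ in range(n_trials):
            attempt_firings(state, params, rng)
            if state.n_fired:
                fired += 1
                state.pot_pos, state.pot_idx = snap[0].copy(), snap[1].copy()
                state.ori_status = snap[2].copy()
                state.bb_left = state.bb_left[:0]
                state.bb_right = state.bb_right[:0]
                state.bb_lact = state.bb_lact[:0]
                state.bb_ract = state.bb_ract[:0]
                state.bb_lo, state.bb_hi = state.bb_lo[:0], state.bb_hi[:0]
                state.n_fired = 0
                state.pool.n_free, state.pool.n_bound_halves = 1, 0
        freq = fired / n_trials
        assert freq == pytest.approx(p_expect, abs=3.5 * np.sqrt(p_expect / n_trials))


class TestForkAdvance:
    def test_converging_forks_merge_and_release_factor(self):
        params = od.SimParams(genome=_point_genome([40.0, 41.0]), v=0.6,
                              ndt=2, kon=1.0, dt=1.0)
        state = new_state(params)
        state.pool.n_loaded = state.pool.n_free = 2
        # fire both origins by hand: two zero-width bubbles 1 kb apart
        state.pot_pos = state.pot_pos[:0]
        state.pot_idx = state.pot_idx[:0]
        state.ori_status[:] = 1
        state.bb_left = np.array([40.0, 41.0])
        state.bb_right = np.array([40.0, 41.0])
        state.bb_lact = np.array([True, True])
        state.bb_ract = np.array([True, True])
        state.bb_lo = np.array([0.0, 0.0])
        state.bb_hi = np.array([100.0, 100.0])
        state.pool.n_free = 0
        state.pool.n_bound_halves = 4
        advance_forks(state, params)
        assert len(state.bb_left) == 1  # merged
        assert state.pool.n_free == 1 and state.pool.n_bound_halves == 2
        assert state.n_merges == 1
        # merged bubble spans the union of both sweeps
        assert state.bb_left[0] == pytest.approx(40.0 - 0.6)
        assert state.bb_right[0] == pytest.approx(41.0 + 0.6)

    def test_fork_reaching_chromosome_start_is_discarded(self):
        params = od.SimParams(genome=_point_genome([0.2], length=100.0),
                              v=0.6, ndt=1, kon=1.0, dt=1.0)
        state = new_state(params)
        state.pot_pos = state.pot_pos[:0]
        state.pot_idx = state.pot_idx[:0]
        state.bb_left = np.array([0.2])
        state.bb_right = np.array([0.2])
        state.bb_lact = np.array([True])
        state.bb_ract = np.array([True])
        state.bb_lo = np.array([0.0])
        state.bb_hi = np.array([100.0])
        state.pool.n_loaded = 1
        state.pool.n_bound_halves = 2
        advance_forks(state, params)
        assert state.bb_left[0] == 0.0 and not state.bb_lact[0]
        assert state.pool.n_lost_halves == 1
        assert state.l_replicated == pytest.approx(0.2 + 0.6)

    def test_swept_origin_is_passivated(self):
        params = od.SimParams(genome=_point_genome([10.0, 10.5]), v=0.6,
                              ndt=1, kon=1.0, dt=1.0)
        state = new_state(params)
        # right-moving fork from a bubble at 10.0; origin at 10.5 in its path
        fire = state.pot_pos == 10.0
        state.ori_status[state.pot_idx[fire]] = 1
        state.pot_pos = state.pot_pos[~fire]
        state.pot_idx = state.pot_idx[~fire]
        state.bb_left = np.array([10.0])
        state.bb_right = np.array([10.0])
        state.bb_lact = np.array([True])
        state.bb_ract = np.array([True])
        state.bb_lo = np.array([0.0])
        state.bb_hi = np.array([100.0])
        state.pool.n_loaded = 1
        state.pool.n_bound_halves = 2
        advance_forks(state, params)
        assert state.n_passivated == 1
        assert state.ori_status[list(state.ori_pos).index(10.5)] == 2

    def test_recycling_restores_end_discarded_halves_in_pairs(self):
        genome = _point_genome([1.0, 99.0], length=100.0)
        params = od.SimParams(genome=genome, v=5.0, ndt=2, kon=1.0, dt=1.0,
                              recycle_at_ends=True)
        state = new_state(params)
        state.pot_pos = state.pot_pos[:0]
        state.pot_idx = state.pot_idx[:0]
        state.bb_left = np.array([1.0, 99.0])
        state.bb_right = np.array([1.0, 99.0])
        state.bb_lact = np.array([True, True])
        state.bb_ract = np.array([True, True])
        state.bb_lo = np.array([0.0, 0.0])
        state.bb_hi = np.array([100.0, 100.0])
        state.pool.n_loaded = 2
        state.pool.n_bound_halves = 4
        advance_forks(state, params)  # both outer forks hit the ends
        assert state.pool.n_free == 1  # two halves re-paired
        assert state.pool.n_lost_halves == 0
        state.pool.check()


class TestStep:
    def test_idle_state_only_advances_time(self):
        params = od.SimParams(genome=_point_genome([50.0]), v=0.5, kon=0.1,
                              ndt=1, dt=0.1)
        state = new_state(params)
        od.step(state, params, np.random.default_rng(0))
        assert state.time == pytest.approx(0.1)
        assert state.n_fired == 0 and state.l_replicated == 0.0


@pytest.fixture(scope="module")
def single_origin_delay_steps(single_origin_params):
    """Firing-delay step counts from 4000 single-origin S-phases.

    On a 1-origin, 1-factor, tau=0 system the replication time decomposes
    exactly as (firing step - 1)*dt + max(x0, L-x0)/v, because the forks
    start moving within the very step that fires the origin.  The firing
    step count (support 1, 2, ...) is geometric with success probability
    1-(1-kon*dt)^1; it is read off each run and shared by the mean and
    distribution oracles below.
    """
    params, x0, length = single_origin_params
    coverage = max(x0, length - x0) / params.v
    rng = np.random.default_rng(11)
    times = np.array([
        od.run_simulation(params, rng).replication_time for _ in range(4000)
    ])
    return np.round((times - coverage) / params.dt).astype(int) + 1


@pytest.fixture(scope="module")
def single_origin_params():
    """1-origin, 1-factor toy system with instantaneous loading."""
    x0, length = 4.0, 10.0
    df = pd.DataFrame({"chrom": ["chr1"], "position": [x0],
                       "status": ["Synthetic"]})
    genome = od.GenomeSpec((od.Chromosome("chr1", length),), df)
    return od.SimParams(genome=genome, v=0.5, kon=0.1, ndt=1,
                        tau_load=0.0, dt=0.1), x0, length


class TestRunSimulation:
    def test_single_origin_replication_time_closed_form(
            self, single_origin_params, single_origin_delay_steps):
        # replication time = firing delay + max(x0, L-x0)/v; the delay is
        # geometric in steps with success prob 1-(1-kon dt)^1
        params, _, _ = single_origin_params
        steps = single_origin_delay_steps
        p_step = od.firing_probability(params.kon, params.dt, 1)
        assert (steps >= 1).all()
        mean_expect = 1 / p_step  # geometric mean number of steps
        se = np.sqrt((1 - p_step) / p_step**2 / len(steps))
        assert steps.mean() == pytest.approx(mean_expect, abs=4 * se)

    def test_first_firing_delay_is_geometric(
            self, single_origin_params, single_origin_delay_steps):
        from scipy import stats

        params, _, _ = single_origin_params
        steps = single_origin_delay_steps
        p_step = od.firing_probability(params.kon, params.dt, 1)
        kmax = int(np.quantile(steps, 0.98))
        observed = np.bincount(np.minimum(steps, kmax + 1), minlength=kmax + 2)[1:]
        k = np.arange(1, kmax + 1)
        probs = (1 - p_step) ** (k - 1) * p_step
        expected = np.append(probs, (1 - p_step) ** kmax) * len(steps)
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.01

    def test_saturating_factors_fire_every_origin(self):
        rng = np.random.default_rng(3)
        genome = od.periodic_genome(100.0, 0.2, rng)  # 20 origins
        params = od.SimParams(genome=genome, v=0.5, kon=0.9, ndt=100, dt=1.0)
        rec = od.run_simulation(params, rng)
        assert rec.total_fired == 20 and rec.total_passivated == 0

    def test_origin_lifecycle_is_exhaustive(self):
        rng = np.random.default_rng(4)
        genome = od.periodic_genome(500.0, 0.1, rng)
        params = od.SimParams(genome=genome, v=0.6, kon=6e-3, ndt=5,
                              tau_load=1.0, dt=0.05)
        rec = od.run_simulation(params, rng)
        assert rec.total_fired + rec.total_passivated == rec.n_origins_initial
        ev = rec.events
        assert len(ev) == rec.n_origins_initial
        assert set(ev["event"]) <= {"fired", "passivated"}

    def test_factor_and_dna_conservation_each_step(self):
        rng = np.random.default_rng(5)
        genome = od.uniform_genome(500.0, 0.1, rng)
        params = od.SimParams(genome=genome, v=0.6, kon=6e-3, ndt=8,
                              tau_load=2.0, dt=0.05)
        rec = od.run_simulation(params, rng, check_invariants=True)
        # unreplicated length series non-increasing, ends at zero
        assert (np.diff(rec.l_unrep) <= 1e-9).all()
        assert rec.l_unrep[-1] == 0.0

    def test_no_factors_raises_stall(self):
        genome = _point_genome([50.0])
        params = od.SimParams(genome=genome, v=0.5, kon=0.1, ndt=0, dt=0.1)
        with pytest.raises(od.SimulationStalledError):
            od.run_simulation(params, np.random.default_rng(0))


class TestEnsemble:
    def test_same_master_seed_is_bit_identical(self):
        rng = np.random.default_rng(6)
        genome = od.periodic_genome(300.0, 0.1, rng)
        params = od.SimParams(genome=genome, v=0.6, kon=0.01, ndt=10,
                              tau_load=1.0, dt=0.05)
        e1 = od.run_ensemble(params, n_runs=5, master_seed=99, bin_width=0.5)
        e2 = od.run_ensemble(params, n_runs=5, master_seed=99, bin_width=0.5)
        np.testing.assert_array_equal(e1.i_pooled, e2.i_pooled)
        np.testing.assert_array_equal(e1.replication_times, e2.replication_times)

    def test_poisson_mode_factor_count_mean(self):
        rng = np.random.default_rng(8)
        genome = od.periodic_genome(200.0, 0.1, rng)
        params = od.SimParams(genome=genome, v=0.6, kon=0.02, ndt=20,
                              dt=0.05, ndt_mode="poisson")
        ens = od.run_ensemble(params, n_runs=300, master_seed=17, bin_width=1.0)
        mean_ndt = ens.per_run["ndt_used"].mean()
        assert mean_ndt == pytest.approx(20, abs=3 * np.sqrt(20 / 300))

    def test_resampled_positions_differ_between_runs(self):
        rng = np.random.default_rng(9)
        genome = od.uniform_genome(200.0, 0.1, rng)
        params = od.SimParams(genome=genome, v=0.6, kon=0.02, ndt=10, dt=0.05)
        ens = od.run_ensemble(params, n_runs=3, master_seed=1, bin_width=1.0,
                              keep_events=True)
        pos = [tuple(r.events.sort_values("position")["position"].round(6))
               for r in ens.records]
        assert len(set(pos)) == 3

    def test_dt_halving_robustness(self):
        # halving dt moves the ensemble mean replication time by less than
        # twice the Monte-Carlo standard error of the difference
        rng = np.random.default_rng(10)
        genome = od.periodic_genome(500.0, 0.2, rng)
        base = dict(genome=genome, v=0.6, kon=6e-3, ndt=20, tau_load=1.0)
        e1 = od.run_ensemble(od.SimParams(dt=0.04, **base), 40, master_seed=3,
                             bin_width=1.0)
        e2 = od.run_ensemble(od.SimParams(dt=0.02, **base), 40, master_seed=4,
                             bin_width=1.0)
        m1, s1, t1 = od.replication_time_summary(e1)
        m2, s2, t2 = od.replication_time_summary(e2)
        se = np.sqrt(s1**2 / len(t1) + s2**2 / len(t2))
        assert abs(m1 - m2) < 2.5 * se
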