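"""Equilibrium solver and slow-state integrator.

The fixed-point solver is checked against an independent oracle: a dense
scan over cardiac-output candidates locating the sign change of
VR(CO) - CO, with the full peripheral chain recomposed here from the
physiology primitives (not via the solver under test).
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from cvpop import simulator as sim
from cvpop.errors import SimulationError, SteadyStateError
from cvpop.simulator import DrainSchedule, ModelState


def _logistic(x, lo, hi, m, s, w):
    # independent transcription of the response curve for the oracle
    return lo + (hi - lo) / (1.0 + np.exp(np.clip(-m * (x - s) / w, -500, 500)))


def oracle_vr_minus_co(co, state, params, bv):
    """VR(CO) - CO recomposed independently of the solver (vectorized).

    For each CO candidate the pressure closure MAP = CO*r_auto*SNA(MAP)
    is solved by 70 steps of plain bisection, then VR follows from the
    filling-pressure chain.
    """
    co = np.asarray(co, dtype=float)
    sna_of = lambda m: _logistic(
        _logistic(state.p_adapt - m, 0.0, params.A_aff, params.m_aff, params.S_aff, params.w_aff),
        params.sna_min, params.sna_min + params.sna_max, params.m_sna, params.S_sna, params.w_sna,
    )
    lo = np.zeros_like(co)
    hi = co * state.r_auto * (params.sna_min + params.sna_max) + 1.0
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        above = mid - co * state.r_auto * sna_of(mid) > 0
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    m = 0.5 * (lo + hi)
    sna = sna_of(m)
    tpr = state.r_auto * sna
    f = co / params.CO_max
    rap = params.S_starling + params.w_starling / params.m_starling * np.log(f / (1 - f))
    sv = bv - params.V0
    mcfp_v = np.maximum(0.0, sv * (params.e_lin * sna + params.e_const))
    rvr_v = params.r_lin * tpr + params.r_const
    return (mcfp_v - np.maximum(rap, params.p_vc)) / rvr_v - co


def oracle_equilibrium_co(state, params, n_grid=20000):
    """Dense-scan-plus-bisection oracle for the CO = VR fixed point."""
    bv = _logistic(state.ecfv, 0.0, params.BV_max, params.m_BV, params.S_BV, params.w_BV)
    grid = np.linspace(1.0, params.CO_max * (1 - 1e-6), n_grid)
    vals = oracle_vr_minus_co(grid, state, params, bv)
    signs = np.sign(vals)
    crossings = np.where(np.diff(signs) < 0)[0]
    assert len(crossings) >= 1
    i = crossings[0]
    co = brentq(lambda c: float(oracle_vr_minus_co(c, state, params, bv)),
                grid[i], grid[i + 1], xtol=1e-6)
    return co, len(crossings)


def random_states(params, n, seed):
    rng = np.random.default_rng(seed)
    states = []
    for _ in range(n):
        states.append(
            ModelState(
                ecfv=rng.uniform(12000.0, 22000.0),
                p_adapt=rng.uniform(80.0, 130.0),
                r_auto=rng.uniform(0.01, 0.04),
            )
        )
    return states


class TestEquilibrium:
    def test_matches_dense_bisection_oracle(self, params):
        """Solver CO agrees with the independent scan to 0.1% on random states."""
        for state in random_states(params, 50, seed=7):
            eq = sim.solve_equilibrium(state, params)
            co_oracle, _ = oracle_equilibrium_co(state, params, n_grid=4000)
            assert eq.co == pytest.approx(co_oracle, rel=1e-3)
            assert eq.converged
            assert abs(eq.co - eq.vr) <= 1e-8 * eq.co

    def test_unique_crossing_on_random_draws(self, params):
        """VR - CO changes sign exactly once over (0, CO_max)."""
        rng = np.random.default_rng(11)
        names = ("A_auto", "S_auto", "A_aff", "sna_min", "m_BV", "BV_max", "e_const")
        for i in range(100):
            trial = params.replace(
                **{n: getattr(params, n) * rng.uniform(0.9, 1.1) for n in names}
            )
            state = random_states(trial, 1, seed=100 + i)[0]
            _, n_crossings = oracle_equilibrium_co(state, trial, n_grid=800)
            assert n_crossings == 1

    def test_higher_ecfv_raises_map(self, params, baseline):
        state, eq0 = baseline
        richer = ModelState(ecfv=state.ecfv + 500.0, p_adapt=state.p_adapt, r_auto=state.r_auto)
        eq1 = sim.solve_equilibrium(richer, params)
        assert eq1.map > eq0.map

    def test_collapse_floor(self, params, baseline):
        """With stressed volume exhausted the solver returns a small CO, flagged."""
        state, _ = baseline
        drained = ModelState(ecfv=9000.0, p_adapt=state.p_adapt, r_auto=state.r_auto)
        eq = sim.solve_equilibrium(drained, params)
        assert eq.converged
        assert eq.collapsed
        assert 0 < eq.co < params.S_auto / 2


class TestStep:
    def test_steady_state_is_fixed_point(self, params, baseline):
        state, _ = baseline
        after = sim.step(state, dt=1.0, params=params)
        assert after.ecfv == pytest.approx(state.ecfv, rel=1e-9)
        assert after.p_adapt == pytest.approx(state.p_adapt, rel=1e-9)
        assert after.r_auto == pytest.approx(state.r_auto, rel=1e-9)

    def test_adapted_pressure_half_time(self, params, baseline):
        """p_adapt relaxes exponentially: half the gap closes in ln2/k_adapt min."""
        state, _ = baseline
        gap = 20.0
        half_time = np.log(2) / params.k_adapt  # ~990 minutes
        # silence the afferent arm so MAP is constant while p_adapt relaxes,
        # freeze autoregulation, and cancel the renal fluid drift each step
        frozen = params.replace(k_auto=0.0, A_aff=1e-9)
        eq0 = sim.solve_equilibrium(state, frozen)
        y = ModelState(state.ecfv, eq0.map + gap, state.r_auto)
        t, dt = 0.0, 15.0
        while t < half_time - 1e-9:
            eqt = sim.solve_equilibrium(y, frozen)
            net = frozen.intake - eqt.uo
            y = sim.step(y, dt, frozen, hemorrhage_rate=net)
            t += dt
        remaining = y.p_adapt - eq0.map
        assert remaining == pytest.approx(gap / 2, rel=0.02)

    def test_drain_removes_rate_times_duration(self, params, baseline):
        state, _ = baseline
        y = state
        for _ in range(40):
            y = sim.step(y, 0.5, params, hemorrhage_rate=37.5)
        removed = state.ecfv - y.ecfv
        net_renal = 0.0  # intake ~ UO during the bleed contributes < 20 mL
        assert removed == pytest.approx(750.0 - net_renal, abs=20.0)

    def test_rejects_nonpositive_dt(self, params, baseline):
        state, _ = baseline
        with pytest.raises(SimulationError):
            sim.step(state, 0.0, params)


class TestIntegrate:
    def test_halving_base_step_converged(self, params, baseline):
        state, _ = baseline
        drain = DrainSchedule(37.5, 0.0, 20.0)
        _, eqs1 = sim.integrate(state, params, 40.0, drain, sample_times=[40.0], base_step=1.0)
        _, eqs2 = sim.integrate(state, params, 40.0, drain, sample_times=[40.0], base_step=0.5)
        assert abs(eqs1[-1].map - eqs2[-1].map) < 1e-4

    def test_deterministic(self, params, baseline):
        state, _ = baseline
        drain = DrainSchedule(37.5, 0.0, 20.0)
        _, a = sim.integrate(state, params, 40.0, drain)
        _, b = sim.integrate(state, params, 40.0, drain)
        assert [e.map for e in a] == [e.map for e in b]
        assert [e.co for e in a] == [e.co for e in b]

    def test_conservation_without_drain(self, params, baseline):
        """Over a drain-free interval, the ECFV change equals net fluid balance."""
        state, _ = baseline
        shifted = ModelState(state.ecfv + 300.0, state.p_adapt, state.r_auto)
        times = np.arange(0.0, 61.0, 1.0)
        states, eqs = sim.integrate(shifted, params, 60.0, sample_times=times)
        net = np.trapezoid([params.intake - e.uo for e in eqs], times)
        assert states[-1].ecfv - shifted.ecfv == pytest.approx(net, abs=0.05)


class TestSteadyState:
    def test_baseline_anchors(self, baseline):
        state, eq = baseline
        assert -2.5 <= eq.rap <= 0.0
        assert 4.0 <= eq.mcfp <= 9.0
        assert 95.0 <= eq.map <= 115.0
        assert abs(eq.uo - 1.0) <= 1e-6

    def test_infinite_gain_kidney(self, params):
        """Doubling water intake barely moves the long-term pressure."""
        _, eq1 = sim.run_to_steady_state(params)
        doubled = params.replace(intake=2.0)
        _, eq2 = sim.run_to_steady_state(doubled)
        assert abs(eq2.map - eq1.map) < 5.0

    def test_idempotent_under_further_integration(self, params, baseline):
        state, eq = baseline
        _, eqs = sim.integrate(state, params, 24 * 60.0, sample_times=[24 * 60.0],
                               base_step=60.0)
        assert abs(eqs[-1].map - eq.map) < 0.01

    def test_rejects_impossible_parameters(self, params):
        bad = params.replace(e_const=1e-9, e_lin=1e-9)  # needs BV above BV_max
        with pytest.raises(SteadyStateError):
            sim.run_to_steady_state(bad)
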