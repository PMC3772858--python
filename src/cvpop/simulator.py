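"""Circulatory equilibrium and slow-state integration.

At every instant the fast circulation is at an algebraic equilibrium:
the cardiac output proposed by the Starling curve must equal the venous
return produced by its own peripheral consequences (pressure, sympathetic
tone, filling pressure).  ``solve_equilibrium`` finds that unique fixed
point.  Three slow states evolve on top of it -- extracellular fluid
volume, the adapted baroreceptor reference pressure, and the delayed
autoregulated resistance -- integrated with an adaptive step-doubling
Runge-Kutta scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from . import physiology as phys
from .errors import SimulationError, SolverError, SteadyStateError
from .physiology import ModelParameters

__all__ = [
    "ModelState",
    "CirculatoryEquilibrium",
    "DrainSchedule",
    "solve_equilibrium",
    "step",
    "integrate",
    "run_to_steady_state",
]

RELATIVE_TOL = 1e-8     # |CO - VR| / CO at the fixed point
INTEGRATOR_TOL = 1e-6   # local relative error per state component
STEADY_UO_TOL = 1e-6    # |intake - UO| at steady state, mL/min


@dataclass
class ModelState:
    """The three integrated states plus the simulation clock (minutes)."""

    ecfv: float
    p_adapt: float
    r_auto: float
    t: float = 0.0

    def validate(self) -> "ModelState":
        if self.ecfv <= 0:
            raise SimulationError("ECFV must be positive", t=self.t)
        if self.r_auto <= 0:
            raise SimulationError("autoregulated resistance must be positive", t=self.t)
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.ecfv, self.p_adapt, self.r_auto])


@dataclass
class CirculatoryEquilibrium:
    """Algebraic variables of the circulation solved at one instant."""

    co: float
    vr: float
    rap: float
    map: float
    tpr: float
    rvr: float
    mcfp: float
    bv: float
    stressed_volume: float
    sna: float
    afferent: float
    uo: float
    elastance: float
    converged: bool
    iterations: int
    collapsed: bool = False      # stressed volume exhausted (MCFP clamped at 0)
    on_plateau: bool = False     # RAP at or below the venous collapse pressure

    FIELDS = (
        "co", "vr", "rap", "map", "tpr", "rvr", "mcfp", "bv", "stressed_volume",
        "sna", "afferent", "uo", "elastance",
    )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


def _project(m: float, state: ModelState, params: ModelParameters, bv: float):
    """Peripheral projection of one tentative pressure: all algebraic variables.

    Given MAP, the sympathetic multiplier, TPR and the tentative cardiac
    output CO = MAP / TPR are explicit; the Starling inverse gives the
    right atrial pressure that output requires, and the filling-pressure
    side gives the venous return it would actually receive.
    """
    aff = phys.afferent_signal(m, state.p_adapt, params)
    sna = phys.sympathetic_multiplier(aff, params)
    tpr = state.r_auto * sna
    co = m / tpr
    rap = phys.starling_rap(co, params)
    mcfp_v, sv, e = phys.mcfp(bv, sna, params)
    rvr_v = phys.rvr(tpr, params)
    vr = phys.venous_return(mcfp_v, rap, rvr_v, params.p_vc)
    return dict(map=m, afferent=aff, sna=sna, tpr=tpr, co=co, rap=rap, mcfp=mcfp_v,
                stressed_volume=sv, elastance=e, rvr=rvr_v, vr=vr)


def solve_equilibrium(
    state: ModelState,
    params: ModelParameters,
    tol: float = RELATIVE_TOL,
    max_iter: int = 400,
) -> CirculatoryEquilibrium:
    """Solve the CO = VR fixed point at one instant.

    Venous return is bounded above (venous collapse plateau) and below,
    and the residual VR - CO changes sign exactly once as the tentative
    operating point sweeps from zero flow to CO_max, so the fixed point
    is unique.  Because MAP = CO * r_auto * SNA(MAP), parametrising the
    sweep by MAP makes CO explicit (CO = MAP / (r_auto * SNA)) and the
    fixed point reduces to one bracketed Brent root find.
    """
    state.validate()
    bv = phys.blood_volume(state.ecfv, params)

    evals = [0]

    def residual(m):
        evals[0] += 1
        return _project(m, state, params, bv)["vr"] - m / (
            state.r_auto
            * phys.sympathetic_multiplier(phys.afferent_signal(m, state.p_adapt, params), params)
        )

    # MAP at which the tentative CO reaches CO_max (SNA is floored there).
    m_hi = params.CO_max * state.r_auto * params.sna_min * (1.0 - 1e-9)
    m_lo = 1e-9 * m_hi
    r_lo, r_hi = residual(m_lo), residual(m_hi)
    if r_lo <= 0 or r_hi >= 0:  # pragma: no cover - excluded by the VR bounds
        raise SolverError("bracket failure: VR - CO does not change sign",
                          residuals=[r_lo, r_hi])
    try:
        m = brentq(residual, m_lo, m_hi, xtol=1e-12, rtol=8.9e-16, maxiter=max_iter)
    except RuntimeError as exc:  # pragma: no cover - brentq always converges on a bracket
        raise SolverError(str(exc), residuals=[r_lo, r_hi]) from exc

    d = _project(m, state, params, bv)
    if abs(d["co"] - d["vr"]) > tol * max(d["co"], 1e-12):  # pragma: no cover
        raise SolverError("fixed point did not meet the relative tolerance",
                          residuals=[d["vr"] - d["co"]])
    uo = phys.urine_output(d["map"], d["sna"], params)
    return CirculatoryEquilibrium(
        co=d["co"], vr=d["vr"], rap=d["rap"], map=d["map"], tpr=d["tpr"],
        rvr=d["rvr"], mcfp=d["mcfp"], bv=bv, stressed_volume=d["stressed_volume"],
        sna=d["sna"], afferent=d["afferent"], uo=uo, elastance=d["elastance"],
        converged=True, iterations=evals[0],
        collapsed=d["stressed_volume"] <= 0.0,
        on_plateau=d["rap"] <= params.p_vc,
    )


@dataclass
class DrainSchedule:
    """Piecewise-constant external fluid drain (mL/min on [start, stop))."""

    rate: float = 0.0
    start: float = 0.0
    stop: float = 0.0

    def __call__(self, t: float) -> float:
        return self.rate if self.start <= t < self.stop else 0.0

    def breakpoints(self) -> tuple:
        return (self.start, self.stop)


def _rhs(y: np.ndarray, t: float, params: ModelParameters, drain_rate: float):
    state = ModelState(ecfv=y[0], p_adapt=y[1], r_auto=y[2], t=t)
    eq = solve_equilibrium(state, params)
    target_r = phys.sigmoid(eq.co, params.autoregulation_spec())
    return (
        np.array([
            params.intake - eq.uo - drain_rate,
            params.k_adapt * (eq.map - y[1]),
            params.k_auto * (target_r - y[2]),
        ]),
        eq,
    )


def _rk4(y: np.ndarray, t: float, dt: float, params: ModelParameters, drain_rate: float):
    k1, _ = _rhs(y, t, params, drain_rate)
    k2, _ = _rhs(y + 0.5 * dt * k1, t + 0.5 * dt, params, drain_rate)
    k3, _ = _rhs(y + 0.5 * dt * k2, t + 0.5 * dt, params, drain_rate)
    k4, _ = _rhs(y + dt * k3, t + dt, params, drain_rate)
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def step(
    state: ModelState,
    dt: float,
    params: ModelParameters,
    hemorrhage_rate: float = 0.0,
) -> ModelState:
    """Advance the three slow states by one Runge-Kutta step of length dt.

    The circulatory equilibrium is re-solved inside every stage
    evaluation; the states relax first-order toward their targets
    (r_auto at rate k_auto, p_adapt toward MAP at rate k_adapt) while
    ECFV accumulates intake less excretion less the hemorrhage drain.
    """
    if dt <= 0:
        raise SimulationError("step requires dt > 0", t=state.t)
    y = _rk4(state.as_array(), state.t, dt, params, hemorrhage_rate)
    if y[0] <= 0:
        raise SimulationError("ECFV driven non-positive", t=state.t + dt)
    return ModelState(ecfv=y[0], p_adapt=y[1], r_auto=y[2], t=state.t + dt)


def _advance_adaptive(
    y: np.ndarray,
    t0: float,
    t1: float,
    params: ModelParameters,
    drain_rate: float,
    tol: float,
    h0: float,
):
    """Integrate y from t0 to t1 (constant drain) by RK4 step doubling."""
    t, h = t0, min(h0, t1 - t0)
    while t < t1 - 1e-12:
        h = min(h, t1 - t)
        y_full = _rk4(y, t, h, params, drain_rate)
        y_half = _rk4(y, t, 0.5 * h, params, drain_rate)
        y_half = _rk4(y_half, t + 0.5 * h, 0.5 * h, params, drain_rate)
        scale = np.maximum(np.abs(y), np.abs(y_half)) + 1e-8
        err = float(np.max(np.abs(y_full - y_half) / scale))
        if err <= tol:
            # local extrapolation: the two half steps are 5th-order accurate here
            y = y_half + (y_half - y_full) / 15.0
            if y[0] <= 0:
                raise SimulationError("ECFV driven non-positive", t=t + h)
            t += h
            h *= min(2.0, max(0.5, 0.9 * (tol / max(err, 1e-300)) ** 0.2))
        else:
            h *= max(0.1, 0.9 * (tol / err) ** 0.2)
        if h < 1e-9:
            raise SimulationError("adaptive step underflow", t=t)
    return y, h


def integrate(
    state: ModelState,
    params: ModelParameters,
    duration: float,
    drain: DrainSchedule | Callable[[float], float] | None = None,
    sample_times: Sequence[float] | None = None,
    tol: float = INTEGRATOR_TOL,
    base_step: float = 1.0,
):
    """Run the slow dynamics for ``duration`` minutes.

    Returns ``(states, equilibria)`` sampled at ``sample_times`` (minutes
    from the start; defaults to every minute).  Integration lands exactly
    on every sample time and on drain-schedule breakpoints, so output is
    deterministic given inputs.
    """
    if duration <= 0:
        raise SimulationError("duration must be positive", t=state.t)
    drain = drain or DrainSchedule()
    if sample_times is None:
        sample_times = np.arange(0.0, duration + 1e-9, 1.0)
    sample_times = np.asarray(sorted(sample_times), dtype=float)
    if sample_times[0] < 0 or sample_times[-1] > duration + 1e-9:
        raise SimulationError("sample times must lie within [0, duration]")

    knots = set(np.round(sample_times, 12))
    if isinstance(drain, DrainSchedule):
        knots.update(b for b in drain.breakpoints() if 0.0 < b < duration)
    knots.update((0.0, duration))
    knots = sorted(knots)

    t_start = state.t
    y = state.as_array()
    states, eqs = [], []
    h = base_step
    wanted = set(np.round(sample_times, 12))
    if 0.0 in wanted:
        st = ModelState(*y, t=t_start)
        states.append(st)
        eqs.append(solve_equilibrium(st, params))
    for a, b in zip(knots[:-1], knots[1:]):
        rate = drain(0.5 * (a + b))
        y, h = _advance_adaptive(y, a, b, params, rate, tol, h)
        if np.round(b, 12) in wanted:
            st = ModelState(y[0], y[1], y[2], t=t_start + b)
            states.append(st)
            eqs.append(solve_equilibrium(st, params))
    return states, eqs


def run_to_steady_state(
    params: ModelParameters,
    fallback_days: float = 200.0,
) -> tuple[ModelState, CirculatoryEquilibrium]:
    """Long-term operating point of one virtual patient.

    At steady state the adapted pressure equals MAP (zero baroreceptor
    deficit), the autoregulated resistance sits on its response curve,
    and urine output equals intake, which pins MAP to the SNA-modulated
    renal set point.  That closes the system algebraically:

        MAP = p_renal * SNA0,   CO solves CO * R_auto(CO) * SNA0 = MAP,

    and the cardiac-integration cascade yields RAP, MCFP, stressed
    volume, BV and ECFV.  The result is verified against the equilibrium
    solver and the state residuals; if verification fails, a literal
    long integration (default 200 days) is attempted before giving up.
    """
    if params.p_renal is None:
        params.resolve()
    sna0 = phys.sympathetic_multiplier(phys.sigmoid(0.0, params.afferent_spec()), params)
    map_ss = params.p_renal * sna0

    auto = params.autoregulation_spec()

    def flow_residual(co):
        return co * phys.sigmoid(co, auto) * sna0 - map_ss

    lo, hi = 1.0, params.CO_max * (1.0 - 1e-9)
    if flow_residual(lo) > 0 or flow_residual(hi) < 0:
        raise SteadyStateError("no admissible steady-state cardiac output")
    co = brentq(flow_residual, lo, hi, xtol=1e-10, rtol=1e-14)
    tpr = map_ss / co
    try:
        rap = phys.starling_rap(co, params)
    except Exception as exc:
        raise SteadyStateError(f"Starling inverse failed: {exc}") from exc
    rvr_v = phys.rvr(tpr, params)
    mcfp_v = max(rap, params.p_vc) + co * rvr_v
    e = phys.elastance(sna0, params)
    if mcfp_v <= 0:
        raise SteadyStateError("steady state requires positive filling pressure")
    sv = mcfp_v / e
    bv = params.V0 + sv
    if not (0.0 < bv < params.BV_max):
        raise SteadyStateError("steady-state blood volume outside the partition range")
    ecfv = phys.blood_volume_inverse(bv, params)
    state = ModelState(ecfv=ecfv, p_adapt=map_ss, r_auto=phys.sigmoid(co, auto), t=0.0)

    eq = solve_equilibrium(state, params)
    if abs(params.intake - eq.uo) <= STEADY_UO_TOL and abs(eq.map - state.p_adapt) < 1e-6:
        return state, eq

    # fall back to the literal long run from the algebraic guess
    states, eqs = integrate(
        state, params, duration=fallback_days * 24 * 60.0,
        sample_times=[fallback_days * 24 * 60.0], base_step=60.0,
    )
    state, eq = states[-1], eqs[-1]
    state = replace(state, t=0.0)
    if abs(params.intake - eq.uo) > STEADY_UO_TOL:
        raise SteadyStateError("steady state not reached after the long integration")
    return state, eq
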