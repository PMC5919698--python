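"""Forward integration to steady state, work loops and mass-specific power.

The coupled system is integrated cycle by cycle, with the integrator
restarted at every excitation edge so the square-wave forcing never crosses
an adaptive step. Per-cycle net work is

    W_net = ∮ F_m dx   (work done by the muscle on the load),

which over a closed steady-state cycle equals the damper dissipation
∫ b (dΔx/dt)² dt, since the spring is conservative and the kinetic energy is
periodic. The cycle-average mass-specific power is P* = W_net f / m_m.
The cycle integral of the instantaneous muscle power F_m v_m, with
v_m = dl_m/dt = -dx/dt, equals -W_net under this sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .activation import ActivationParams, ExcitationProtocol, excitation
from .plant import (
    MuscleProperties,
    OscillatorLoad,
    SimulationBlowupError,
    SystemState,
    system_rhs,
)

__all__ = [
    "SimulationResult",
    "WorkLoop",
    "run_forward",
    "detect_steady_state",
    "work_loop",
    "cycle_net_work",
    "mass_specific_power",
    "instantaneous_power",
    "trace_to_csv",
]


@dataclass
class SimulationResult:
    """Sampled trajectory, per-cycle work and steady-state power.

    Series are stored as ``(n_cycles, samples_per_cycle + 1)`` arrays; the
    last sample of one cycle coincides in time with the first of the next.
    """

    t: np.ndarray
    u: np.ndarray
    a: np.ndarray
    x: np.ndarray
    v: np.ndarray
    l_m: np.ndarray
    v_m: np.ndarray
    F_m: np.ndarray
    power: np.ndarray
    work: np.ndarray
    damper_work: np.ndarray
    steady_start: Optional[int]
    steady_state_reached: bool
    n_cycles_run: int
    P_star: float
    muscle: MuscleProperties = None
    load: OscillatorLoad = None
    protocol: ExcitationProtocol = None
    act_params: ActivationParams = None

    def to_frame(self) -> pd.DataFrame:
        n_cycles, n = self.t.shape
        idx = np.repeat(np.arange(n_cycles), n)
        return pd.DataFrame(
            {
                "cycle_index": idx,
                "t_s": self.t.ravel(),
                "u": self.u.ravel(),
                "a": self.a.ravel(),
                "x_m": self.x.ravel(),
                "l_m_m": self.l_m.ravel(),
                "v_m_m_per_s": self.v_m.ravel(),
                "F_m_N": self.F_m.ravel(),
                "power_W": self.power.ravel(),
            }
        )


@dataclass
class WorkLoop:
    """Closed (l_m, F_m) path over one cycle."""

    l_m: np.ndarray
    F_m: np.ndarray
    net_work: float
    direction: str  # "clockwise" or "counter-clockwise" in the (l_m, F_m) plane

    @property
    def closes(self) -> bool:
        return bool(
            np.isclose(self.l_m[0], self.l_m[-1], rtol=1e-6, atol=1e-12)
            and np.isclose(self.F_m[0], self.F_m[-1], rtol=1e-6, atol=1e-12)
        )


def cycle_net_work(F_m: np.ndarray, x: np.ndarray) -> float:
    """∮ F_m dx over one sampled cycle (trapezoidal rule)."""
    return float(np.trapezoid(F_m, x))


def instantaneous_power(F_m, v_m):
    """Instantaneous muscle power: elementwise F_m · v_m (v_m = dl_m/dt)."""
    return np.asarray(F_m, dtype=float) * np.asarray(v_m, dtype=float)


def mass_specific_power(W_net: float, f: float, m_m: float) -> float:
    """Cycle-average mass-specific power P* = W_net f / m_m (W/kg)."""
    if not m_m > 0:
        raise ValueError("muscle mass must be positive")
    return float(W_net) * float(f) / float(m_m)


def detect_steady_state(
    per_cycle_work, rel_tol: float = 1e-4, floor: float = 1e-15
) -> Optional[int]:
    """First cycle index from which successive works stop changing.

    Returns the first index ``i >= 1`` such that for that and every later
    cycle ``|W_j - W_{j-1}| <= rel_tol * max(|W_j|, floor)``, or ``None`` if
    the sequence never settles.
    """
    w = np.asarray(per_cycle_work, dtype=float)
    if w.size < 2:
        raise ValueError("need at least 2 completed cycles")
    ok = np.abs(np.diff(w)) <= rel_tol * np.maximum(np.abs(w[1:]), floor)
    # last run of consecutive True reaching the end
    idx = None
    for i in range(len(ok) - 1, -1, -1):
        if ok[i]:
            idx = i + 1
        else:
            break
    return idx


def run_forward(
    muscle: MuscleProperties,
    curves,
    load: OscillatorLoad,
    protocol: ExcitationProtocol,
    act_params: ActivationParams,
    *,
    n_max_cycles: int = 100,
    min_cycles: int = 5,
    work_rel_tol: float = 1e-4,
    samples_per_cycle: int = 2048,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "DOP853",
    activation_mode: str = "ode",
    initial_state: Optional[SystemState] = None,
) -> SimulationResult:
    """Integrate the muscle–oscillator system until the per-cycle work settles.

    Starts from rest at the oscillator resting length, (x0, 0, 0), unless an
    initial state is given. Stops once at least ``min_cycles`` cycles have run
    and the last three consecutive per-cycle work differences are within
    ``work_rel_tol`` (relative), or at ``n_max_cycles`` with the steady flag
    unset. Because of damping the steady state is independent of the initial
    conditions. P* is averaged over the last three cycles.
    """
    if n_max_cycles < 5:
        raise ValueError("n_max_cycles must be at least 5")
    T = protocol.period
    if initial_state is None:
        state = np.array([load.x0, 0.0, 0.0])
    else:
        state = np.array([initial_state.x, initial_state.v, initial_state.a])

    def rhs(t, y):
        return system_rhs(
            t, y, muscle, load, curves, protocol, act_params, activation_mode
        )

    def lm_positive(t, y):
        return (load.l_tot - y[0]) - 1e-9 * muscle.l0

    lm_positive.terminal = True
    lm_positive.direction = -1

    t_rows, x_rows, v_rows, a_rows = [], [], [], []
    works, damper_works = [], []
    n_run = 0
    steady = False
    for n in range(n_max_cycles):
        t0 = n * T
        spans = [(t0, t0 + protocol.D * T)]
        if protocol.D < 1.0:
            spans.append((t0 + protocol.D * T, (n + 1) * T))
        sols = []
        for a_t, b_t in spans:
            sol = solve_ivp(
                rhs,
                (a_t, b_t),
                state,
                method=method,
                rtol=rtol,
                atol=atol,
                dense_output=True,
                events=lm_positive,
            )
            if sol.status == 1 or not np.all(np.isfinite(sol.y[:, -1])):
                raise SimulationBlowupError(
                    f"simulation blew up in cycle {n}",
                    last_state=SystemState(
                        x=float(sol.y[0, -1]),
                        v=float(sol.y[1, -1]),
                        a=float(sol.y[2, -1]),
                        t=float(sol.t[-1]),
                    ),
                )
            state = sol.y[:, -1]
            sols.append((a_t, b_t, sol))
        ts = np.linspace(t0, (n + 1) * T, samples_per_cycle + 1)
        ys = np.empty((3, ts.size))
        for a_t, b_t, sol in sols:
            m = (ts >= a_t) & (ts <= b_t)
            ys[:, m] = sol.sol(ts[m])
        t_rows.append(ts)
        x_rows.append(ys[0])
        v_rows.append(ys[1])
        a_rows.append(ys[2])
        # per-cycle energies from the dense samples
        F = _forces(muscle, load, curves, protocol, ts, ys, activation_mode)
        works.append(cycle_net_work(F, ys[0]))
        damper_works.append(float(np.trapezoid(load.b * ys[1] ** 2, ts)))
        n_run = n + 1
        if n_run >= max(min_cycles, 4):
            d = np.abs(np.diff(works[-4:]))
            ref = work_rel_tol * np.maximum(np.abs(works[-3:]), 1e-15)
            if np.all(d <= ref):
                steady = True
                break

    t = np.vstack(t_rows)
    x = np.vstack(x_rows)
    v = np.vstack(v_rows)
    a = np.vstack(a_rows)
    u = excitation(t, protocol)
    l_m = load.l_tot - x
    v_m = -v
    if activation_mode == "instantaneous":
        a_eff = u
    else:
        a_eff = a
    l_hat = l_m / muscle.l0
    v_hat = -v / (muscle.l0 * muscle.eps0_dot)
    F_m = muscle.F0 * (
        a_eff * curves.active_force_length.evaluate(l_hat)
        * curves.force_velocity.evaluate(v_hat)
        + curves.passive_force_length.evaluate(l_hat)
    )
    power = instantaneous_power(F_m, v_m)
    works = np.asarray(works)
    steady_start = detect_steady_state(works, work_rel_tol) if n_run >= 2 else None
    P_star = mass_specific_power(float(np.mean(works[-3:])), protocol.f, muscle.m_m)
    return SimulationResult(
        t=t,
        u=u,
        a=a,
        x=x,
        v=v,
        l_m=l_m,
        v_m=v_m,
        F_m=F_m,
        power=power,
        work=works,
        damper_work=np.asarray(damper_works),
        steady_start=steady_start,
        steady_state_reached=steady,
        n_cycles_run=n_run,
        P_star=P_star,
        muscle=muscle,
        load=load,
        protocol=protocol,
        act_params=act_params,
    )


def _forces(muscle, load, curves, protocol, ts, ys, activation_mode):
    l_hat = (load.l_tot - ys[0]) / muscle.l0
    v_hat = -ys[1] / (muscle.l0 * muscle.eps0_dot)
    if activation_mode == "instantaneous":
        a_eff = excitation(ts, protocol)
    else:
        a_eff = ys[2]
    return muscle.F0 * (
        a_eff * curves.active_force_length.evaluate(l_hat)
        * curves.force_velocity.evaluate(v_hat)
        + curves.passive_force_length.evaluate(l_hat)
    )


def work_loop(result: SimulationResult, cycle_index: int = -1) -> WorkLoop:
    """Extract the closed (l_m, F_m) loop of one completed cycle."""
    l = result.l_m[cycle_index]
    F = result.F_m[cycle_index]
    x = result.x[cycle_index]
    W = cycle_net_work(F, x)
    # shoelace orientation in the (l_m, F_m) plane
    area = 0.5 * float(np.sum((l[:-1] * F[1:] - l[1:] * F[:-1])))
    direction = "counter-clockwise" if area > 0 else "clockwise"
    return WorkLoop(l_m=l, F_m=F, net_work=W, direction=direction)


def trace_to_csv(result: SimulationResult, path) -> None:
    result.to_frame().to_csv(path, index=False, lineterminator="\n")
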