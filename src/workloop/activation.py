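"""Square-wave excitation and first-order bilinear activation dynamics.

Excitation u(t) is a repeating square wave with frequency f, duty cycle D and
amplitude u_max. Activation a(t) lags excitation through

    da/dt = (u - a (beta + u (1 - beta))) / tau_act

so the rise under constant u is exponential with rate
(beta + u (1 - beta)) / tau_act toward the steady state
a_ss = u / (beta + u (1 - beta)), and the decay under u = 0 has the slower
rate beta / tau_act (beta <= 1: deactivation is slower than activation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ExcitationProtocol",
    "ActivationParams",
    "excitation",
    "activation_rate",
    "steady_activation",
    "activation_closed_form",
    "activation_time_constant",
    "simulate_activation",
]


@dataclass(frozen=True)
class ExcitationProtocol:
    """Square-wave excitation: frequency ``f`` (Hz), duty cycle ``D``,
    amplitude ``u_max``. ``D = 1`` is allowed as the degenerate always-on
    protocol."""

    f: float
    D: float
    u_max: float

    def __post_init__(self):
        if not self.f > 0:
            raise ValueError(f"excitation frequency must be positive, got {self.f}")
        if not 0 < self.D <= 1:
            raise ValueError(f"duty cycle must lie in (0, 1], got {self.D}")
        if not 0 < self.u_max <= 1:
            raise ValueError(f"u_max must lie in (0, 1], got {self.u_max}")

    @property
    def period(self) -> float:
        return 1.0 / self.f


@dataclass(frozen=True)
class ActivationParams:
    """Activation time constant ``tau_act`` (s) and activation/deactivation
    time-constant ratio ``beta``."""

    tau_act: float
    beta: float = 0.6

    def __post_init__(self):
        if not self.tau_act > 0:
            raise ValueError(f"tau_act must be positive, got {self.tau_act}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")


def activation_time_constant(eps0_dot: float) -> float:
    """Default tau_act (s) by fibre speed: 0.045 for slow muscle
    (maximum shortening strain rate 5 1/s), 0.025 for fast (10 1/s)."""
    return 0.045 if eps0_dot < 7.5 else 0.025


def excitation(t, protocol: ExcitationProtocol):
    """Square-wave excitation at time(s) ``t`` (on-phase starts each cycle)."""
    t = np.asarray(t, dtype=float)
    phase = t * protocol.f
    phase = phase - np.floor(phase)
    u = np.where(phase < protocol.D, protocol.u_max, 0.0)
    return float(u) if u.ndim == 0 else u


def activation_rate(a: float, u: float, params: ActivationParams) -> float:
    """da/dt for activation ``a`` under excitation ``u``."""
    return (u - a * (params.beta + u * (1.0 - params.beta))) / params.tau_act


def steady_activation(u: float, params: ActivationParams) -> float:
    """Fixed point of the activation dynamics under constant excitation."""
    return u / (params.beta + u * (1.0 - params.beta))


def activation_closed_form(t, a0: float, u: float, params: ActivationParams):
    """Exact activation trajectory under constant excitation ``u``."""
    t = np.asarray(t, dtype=float)
    rate = (params.beta + u * (1.0 - params.beta)) / params.tau_act
    a_ss = steady_activation(u, params)
    a = a_ss + (a0 - a_ss) * np.exp(-rate * t)
    return float(a) if a.ndim == 0 else a


def simulate_activation(
    protocol: ExcitationProtocol,
    params: ActivationParams,
    n_cycles: int,
    a0: float = 0.0,
    samples_per_cycle: int = 256,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Numerically integrate the activation ODE alone.

    The integrator is restarted at every excitation edge so the square-wave
    discontinuity never crosses an adaptive step. Returns ``(t, a)`` sampled
    on a uniform grid of ``samples_per_cycle`` intervals per cycle.
    """
    T = protocol.period
    t_all, a_all = [], []
    a = float(a0)
    for n in range(n_cycles):
        edges = [(n * T, n * T + protocol.D * T, protocol.u_max)]
        if protocol.D < 1.0:
            edges.append((n * T + protocol.D * T, (n + 1) * T, 0.0))
        sols = []
        for t0, t1, u in edges:
            sol = solve_ivp(
                lambda t, y, u=u: [activation_rate(y[0], u, params)],
                (t0, t1),
                [a],
                method="DOP853",
                rtol=rtol,
                atol=atol,
                dense_output=True,
            )
            a = float(sol.y[0, -1])
            sols.append((t0, t1, sol))
        ts = np.linspace(n * T, (n + 1) * T, samples_per_cycle + 1)
        vals = np.empty_like(ts)
        for t0, t1, sol in sols:
            m = (ts >= t0) & (ts <= t1)
            vals[m] = sol.sol(ts[m])[0]
        t_all.append(ts)
        a_all.append(vals)
    return np.concatenate(t_all), np.concatenate(a_all)
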