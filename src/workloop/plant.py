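"""Dimensional muscle–oscillator plant.

A cylindrical bundle of parallel fibres (contractile + parallel elastic
element, no tendon) acts in series on a damped harmonic oscillator. The
muscle length is l_m = l_tot - x for oscillator position x, and the equation
of motion is

    m d²Δx/dt² + b dΔx/dt + k Δx = F_m,   Δx = x - x0,
    F_m = F0 (a F_A(l̂) F_V(v̂) + F_P(l̂)),

with l̂ = l_m / l0 and v̂ = (dl_m/dt) / (l0 ε̇0). The oscillator constants are
tied to the muscle through dimensionless linkage fractions: natural frequency
ω_n = 2π c1 f_d, mass m = c2 F0, resting length x0 = c3 (l_tot - l0), and the
damping is exactly critical, b = √(4 m k).

The muscle tissue itself is treated as massless in the dynamics; its mass
m_m = ρ l0 A enters only the normalization of power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .activation import ActivationParams, ExcitationProtocol, activation_rate, excitation

__all__ = [
    "MuscleProperties",
    "LinkageParams",
    "OscillatorLoad",
    "SystemState",
    "SimulationBlowupError",
    "derive_geometry",
    "build_oscillator",
    "muscle_force",
    "system_rhs",
    "linear_plant_steady_response",
]


class SimulationBlowupError(RuntimeError):
    """The state left the physically meaningful region (l_m <= 0 or non-finite)."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class MuscleProperties:
    """Dimensional muscle constants with derived geometry.

    l0 — optimal length (m); sigma0 — maximum isometric stress (Pa);
    rho — density (kg/m³); aspect_ratio — l0 : diameter; eps0_dot — maximum
    shortening strain rate (1/s).
    """

    l0: float
    sigma0: float
    rho: float
    aspect_ratio: float
    eps0_dot: float

    def __post_init__(self):
        for name in ("l0", "sigma0", "rho", "aspect_ratio", "eps0_dot"):
            if not getattr(self, name) > 0:
                raise ValueError(f"muscle property {name} must be positive")

    @property
    def A(self) -> float:
        """Cross-sectional area (m²) of the cylindrical model."""
        return 0.25 * math.pi * (self.l0 / self.aspect_ratio) ** 2

    @property
    def F0(self) -> float:
        """Maximum isometric force (N)."""
        return self.sigma0 * self.A

    @property
    def m_m(self) -> float:
        """Muscle mass (kg)."""
        return self.rho * self.l0 * self.A


def derive_geometry(
    l0: float, sigma0: float, rho: float, aspect_ratio: float, eps0_dot: float = 10.0
) -> MuscleProperties:
    """Construct :class:`MuscleProperties`, validating positivity."""
    return MuscleProperties(l0, sigma0, rho, aspect_ratio, eps0_dot)


@dataclass(frozen=True)
class LinkageParams:
    """Dimensionless oscillator-linkage fractions and the driving frequency.

    c1 = ω_n/ω_d; c2 = m/F0 (kg/N); c3 = x0/(l_tot - l0); fd — driving
    frequency (Hz).
    """

    c1: float
    c2: float
    c3: float
    fd: float

    def __post_init__(self):
        for name in ("c1", "c2", "c3", "fd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"linkage parameter {name} must be positive")
        if not self.c3 < 1:
            raise ValueError(f"c3 must be below 1, got {self.c3}")


@dataclass(frozen=True)
class OscillatorLoad:
    """Oscillator constants: mass m (kg), stiffness k (N/m), damping
    b (N s/m), resting length x0 (m), total system length l_tot (m)."""

    m: float
    k: float
    b: float
    x0: float
    l_tot: float

    def __post_init__(self):
        for name in ("m", "k", "b", "x0", "l_tot"):
            if not getattr(self, name) > 0:
                raise ValueError(f"oscillator property {name} must be positive")

    @property
    def omega_n(self) -> float:
        return math.sqrt(self.k / self.m)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state: position x (m), velocity v (m/s), activation a."""

    x: float
    v: float
    a: float
    t: float = 0.0


def build_oscillator(
    linkage: LinkageParams, F0: float, l_tot: float, l0: float
) -> OscillatorLoad:
    """Construct the oscillator from linkage fractions.

    m = c2 F0, b = 4π m c1 fd and k = b²/(4m), so critical damping b² = 4 m k
    holds bit-exactly; k equals m (2π c1 fd)² up to rounding.
    """
    if not l_tot > l0:
        raise ValueError(f"l_tot ({l_tot}) must exceed l0 ({l0})")
    m = linkage.c2 * F0
    b = 4.0 * math.pi * m * linkage.c1 * linkage.fd
    k = b * b / (4.0 * m)
    x0 = linkage.c3 * (l_tot - l0)
    return OscillatorLoad(m=m, k=k, b=b, x0=x0, l_tot=l_tot)


def muscle_force(a: float, l_hat: float, v_hat: float, curves, F0: float) -> float:
    """Hill-type force: F0 (a F_A(l̂) F_V(v̂) + F_P(l̂))."""
    fa = curves.active_force_length(l_hat)
    fv = curves.force_velocity(v_hat)
    fp = curves.passive_force_length(l_hat)
    return F0 * (a * fa * fv + fp)


def system_rhs(
    t: float,
    y,
    muscle: MuscleProperties,
    load: OscillatorLoad,
    curves,
    protocol: ExcitationProtocol,
    act_params: ActivationParams,
    activation_mode: str = "ode",
):
    """Time derivative of the state (x, v, a).

    With ``activation_mode="instantaneous"`` the activation equals the
    excitation directly (no lag), which makes the plant linear when the
    curves are constant.
    """
    x, v, a = float(y[0]), float(y[1]), float(y[2])
    l_m = load.l_tot - x
    if l_m <= 0.0:
        raise SimulationBlowupError(
            f"muscle length became non-positive at t={t}",
            last_state=SystemState(x=x, v=v, a=a, t=t),
        )
    u = excitation(t, protocol)
    if activation_mode == "instantaneous":
        a_eff, dadt = u, 0.0
    else:
        a_eff, dadt = a, activation_rate(a, u, act_params)
    l_hat = l_m / muscle.l0
    v_hat = -v / (muscle.l0 * muscle.eps0_dot)  # shortening (v>0) -> v_hat<0
    F_m = muscle_force(a_eff, l_hat, v_hat, curves, muscle.F0)
    dvdt = (F_m - load.k * (x - load.x0) - load.b * v) / load.m
    return (v, dvdt, dadt)


def linear_plant_steady_response(
    load: OscillatorLoad,
    force_on: float,
    protocol: ExcitationProtocol,
    n_samples: int = 2048,
):
    """Closed-form periodic response of the critically damped plant to a
    square-wave force (``force_on`` during the on-phase, zero otherwise).

    On each constant-force interval the solution is
    Δx(t) = F/k + (C1 + C2 t) exp(-ω t) with ω = √(k/m); the state map over
    one interval is affine, so the periodic steady state solves a 2×2 linear
    system. Returns ``(t, x, v)`` over one period starting at the on-phase.
    """
    w = load.omega_n
    T = protocol.period

    def seg_map(tau, F):
        e = math.exp(-w * tau)
        M = np.array(
            [
                [e * (1.0 + w * tau), e * tau],
                [-e * w * w * tau, e * (1.0 - w * tau)],
            ]
        )
        xp = F / load.k
        d = np.array([xp * (1.0 - e * (1.0 + w * tau)), xp * e * w * w * tau])
        return M, d

    tau_on = protocol.D * T
    tau_off = T - tau_on
    M1, d1 = seg_map(tau_on, force_on)
    if tau_off > 0:
        M2, d2 = seg_map(tau_off, 0.0)
    else:
        M2, d2 = np.eye(2), np.zeros(2)
    M = M2 @ M1
    d = M2 @ d1 + d2
    s0 = np.linalg.solve(np.eye(2) - M, d)  # periodic (Δx, v) at the on edge

    t = np.linspace(0.0, T, n_samples + 1)
    dx = np.empty_like(t)
    v = np.empty_like(t)
    s_edge = M1 @ s0 + d1  # state at the off edge
    for i, ti in enumerate(t):
        if ti <= tau_on:
            F, tloc, s = force_on, ti, s0
        else:
            F, tloc, s = 0.0, ti - tau_on, s_edge
        xp = F / load.k
        C1 = s[0] - xp
        C2 = s[1] + w * C1
        e = math.exp(-w * tloc)
        dx[i] = xp + (C1 + C2 * tloc) * e
        v[i] = (C2 - w * (C1 + C2 * tloc)) * e
    return t, load.x0 + dx, v
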