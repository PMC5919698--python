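"""Global optimization of the oscillator linkage for maximum power.

The free parameters (c1, c2, c3, fd, D) — or (c1, c2, c3, D) when the
driving frequency is tied to a prescribed excitation frequency — are searched
with seeded differential evolution inside box bounds, followed by a bounded
Nelder–Mead polish (the objective passes through an adaptive ODE solve, so
finite-difference gradients are unreliable). The objective is the cycle-
average mass-specific power P* of the steady-state solution. c2 spans several
decades of load mass per unit force and is searched on a log10 scale.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .config import RunConfig, simulate_config
from .plant import SimulationBlowupError

__all__ = [
    "OptimizationSpec",
    "OptimizationResult",
    "DEFAULT_BOUNDS",
    "objective",
    "optimize_linkage",
]

#: physically sensible search box (c2 in kg/N spans light to heavy loads)
DEFAULT_BOUNDS = {
    "c1": (0.05, 2.0),
    "c2": (1e-3, 1e2),
    "c3": (0.05, 0.95),
    "fd": (0.1, 5.0),
    "D": (0.05, 0.95),
}

#: large penalty assigned to candidates whose simulation blows up
PENALTY = -1e6

#: reduced-accuracy solver settings used inside the search (the winner can be
#: re-evaluated at full accuracy afterwards)
SEARCH_SOLVER = {
    "samples_per_cycle": 256,
    "rtol": 1e-6,
    "atol": 1e-9,
    "n_max_cycles": 60,
    "min_cycles": 5,
    "work_rel_tol": 1e-4,
}


@dataclass
class OptimizationSpec:
    """What to optimize and under which fixed conditions.

    ``f_hz=None`` leaves the driving frequency fd free and ties the
    excitation frequency to it; a fixed ``f_hz`` removes fd from the search
    (fd = f). The budget is roughly ``popsize * n_params * (maxiter + 1)``
    objective evaluations plus the polish.
    """

    eps0_dot: float = 10.0
    u_max: float = 1.0
    f_hz: Optional[float] = None
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int = 0
    popsize: int = 10
    maxiter: int = 25
    polish_maxfev: int = 120
    solver: dict = field(default_factory=lambda: dict(SEARCH_SOLVER))
    base_config: Optional[RunConfig] = None

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite, positive, ordered")
        for name in ("c3", "D"):
            lo, hi = self.bounds[name]
            if not (0 < lo and hi < 1):
                raise ValueError(f"bounds for {name!r} must lie inside (0, 1)")

    @property
    def param_names(self) -> tuple:
        if self.f_hz is None:
            return ("c1", "c2", "c3", "fd", "D")
        return ("c1", "c2", "c3", "D")


@dataclass
class OptimizationResult:
    params: dict
    P_star: float
    n_evaluations: int
    trace: np.ndarray  # best-so-far P* after each evaluation
    evaluations: list  # (params dict, P*) in evaluation order
    active_bounds: dict  # param -> "lower" | "upper" | None


def _config_for(params: dict, spec: OptimizationSpec) -> RunConfig:
    base = spec.base_config if spec.base_config is not None else RunConfig()
    fd = params.get("fd", spec.f_hz)
    return dataclasses.replace(
        base,
        eps0_dot_per_s=spec.eps0_dot,
        u_max=spec.u_max,
        f_hz=spec.f_hz,
        fd_hz=fd,
        c1=params["c1"],
        c2=params["c2"],
        c3=params["c3"],
        duty_cycle=params["D"],
        tau_act_s=base.tau_act_s,
    )


def objective(params: dict, spec: OptimizationSpec) -> float:
    """Mass-specific power P* (W/kg) of one candidate; penalized on blow-up."""
    cfg = _config_for(params, spec)
    try:
        result = simulate_config(cfg, **spec.solver)
    except (SimulationBlowupError, ValueError):
        return PENALTY
    if not np.isfinite(result.P_star):
        return PENALTY
    return result.P_star


def _encode_bounds(spec: OptimizationSpec):
    enc = []
    for name in spec.param_names:
        lo, hi = spec.bounds[name]
        if name == "c2":
            enc.append((math.log10(lo), math.log10(hi)))
        else:
            enc.append((lo, hi))
    return enc


def _decode(vec, spec: OptimizationSpec) -> dict:
    params = {}
    for name, value in zip(spec.param_names, vec):
        params[name] = 10.0 ** value if name == "c2" else float(value)
    return params


def optimize_linkage(spec: OptimizationSpec) -> OptimizationResult:
    """Seeded global search + local polish; deterministic for a fixed seed."""
    bounds = _encode_bounds(spec)
    evaluations = []
    trace = []
    best = -math.inf

    def neg_p(vec):
        nonlocal best
        params = _decode(vec, spec)
        value = objective(params, spec)
        evaluations.append((params, value))
        best = max(best, value)
        trace.append(best)
        return -value

    de = differential_evolution(
        neg_p,
        bounds=bounds,
        seed=spec.seed,
        popsize=spec.popsize,
        maxiter=spec.maxiter,
        tol=1e-8,
        polish=False,
    )
    polished = minimize(
        neg_p,
        de.x,
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxfev": spec.polish_maxfev, "xatol": 1e-4, "fatol": 1e-6},
    )
    if not evaluations:
        raise RuntimeError("optimization produced no evaluations")
    best_params, best_value = max(evaluations, key=lambda pv: pv[1])
    if best_value <= PENALTY:
        raise RuntimeError("optimization failed: every candidate was penalized")
    active = {}
    for name in spec.param_names:
        lo, hi = spec.bounds[name]
        val = best_params[name]
        span = hi - lo
        if val - lo < 1e-3 * span:
            active[name] = "lower"
        elif hi - val < 1e-3 * span:
            active[name] = "upper"
        else:
            active[name] = None
    return OptimizationResult(
        params=best_params,
        P_star=best_value,
        n_evaluations=len(evaluations),
        trace=np.asarray(trace),
        evaluations=evaluations,
        active_bounds=active,
    )
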