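"""Geometric scaling with preserved kinematic and dynamic similarity.

With maximum isometric stress, density and mass-specific power held constant
across sizes, every scale factor follows from the length scale λ of the
muscle: forces scale with λ², muscle mass with λ³, both time scales are 1,
and the oscillator constants m, b, k and its resting length x0 all scale
with λ. Two systems built this way share the three dimensionless groups

    g1 = m x0 / (F0 t_h²),  g2 = b t_h / m,  g3 = k t_h² / m,

so their dimensionless trajectories coincide and the mass-specific power P*
is size-invariant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import TYPE_CHECKING, Union

import numpy as np
import pandas as pd

from .plant import OscillatorLoad

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig

__all__ = [
    "ScaleFactors",
    "scale_factors",
    "dimensionless_groups",
    "apply_scaling",
    "nondimensionalize",
    "check_similarity",
]

#: muscle and oscillator time scales (s); size-independent
T_MUSCLE = 1.0
T_OSCILLATOR = 1.0


@dataclass(frozen=True)
class ScaleFactors:
    """Multiplicative factors between a scaled and a root system."""

    lambda_l0: float
    lambda_sigma0: float = 1.0
    lambda_rho: float = 1.0
    lambda_Pstar: float = 1.0
    lambda_tm: float = 1.0
    lambda_th: float = 1.0

    @property
    def lambda_x0(self) -> float:
        return self.lambda_l0

    @property
    def lambda_F0(self) -> float:
        return self.lambda_l0 ** 2

    @property
    def lambda_mm(self) -> float:
        return self.lambda_l0 ** 3

    @property
    def lambda_m(self) -> float:
        return self.lambda_l0

    @property
    def lambda_b(self) -> float:
        return self.lambda_l0

    @property
    def lambda_k(self) -> float:
        return self.lambda_l0


def scale_factors(lambda_l0: float) -> ScaleFactors:
    """Full similarity-preserving factor set for a length scale λ."""
    if not lambda_l0 > 0:
        raise ValueError(f"lambda_l0 must be positive, got {lambda_l0}")
    return ScaleFactors(lambda_l0=float(lambda_l0))


def dimensionless_groups(load: OscillatorLoad, F0: float, t_h: float = T_OSCILLATOR) -> dict:
    """The three groups that must match for dynamic similarity."""
    return {
        "g1": load.m * load.x0 / (F0 * t_h ** 2),
        "g2": load.b * t_h / load.m,
        "g3": load.k * t_h ** 2 / load.m,
    }


def apply_scaling(config: "RunConfig", factors: Union[ScaleFactors, float]) -> "RunConfig":
    """Return a root-level config rescaled by λ (its own lambda_l0 reset to 1).

    Lengths (l0, and x0/l_tot through the geometry) scale with λ. With stress
    and density constant, F0 rescales with λ² automatically. The linkage
    fraction c2 = m/F0 carries units kg/N and must scale with 1/λ so that the
    oscillator mass scales with λ; c1, c3, fd and all time-domain parameters
    are unchanged. An explicit oscillator load has m, b, k, x0 scaled by λ.
    """
    if not isinstance(factors, ScaleFactors):
        factors = scale_factors(float(factors))
    lam = factors.lambda_l0
    changes = {"l0_m": config.l0_m * lam, "lambda_l0": 1.0}
    if config.explicit_load is not None:
        changes["explicit_load"] = {
            "m": config.explicit_load["m"] * factors.lambda_m,
            "k": config.explicit_load["k"] * factors.lambda_k,
            "b": config.explicit_load["b"] * factors.lambda_b,
            "x0": config.explicit_load["x0"] * factors.lambda_x0,
        }
    else:
        changes["c2"] = config.c2 / lam
    return dataclasses.replace(config, **changes)


def nondimensionalize(result) -> dict:
    """Dimensionless channels of the last completed cycle of a simulation.

    Returns arrays on the cycle's own uniform phase grid: t̂ (cycle phase),
    l̂ = l_m/l0, v̂ = v_m/(l0 ε̇0), Δx̂ = (x - x0)/x0, F̂ = F_m/F0, â, and
    û = u/u_max.
    """
    mus, load, prot = result.muscle, result.load, result.protocol
    i = -1
    t = result.t[i]
    return {
        "t_hat": (t - t[0]) * prot.f,
        "l_hat": result.l_m[i] / mus.l0,
        "v_hat": result.v_m[i] / (mus.l0 * mus.eps0_dot),
        "dx_hat": (result.x[i] - load.x0) / load.x0,
        "F_hat": result.F_m[i] / mus.F0,
        "a_hat": result.a[i],
        "u_hat": result.u[i] / prot.u_max,
    }


def check_similarity(root_result, scaled_result, tol: float = 1e-6) -> pd.DataFrame:
    """Compare two runs channel-by-channel in dimensionless form.

    Both runs must use the same excitation protocol (f, D, u_max). The last
    cycle of each run is nondimensionalized and resampled onto a common
    uniform phase grid by monotone interpolation; the report lists the
    maximum absolute deviation per channel plus the relative deviation of P*,
    each with a pass/fail flag against ``tol``.
    """
    pr, ps = root_result.protocol, scaled_result.protocol
    if (pr.f, pr.D, pr.u_max) != (ps.f, ps.D, ps.u_max):
        raise ValueError("similarity comparison requires identical excitation protocols")
    a = nondimensionalize(root_result)
    b = nondimensionalize(scaled_result)
    grid = np.linspace(0.0, 1.0, 2049)
    rows = []
    for name in ("l_hat", "v_hat", "dx_hat", "F_hat", "a_hat", "u_hat"):
        ya = np.interp(grid, a["t_hat"], a[name])
        yb = np.interp(grid, b["t_hat"], b[name])
        dev = float(np.max(np.abs(ya - yb)))
        rows.append((name, dev, dev <= tol))
    p_dev = abs(scaled_result.P_star - root_result.P_star) / max(
        abs(root_result.P_star), 1e-300
    )
    rows.append(("P_star_rel", float(p_dev), p_dev <= tol))
    return pd.DataFrame(rows, columns=["channel", "max_abs_deviation", "passed"])
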