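"""Deterministic fixture generation.

Everything every other module needs for testing is generated here from a
seed: digitized-style curve data sampled from the default curves (optionally
with Gaussian ordinate noise), a linear-plant configuration whose steady
state has a closed form, a synthetic elliptical work-loop trace with known
enclosed area, and the 16-condition simulation grid (cycle frequency ×
fibre speed × excitation level × geometric scale).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, config_to_dict
from .curves import BezierCurveSet

__all__ = ["FixtureSpec", "generate_fixture", "condition_grid", "sample_curve_data"]

FIXTURE_KINDS = ("curve_data", "linear_plant", "ellipse_loop", "table3_grid")

#: (f Hz, eps0_dot 1/s) pairings of the published simulation grid; each is
#: crossed with u_max in {0.1, 1} and lambda_l0 in {1, 10} -> 16 conditions
GRID_F_EPS0 = ((0.5, 5.0), (1.0, 5.0), (1.0, 10.0), (2.0, 10.0))


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    noise: float = 0.0
    n: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"kind must be one of {FIXTURE_KINDS}, got {self.kind!r}")
        if self.noise < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.n < 8:
            raise ValueError("need at least 8 points per fixture")


def condition_grid() -> list:
    """The 16 (f, eps0_dot, u_max, lambda_l0) condition dicts."""
    grid = []
    for f, eps0 in GRID_F_EPS0:
        for u_max in (0.1, 1.0):
            for lam in (1.0, 10.0):
                grid.append(
                    {"f_hz": f, "eps0_dot_per_s": eps0, "u_max": u_max, "lambda_l0": lam}
                )
    return grid


def sample_curve_data(
    curve, domain: tuple, n: int, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2) array of (abscissa, ordinate) pairs sampled uniformly over the
    domain with Gaussian ordinate noise."""
    xs = np.linspace(domain[0], domain[1], n)
    ys = curve.evaluate(xs)
    if noise > 0:
        ys = ys + rng.normal(0.0, noise, size=ys.shape)
    return np.column_stack([xs, ys])


def _write_json(path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def generate_fixture(spec: FixtureSpec, outdir) -> list:
    """Write the requested fixture files; returns the list of paths.

    Outputs are fully determined by the seed (same seed, byte-identical
    files).
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    paths = []

    if spec.kind == "curve_data":
        curves = BezierCurveSet.default()
        domains = {
            "force_velocity": (-1.0, 1.0),
            "active_force_length": (0.45, 1.65),
            "passive_force_length": (0.7, 1.65),
        }
        for kind, domain in domains.items():
            data = sample_curve_data(
                getattr(curves, kind), domain, spec.n, spec.noise, rng
            )
            path = os.path.join(str(outdir), f"{kind}_data.csv")
            pd.DataFrame(data, columns=["abscissa", "ordinate"]).to_csv(
                path, index=False, lineterminator="\n"
            )
            paths.append(path)

    elif spec.kind == "linear_plant":
        # quarter excitation keeps the unbounded linear plant's motion inside
        # the system length (constant curves remove the force-length collapse
        # that normally limits travel)
        cfg = RunConfig(
            curves_mode="constant",
            curves_params={"fv": 1.0, "fa": 1.0, "fp": 0.0},
            activation_mode="instantaneous",
            u_max=0.25,
            seed=spec.seed,
        )
        path = os.path.join(str(outdir), "linear_plant_config.json")
        _write_json(path, config_to_dict(cfg))
        paths.append(path)

    elif spec.kind == "ellipse_loop":
        # l_m = L + A cos(theta), F_m = F + B sin(theta): enclosed area pi*A*B
        L, A, F, B = 0.02, 0.002, 5e-3, 2e-3
        theta = np.linspace(0.0, 2.0 * np.pi, spec.n)
        df = pd.DataFrame(
            {
                "t_s": theta / (2.0 * np.pi),
                "l_m_m": L + A * np.cos(theta),
                "F_m_N": F + B * np.sin(theta),
            }
        )
        path = os.path.join(str(outdir), "ellipse_loop.csv")
        df.to_csv(path, index=False, lineterminator="\n")
        paths.append(path)

    elif spec.kind == "table3_grid":
        for i, cond in enumerate(condition_grid()):
            cfg = RunConfig(
                f_hz=cond["f_hz"],
                eps0_dot_per_s=cond["eps0_dot_per_s"],
                u_max=cond["u_max"],
                lambda_l0=cond["lambda_l0"],
                seed=spec.seed,
            )
            path = os.path.join(str(outdir), f"condition_{i:02d}.json")
            _write_json(path, config_to_dict(cfg))
            paths.append(path)

    return paths
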