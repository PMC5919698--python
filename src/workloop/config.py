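"""Run configuration: defaults, JSON loading/validation, system assembly.

A single JSON file (nested sections ``muscle``, ``activation``, ``protocol``,
``linkage`` or ``load``, ``curves``, ``solver``, plus top-level ``lambda_l0``
and ``seed``) describes one simulation. Every key has a physically motivated
default, so an empty config runs the root model. Unknown keys raise a
validation error naming the key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .activation import ActivationParams, ExcitationProtocol, activation_time_constant
from .curves import BezierCurveSet, ConstantCurveSet, curve_set_from_csv
from .plant import (
    LinkageParams,
    MuscleProperties,
    OscillatorLoad,
    build_oscillator,
    derive_geometry,
)

__all__ = [
    "RunConfig",
    "System",
    "ConfigError",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "save_config",
    "build_system",
    "simulate_config",
    "DEFAULT_LINKAGE",
    "DEFAULT_DUTY_CYCLE",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


#: Root-model linkage fractions and driving frequency, frozen from one run of
#: this package's global optimizer (optimize.optimize_linkage, seed 2018,
#: budget ~4000 evaluations) for a fast muscle (eps0_dot = 10 1/s, u_max = 1),
#: mirroring how the root oscillator is tied to the muscle. See docs/methods.md.
DEFAULT_LINKAGE = {
    "c1": 1.0750,
    "c2": 0.1704,
    "c3": 0.3089,
    "fd_hz": 1.8316,
}
#: Optimized excitation duty cycle from the same run.
DEFAULT_DUTY_CYCLE = 0.5859


@dataclass(frozen=True)
class RunConfig:
    """Validated, flat view of one run's parameters (SI units)."""

    # muscle
    l0_m: float = 0.02
    sigma0_pa: float = 225000.0
    rho_kg_m3: float = 1060.0
    aspect_ratio: float = 100.0
    eps0_dot_per_s: float = 10.0
    l_tot_over_l0: float = 2.0
    # activation
    tau_act_s: Optional[float] = None  # None -> by eps0_dot
    beta: float = 0.6
    # protocol
    f_hz: Optional[float] = None  # None -> fd
    duty_cycle: float = DEFAULT_DUTY_CYCLE
    u_max: float = 1.0
    # linkage (exclusive with explicit_load)
    c1: float = DEFAULT_LINKAGE["c1"]
    c2: float = DEFAULT_LINKAGE["c2"]
    c3: float = DEFAULT_LINKAGE["c3"]
    fd_hz: Optional[float] = None  # None -> f_hz, or the optimized default
    explicit_load: Optional[dict] = None  # {"m","k","b","x0"} in SI units
    # curves
    curves_mode: str = "default"  # "default" | "constant" | "csv"
    curves_params: dict = field(default_factory=dict)
    # scaling
    lambda_l0: float = 1.0
    # solver (tolerances chosen so dimensionless traces of geometrically
    # similar runs agree to better than 1e-6; see docs/methods.md)
    rtol: float = 1e-9
    atol: float = 1e-12
    samples_per_cycle: int = 2048
    n_max_cycles: int = 100
    min_cycles: int = 8
    work_rel_tol: float = 1e-6
    activation_mode: str = "ode"
    seed: int = 0

    @property
    def resolved_fd_hz(self) -> float:
        if self.fd_hz is not None:
            return self.fd_hz
        if self.f_hz is not None:
            return self.f_hz
        return DEFAULT_LINKAGE["fd_hz"]

    @property
    def resolved_f_hz(self) -> float:
        return self.f_hz if self.f_hz is not None else self.resolved_fd_hz

    @property
    def resolved_tau_act_s(self) -> float:
        if self.tau_act_s is not None:
            return self.tau_act_s
        return activation_time_constant(self.eps0_dot_per_s)


class System(NamedTuple):
    """Assembled simulation inputs."""

    muscle: MuscleProperties
    curves: object
    load: OscillatorLoad
    protocol: ExcitationProtocol
    act_params: ActivationParams
    solver: dict


_SECTION_KEYS = {
    "muscle": {
        "l0_m": "l0_m",
        "sigma0_pa": "sigma0_pa",
        "rho_kg_m3": "rho_kg_m3",
        "aspect_ratio": "aspect_ratio",
        "eps0_dot_per_s": "eps0_dot_per_s",
        "l_tot_over_l0": "l_tot_over_l0",
    },
    "activation": {"tau_act_s": "tau_act_s", "beta": "beta"},
    "protocol": {"f_hz": "f_hz", "duty_cycle": "duty_cycle", "u_max": "u_max"},
    "linkage": {"c1": "c1", "c2": "c2", "c3": "c3", "fd_hz": "fd_hz"},
    "solver": {
        "rtol": "rtol",
        "atol": "atol",
        "samples_per_cycle": "samples_per_cycle",
        "n_max_cycles": "n_max_cycles",
        "min_cycles": "min_cycles",
        "work_rel_tol": "work_rel_tol",
        "activation_mode": "activation_mode",
    },
}


def config_from_dict(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a (possibly empty) nested dict."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a JSON object")
    kwargs = {}
    known_top = set(_SECTION_KEYS) | {"load", "curves", "lambda_l0", "seed"}
    for key in raw:
        if key not in known_top:
            raise ConfigError(f"unknown config section or key: {key!r}")
    for section, mapping in _SECTION_KEYS.items():
        sub = raw.get(section, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"config section {section!r} must be an object")
        for k, v in sub.items():
            if k not in mapping:
                raise ConfigError(f"unknown key {k!r} in section {section!r}")
            kwargs[mapping[k]] = v
    if "load" in raw:
        if "linkage" in raw:
            raise ConfigError("provide exactly one of 'linkage' or 'load', not both")
        sub = raw["load"]
        need = {"m", "k", "b", "x0"}
        if not isinstance(sub, dict) or set(sub) != need:
            raise ConfigError(f"'load' section must have exactly the keys {sorted(need)}")
        kwargs["explicit_load"] = {k: float(v) for k, v in sub.items()}
    if "curves" in raw:
        sub = dict(raw["curves"])
        mode = sub.pop("mode", "default")
        if mode not in ("default", "constant", "csv"):
            raise ConfigError(f"unknown curves mode {mode!r}")
        kwargs["curves_mode"] = mode
        kwargs["curves_params"] = sub
    if "lambda_l0" in raw:
        kwargs["lambda_l0"] = float(raw["lambda_l0"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    cfg = RunConfig(**kwargs)
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    positive = [
        "l0_m", "sigma0_pa", "rho_kg_m3", "aspect_ratio", "eps0_dot_per_s",
        "beta", "c1", "c2", "c3", "lambda_l0", "rtol", "atol",
    ]
    for name in positive:
        if not getattr(cfg, name) > 0:
            raise ConfigError(f"config key {name!r} must be positive")
    if not 0 < cfg.duty_cycle < 1:
        raise ConfigError(f"config key 'duty_cycle' must lie in (0, 1), got {cfg.duty_cycle}")
    if not 0 < cfg.u_max <= 1:
        raise ConfigError(f"config key 'u_max' must lie in (0, 1], got {cfg.u_max}")
    if not cfg.c3 < 1:
        raise ConfigError(f"config key 'c3' must be below 1, got {cfg.c3}")
    if not cfg.l_tot_over_l0 > 1:
        raise ConfigError("config key 'l_tot_over_l0' must exceed 1")
    if cfg.tau_act_s is not None and not cfg.tau_act_s > 0:
        raise ConfigError("config key 'tau_act_s' must be positive")
    if cfg.f_hz is not None and not cfg.f_hz > 0:
        raise ConfigError("config key 'f_hz' must be positive")
    if cfg.fd_hz is not None and not cfg.fd_hz > 0:
        raise ConfigError("config key 'fd_hz' must be positive")
    if cfg.activation_mode not in ("ode", "instantaneous"):
        raise ConfigError(f"unknown activation_mode {cfg.activation_mode!r}")
    if cfg.curves_mode == "csv":
        import os

        for key in ("force_velocity", "active_force_length", "passive_force_length"):
            path = cfg.curves_params.get(key)
            if path is None:
                raise ConfigError(f"curves csv mode needs key {key!r}")
            if not os.path.exists(path):
                raise ConfigError(f"curve control-point file not found: {path}")


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config file {path} is not valid JSON: {exc}") from exc
    return config_from_dict(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    """Nested-dict form of a config (inverse of :func:`config_from_dict`)."""
    out = {
        "muscle": {
            "l0_m": cfg.l0_m,
            "sigma0_pa": cfg.sigma0_pa,
            "rho_kg_m3": cfg.rho_kg_m3,
            "aspect_ratio": cfg.aspect_ratio,
            "eps0_dot_per_s": cfg.eps0_dot_per_s,
            "l_tot_over_l0": cfg.l_tot_over_l0,
        },
        "activation": {"tau_act_s": cfg.tau_act_s, "beta": cfg.beta},
        "protocol": {"f_hz": cfg.f_hz, "duty_cycle": cfg.duty_cycle, "u_max": cfg.u_max},
        "curves": {"mode": cfg.curves_mode, **cfg.curves_params},
        "solver": {
            "rtol": cfg.rtol,
            "atol": cfg.atol,
            "samples_per_cycle": cfg.samples_per_cycle,
            "n_max_cycles": cfg.n_max_cycles,
            "min_cycles": cfg.min_cycles,
            "work_rel_tol": cfg.work_rel_tol,
            "activation_mode": cfg.activation_mode,
        },
        "lambda_l0": cfg.lambda_l0,
        "seed": cfg.seed,
    }
    if cfg.explicit_load is not None:
        out["load"] = dict(cfg.explicit_load)
    else:
        out["linkage"] = {"c1": cfg.c1, "c2": cfg.c2, "c3": cfg.c3, "fd_hz": cfg.fd_hz}
    # drop None values so a round-trip uses defaults again
    for section in list(out):
        if isinstance(out[section], dict):
            out[section] = {k: v for k, v in out[section].items() if v is not None}
    return out


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config_to_dict(cfg), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _build_curves(cfg: RunConfig):
    if cfg.curves_mode == "default":
        f_max = cfg.curves_params.get("f_max_ecc")
        return BezierCurveSet.default() if f_max is None else BezierCurveSet.default(f_max)
    if cfg.curves_mode == "constant":
        return ConstantCurveSet(
            fv=cfg.curves_params.get("fv", 1.0),
            fa=cfg.curves_params.get("fa", 1.0),
            fp=cfg.curves_params.get("fp", 0.0),
        )
    return curve_set_from_csv(
        cfg.curves_params["force_velocity"],
        cfg.curves_params["active_force_length"],
        cfg.curves_params["passive_force_length"],
    )


def build_system(cfg: RunConfig) -> System:
    """Assemble muscle, curves, load and protocol, applying lambda_l0."""
    from .scaling import apply_scaling  # local import to avoid a cycle

    if cfg.lambda_l0 != 1.0:
        cfg = apply_scaling(cfg, cfg.lambda_l0)
    muscle = derive_geometry(
        cfg.l0_m, cfg.sigma0_pa, cfg.rho_kg_m3, cfg.aspect_ratio, cfg.eps0_dot_per_s
    )
    l_tot = cfg.l_tot_over_l0 * cfg.l0_m
    if cfg.explicit_load is not None:
        load = OscillatorLoad(l_tot=l_tot, **cfg.explicit_load)
    else:
        linkage = LinkageParams(c1=cfg.c1, c2=cfg.c2, c3=cfg.c3, fd=cfg.resolved_fd_hz)
        load = build_oscillator(linkage, muscle.F0, l_tot, cfg.l0_m)
    protocol = ExcitationProtocol(f=cfg.resolved_f_hz, D=cfg.duty_cycle, u_max=cfg.u_max)
    act_params = ActivationParams(tau_act=cfg.resolved_tau_act_s, beta=cfg.beta)
    solver = {
        "rtol": cfg.rtol,
        "atol": cfg.atol,
        "samples_per_cycle": cfg.samples_per_cycle,
        "n_max_cycles": cfg.n_max_cycles,
        "min_cycles": cfg.min_cycles,
        "work_rel_tol": cfg.work_rel_tol,
        "activation_mode": cfg.activation_mode,
    }
    return System(muscle, _build_curves(cfg), load, protocol, act_params, solver)


def simulate_config(cfg: RunConfig, **overrides):
    """Run a configured simulation (overrides are solver keyword arguments)."""
    from .simulate import run_forward

    sys = build_system(cfg)
    solver = {**sys.solver, **overrides}
    return run_forward(
        sys.muscle,
        sys.curves,
        sys.load,
        sys.protocol,
        sys.act_params,
        n_max_cycles=solver["n_max_cycles"],
        min_cycles=solver["min_cycles"],
        work_rel_tol=solver["work_rel_tol"],
        samples_per_cycle=solver["samples_per_cycle"],
        rtol=solver["rtol"],
        atol=solver["atol"],
        activation_mode=solver["activation_mode"],
    )
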