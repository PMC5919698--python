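"""Constrained cubic Bézier curves for muscle intrinsic properties.

The force–velocity and active force–length relationships of the contractile
element are each represented by two cubic Bézier segments joined with a
continuous first derivative; the passive force–length relationship of the
parallel elastic element is a single cubic segment with a linear extension
at long lengths. All curves are dimensionless: forces in units of the maximum
isometric force F0, velocities in units of the maximum shortening strain
rate, lengths in units of the optimal length l0.

Control-point abscissas are required to be non-decreasing, which makes the
abscissa component of each parametric segment monotone, so a query abscissa
maps to a unique curve parameter. Physiological constraints (anchor points,
matched or zero end slopes, symmetry of the concentric limb about F = -v)
fix most control-point coordinates; the remaining free coordinates are either
given, taken from package defaults, or fitted to digitized data.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

__all__ = [
    "BezierSegment",
    "Extrapolation",
    "CurveDef",
    "BezierCurveSet",
    "ConstantCurve",
    "ConstantCurveSet",
    "CurveFitResult",
    "CurveConstructionError",
    "FitError",
    "eval_segment",
    "eval_curve",
    "build_force_velocity",
    "build_active_force_length",
    "build_passive_force_length",
    "fit_curve",
    "curve_to_csv",
    "curve_from_csv",
    "curve_set_to_csv",
    "curve_set_from_csv",
]


class CurveConstructionError(ValueError):
    """A requested curve violates one of its defining constraints."""


class FitError(RuntimeError):
    """Curve fitting cannot proceed (e.g. degenerate data)."""


#: absolute tolerance on the abscissa when inverting a segment
INVERSION_TOL = 1e-12


@dataclass(frozen=True)
class BezierSegment:
    """A single cubic Bézier segment with monotone abscissas.

    Parameters
    ----------
    control_points
        Exactly four ``(abscissa, ordinate)`` pairs with non-decreasing
        abscissas.
    """

    control_points: tuple

    def __post_init__(self):
        pts = tuple((float(x), float(y)) for x, y in self.control_points)
        if len(pts) != 4:
            raise CurveConstructionError(
                f"cubic segment needs exactly 4 control points, got {len(pts)}"
            )
        xs = [p[0] for p in pts]
        if any(b < a for a, b in zip(xs, xs[1:])):
            raise CurveConstructionError(
                f"control-point abscissas must be non-decreasing, got {xs}"
            )
        object.__setattr__(self, "control_points", pts)

    # power-basis coefficients of the parametric cubic x(s), y(s), s in [0, 1]
    @cached_property
    def _coeffs(self):
        (x0, y0), (x1, y1), (x2, y2), (x3, y3) = self.control_points
        cx = (x0, 3.0 * (x1 - x0), 3.0 * (x0 - 2.0 * x1 + x2), x3 - x0 + 3.0 * (x1 - x2))
        cy = (y0, 3.0 * (y1 - y0), 3.0 * (y0 - 2.0 * y1 + y2), y3 - y0 + 3.0 * (y1 - y2))
        return cx, cy

    @property
    def x_start(self) -> float:
        return self.control_points[0][0]

    @property
    def x_end(self) -> float:
        return self.control_points[3][0]

    def _x(self, s):
        c = self._coeffs[0]
        return ((c[3] * s + c[2]) * s + c[1]) * s + c[0]

    def _y(self, s):
        c = self._coeffs[1]
        return ((c[3] * s + c[2]) * s + c[1]) * s + c[0]

    def _dxds(self, s):
        c = self._coeffs[0]
        return (3.0 * c[3] * s + 2.0 * c[2]) * s + c[1]

    def parameter_at(self, x: float, tol: float = INVERSION_TOL) -> float:
        """Invert abscissa -> curve parameter by safeguarded Newton iteration.

        Monotone abscissas make the root unique; bisection is used whenever a
        Newton step leaves the current bracket or the slope vanishes.
        """
        if x < self.x_start - 1e-9 or x > self.x_end + 1e-9:
            raise ValueError(
                f"abscissa {x!r} outside segment span "
                f"[{self.x_start}, {self.x_end}]"
            )
        if x <= self.x_start:
            return 0.0
        if x >= self.x_end:
            return 1.0
        lo, hi = 0.0, 1.0
        span = self.x_end - self.x_start
        s = (x - self.x_start) / span
        # converge to rounding level (well inside the documented tolerance)
        target = min(tol, 1e-15 * max(1.0, abs(x)))
        for _ in range(200):
            fx = self._x(s) - x
            if abs(fx) <= target or hi - lo < 1e-16:
                return s
            if fx > 0.0:
                hi = s
            else:
                lo = s
            d = self._dxds(s)
            s_new = s - fx / d if d > 0.0 else 0.5 * (lo + hi)
            if not (lo < s_new < hi):
                s_new = 0.5 * (lo + hi)
            s = s_new
        return s

    def _parameters_at(self, xs: np.ndarray) -> np.ndarray:
        # vectorized bisection: 60 halvings shrink the bracket below 1e-18
        lo = np.zeros_like(xs)
        hi = np.ones_like(xs)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            above = self._x(mid) > xs
            hi = np.where(above, mid, hi)
            lo = np.where(above, lo, mid)
        return 0.5 * (lo + hi)

    def evaluate(self, x: float) -> float:
        """Ordinate at the given abscissa (scalar)."""
        return self._y(self.parameter_at(x))

    def evaluate_many(self, xs: np.ndarray) -> np.ndarray:
        xs = np.asarray(xs, dtype=float)
        return self._y(self._parameters_at(np.clip(xs, self.x_start, self.x_end)))


def eval_segment(segment: BezierSegment, abscissa: float) -> float:
    """Evaluate one segment at an abscissa inside its span."""
    return segment.evaluate(abscissa)


@dataclass(frozen=True)
class Extrapolation:
    """Rule applied outside the curve domain.

    ``mode`` is ``"constant"`` (hold ``value``) or ``"linear"`` (extend from
    the domain edge with slope ``value``).
    """

    mode: str
    value: float

    def __post_init__(self):
        if self.mode not in ("constant", "linear"):
            raise CurveConstructionError(f"unknown extrapolation mode {self.mode!r}")


@dataclass(frozen=True)
class CurveDef:
    """A composite curve: joined Bézier segments plus extrapolation rules."""

    segments: tuple
    left: Extrapolation
    right: Extrapolation

    def __post_init__(self):
        segs = tuple(self.segments)
        if not segs:
            raise CurveConstructionError("curve needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            pa = a.control_points[3]
            pb = b.control_points[0]
            if pa != pb:
                raise CurveConstructionError(
                    f"segments must join continuously: {pa} != {pb}"
                )
        object.__setattr__(self, "segments", segs)

    @property
    def domain(self) -> tuple:
        return (self.segments[0].x_start, self.segments[-1].x_end)

    def _edge_value(self, side: str) -> float:
        if side == "left":
            return self.segments[0].control_points[0][1]
        return self.segments[-1].control_points[3][1]

    def __call__(self, x: float) -> float:
        xmin, xmax = self.domain
        if x < xmin:
            if self.left.mode == "constant":
                return self.left.value
            return self._edge_value("left") + self.left.value * (x - xmin)
        if x > xmax:
            if self.right.mode == "constant":
                return self.right.value
            return self._edge_value("right") + self.right.value * (x - xmax)
        # inside the domain the left-most containing segment claims joins
        for seg in self.segments:
            if x <= seg.x_end:
                return seg.evaluate(min(max(x, seg.x_start), seg.x_end))
        return self.segments[-1].evaluate(xmax)

    def evaluate(self, xs) -> np.ndarray:
        """Vectorized evaluation with extrapolation; accepts any array-like."""
        xs = np.asarray(xs, dtype=float)
        scalar = xs.ndim == 0
        xs = np.atleast_1d(xs)
        out = np.empty_like(xs)
        xmin, xmax = self.domain
        left_m = xs < xmin
        right_m = xs > xmax
        if self.left.mode == "constant":
            out[left_m] = self.left.value
        else:
            out[left_m] = self._edge_value("left") + self.left.value * (xs[left_m] - xmin)
        if self.right.mode == "constant":
            out[right_m] = self.right.value
        else:
            out[right_m] = self._edge_value("right") + self.right.value * (xs[right_m] - xmax)
        todo = ~(left_m | right_m)
        for seg in self.segments:
            m = todo & (xs <= seg.x_end)
            if np.any(m):
                out[m] = seg.evaluate_many(xs[m])
                todo &= ~m
        if np.any(todo):  # numerical fuzz at the right edge
            out[todo] = self._edge_value("right")
        return out[0] if scalar else out


def eval_curve(curve: CurveDef, abscissa: float) -> float:
    """Evaluate a composite curve anywhere on the real line."""
    return curve(abscissa)


# ---------------------------------------------------------------------------
# constrained builders
# ---------------------------------------------------------------------------

#: default free parameters (see docs/methods.md for their meaning)
DEFAULT_FV_PARAMS = (-0.35, 0.125, 0.05, 0.40)
DEFAULT_FL_PARAMS = (0.73, 0.82, 1.15, 1.45)
DEFAULT_FP_PARAMS = (1.10, 1.50, 0.12, 0.50)
DEFAULT_F_MAX_ECC = 1.5
DEFAULT_ASCENDING_END = 0.45
DEFAULT_DESCENDING_END = 1.65
DEFAULT_SLACK_LENGTH = 0.70
DEFAULT_EXTRAP_START = 1.65

#: box bounds for the free parameters used when fitting; every point of each
#: box yields a feasible (monotone-abscissa) curve
FV_FIT_BOUNDS = ((-0.90, -0.20), (0.01, 0.19), (0.01, 0.30), (0.31, 0.90))
FL_FIT_BOUNDS = ((0.50, 0.74), (0.75, 0.99), (1.01, 1.30), (1.31, 1.64))
FP_FIT_BOUNDS = ((0.75, 1.20), (1.25, 1.60), (0.01, 0.45), (0.05, 1.50))


def build_force_velocity(
    f_max_ecc: float = DEFAULT_F_MAX_ECC,
    free_params: Sequence[float] = DEFAULT_FV_PARAMS,
) -> CurveDef:
    """Build the normalized force–velocity curve.

    Two cubic segments join at (0, 1): the concentric limb runs from (-1, 0)
    and is symmetric about the line F = -v (reflecting its control polygon
    across that line maps it onto itself); the eccentric limb rises to the
    plateau ``f_max_ecc`` at v = +1 with zero end slope, and its initial slope
    matches the concentric limb's slope at v = 0. Outside [-1, 1] the force is
    held at 0 and ``f_max_ecc``. The concentric end at v = -1 is the one point
    where the first derivative is allowed to be discontinuous.

    ``free_params`` are ``(p, q, e1x, e2x)``: the concentric inner control
    point is (p, q) (its mirror (-q, -p) is implied), and ``e1x``/``e2x`` are
    the abscissas of the two inner eccentric control points.
    """
    p, q, e1x, e2x = (float(v) for v in free_params)
    if not f_max_ecc > 1.0:
        raise CurveConstructionError("f_max_ecc must exceed 1 (eccentric plateau above F0)")
    if q <= 0.0:
        raise CurveConstructionError("concentric inner ordinate q must be positive")
    if not (-1.0 <= p <= -q <= 0.0):
        raise CurveConstructionError(
            "concentric inner point must satisfy -1 <= p <= -q <= 0 for monotone abscissas"
        )
    if not (0.0 < e1x <= e2x < 1.0):
        raise CurveConstructionError(
            "eccentric inner abscissas must satisfy 0 < e1x <= e2x < 1"
        )
    slope0 = (1.0 + p) / q  # shared slope of both limbs at v = 0
    concentric = BezierSegment(((-1.0, 0.0), (p, q), (-q, -p), (0.0, 1.0)))
    eccentric = BezierSegment(
        ((0.0, 1.0), (e1x, 1.0 + slope0 * e1x), (e2x, f_max_ecc), (1.0, f_max_ecc))
    )
    return CurveDef(
        segments=(concentric, eccentric),
        left=Extrapolation("constant", 0.0),
        right=Extrapolation("constant", f_max_ecc),
    )


def build_active_force_length(
    ascending_end: float = DEFAULT_ASCENDING_END,
    descending_end: float = DEFAULT_DESCENDING_END,
    free_params: Sequence[float] = DEFAULT_FL_PARAMS,
) -> CurveDef:
    """Build the normalized active force–length curve.

    Ascending and descending cubic limbs join at the optimum (1, 1) with zero
    slope on both sides; the curve starts and ends at zero force with zero
    slope, and is zero outside [ascending_end, descending_end].

    ``free_params`` are ``(a1x, a2x, d1x, d2x)``, the inner control-point
    abscissas of the ascending and descending limbs (inner ordinates are fixed
    by the zero-slope constraints).
    """
    a1x, a2x, d1x, d2x = (float(v) for v in free_params)
    if not ascending_end < 1.0 < descending_end:
        raise CurveConstructionError("need ascending_end < 1 < descending_end")
    if not (ascending_end <= a1x <= a2x <= 1.0):
        raise CurveConstructionError(
            "ascending inner abscissas must satisfy ascending_end <= a1x <= a2x <= 1"
        )
    if not (1.0 <= d1x <= d2x <= descending_end):
        raise CurveConstructionError(
            "descending inner abscissas must satisfy 1 <= d1x <= d2x <= descending_end"
        )
    ascending = BezierSegment(
        ((ascending_end, 0.0), (a1x, 0.0), (a2x, 1.0), (1.0, 1.0))
    )
    descending = BezierSegment(
        ((1.0, 1.0), (d1x, 1.0), (d2x, 0.0), (descending_end, 0.0))
    )
    return CurveDef(
        segments=(ascending, descending),
        left=Extrapolation("constant", 0.0),
        right=Extrapolation("constant", 0.0),
    )


def build_passive_force_length(
    slack_length: float = DEFAULT_SLACK_LENGTH,
    extrap_start: float = DEFAULT_EXTRAP_START,
    free_params: Sequence[float] = DEFAULT_FP_PARAMS,
) -> CurveDef:
    """Build the normalized passive force–length curve.

    A single cubic segment spans [slack_length, extrap_start] with zero force
    and slope at the slack length. Below slack the force is zero; beyond
    ``extrap_start`` the curve continues linearly with the slope of the chord
    between its last two control points, which equals the curve's end slope,
    so both sides are C1.

    ``free_params`` are ``(p1x, p2x, p2y, y_end)``.
    """
    p1x, p2x, p2y, y_end = (float(v) for v in free_params)
    if not slack_length < extrap_start:
        raise CurveConstructionError("need slack_length < extrap_start")
    if not (slack_length <= p1x <= p2x < extrap_start):
        raise CurveConstructionError(
            "passive inner abscissas must satisfy slack <= p1x <= p2x < extrap_start"
        )
    if p2y < 0.0 or y_end < 0.0:
        raise CurveConstructionError("passive ordinates must be non-negative")
    seg = BezierSegment(
        ((slack_length, 0.0), (p1x, 0.0), (p2x, p2y), (extrap_start, y_end))
    )
    chord_slope = (y_end - p2y) / (extrap_start - p2x)
    return CurveDef(
        segments=(seg,),
        left=Extrapolation("constant", 0.0),
        right=Extrapolation("linear", chord_slope),
    )


@dataclass(frozen=True)
class BezierCurveSet:
    """The three intrinsic curves of one muscle model."""

    force_velocity: CurveDef
    active_force_length: CurveDef
    passive_force_length: CurveDef
    f_max_ecc: float = DEFAULT_F_MAX_ECC

    @classmethod
    def default(cls, f_max_ecc: float = DEFAULT_F_MAX_ECC) -> "BezierCurveSet":
        return cls(
            force_velocity=build_force_velocity(f_max_ecc),
            active_force_length=build_active_force_length(),
            passive_force_length=build_passive_force_length(),
            f_max_ecc=f_max_ecc,
        )


class ConstantCurve:
    """Curve stub returning a fixed value everywhere (linear-plant checks)."""

    def __init__(self, value: float):
        self.value = float(value)

    def __call__(self, x):
        return self.value

    def evaluate(self, xs):
        xs = np.asarray(xs, dtype=float)
        if xs.ndim == 0:
            return self.value
        return np.full_like(xs, self.value)


@dataclass(frozen=True)
class ConstantCurveSet:
    """Curve set with constant factors; reduces the plant to a linear system."""

    fv: float = 1.0
    fa: float = 1.0
    fp: float = 0.0

    @property
    def force_velocity(self):
        return ConstantCurve(self.fv)

    @property
    def active_force_length(self):
        return ConstantCurve(self.fa)

    @property
    def passive_force_length(self):
        return ConstantCurve(self.fp)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class CurveFitResult:
    fitted_curve: CurveDef
    r_squared: float
    free_parameters: np.ndarray
    n_evaluations: int = 0


def fit_curve(
    data,
    builder: Callable[[Sequence[float]], CurveDef],
    bounds: Sequence[tuple],
    seed: int = 0,
    maxiter: int = 300,
    popsize: int = 20,
) -> CurveFitResult:
    """Fit a constrained curve to digitized (abscissa, ordinate) data.

    The free control-point coordinates are searched with seeded differential
    evolution inside box bounds chosen so every candidate is feasible,
    followed by a local polish; the objective is the coefficient of
    determination r² = 1 - SSres/SStot, maximized. Deterministic for a fixed
    seed.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FitError("data must be an (n, 2) array of (abscissa, ordinate) pairs")
    if arr.shape[0] < 8:
        raise FitError(f"need at least 8 data points, got {arr.shape[0]}")
    xs, ys = arr[:, 0], arr[:, 1]
    sstot = float(np.sum((ys - ys.mean()) ** 2))
    if sstot <= 0.0:
        raise FitError("degenerate data: all ordinates equal (SStot = 0)")
    n_eval = 0

    def neg_r2(params):
        nonlocal n_eval
        n_eval += 1
        try:
            curve = builder(tuple(params))
        except CurveConstructionError:
            return 1e6
        ssres = float(np.sum((curve.evaluate(xs) - ys) ** 2))
        return ssres / sstot - 1.0  # = -r²

    result = differential_evolution(
        neg_r2,
        bounds=list(bounds),
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=1e-12,
        polish=True,
    )
    params = np.asarray(result.x, dtype=float)
    return CurveFitResult(
        fitted_curve=builder(tuple(params)),
        r_squared=-float(neg_r2(params)),
        free_parameters=params,
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# CSV interchange (columns: segment_index, point_index, abscissa, ordinate)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["segment_index", "point_index", "abscissa", "ordinate"]

#: curve roles understood by :func:`curve_from_csv`
CURVE_KINDS = ("force_velocity", "active_force_length", "passive_force_length")


def curve_to_csv(curve: CurveDef, path) -> None:
    rows = []
    for i, seg in enumerate(curve.segments):
        for j, (x, y) in enumerate(seg.control_points):
            rows.append((i, j, x, y))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def curve_from_csv(path, kind: str) -> CurveDef:
    """Load control points and apply the extrapolation rule of the given role.

    Published control-point tables can be dropped in directly; only the
    structural invariants (4 points per segment, monotone abscissas,
    continuous joins) are enforced here.
    """
    if kind not in CURVE_KINDS:
        raise ValueError(f"kind must be one of {CURVE_KINDS}, got {kind!r}")
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"control-point CSV missing columns {missing}")
    segments = []
    for i in sorted(df["segment_index"].unique()):
        sub = df[df["segment_index"] == i].sort_values("point_index")
        pts = tuple(zip(sub["abscissa"].to_numpy(), sub["ordinate"].to_numpy()))
        segments.append(BezierSegment(pts))
    if kind == "force_velocity":
        plateau = segments[-1].control_points[3][1]
        left, right = Extrapolation("constant", 0.0), Extrapolation("constant", plateau)
    elif kind == "active_force_length":
        left, right = Extrapolation("constant", 0.0), Extrapolation("constant", 0.0)
    else:
        (x2, y2), (x3, y3) = segments[-1].control_points[2:]
        if x3 <= x2:
            raise CurveConstructionError(
                "passive curve needs distinct abscissas in its last two control points"
            )
        left = Extrapolation("constant", 0.0)
        right = Extrapolation("linear", (y3 - y2) / (x3 - x2))
    return CurveDef(segments=tuple(segments), left=left, right=right)


def curve_set_to_csv(curves: BezierCurveSet, directory) -> dict:
    """Write the three curves of a set; returns {kind: path}."""
    import os

    paths = {}
    for kind in CURVE_KINDS:
        path = os.path.join(str(directory), f"{kind}.csv")
        curve_to_csv(getattr(curves, kind), path)
        paths[kind] = path
    return paths


def curve_set_from_csv(
    force_velocity_path, active_force_length_path, passive_force_length_path
) -> BezierCurveSet:
    fv = curve_from_csv(force_velocity_path, "force_velocity")
    fl = curve_from_csv(active_force_length_path, "active_force_length")
    fp = curve_from_csv(passive_force_length_path, "passive_force_length")
    return BezierCurveSet(
        force_velocity=fv,
        active_force_length=fl,
        passive_force_length=fp,
        f_max_ecc=fv.segments[-1].control_points[3][1],
    )
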