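import pytest
from scipy.optimize import brentq

import workloop as wl

# fast solver settings shared by tests that only need qualitative accuracy
FAST_SOLVER = dict(samples_per_cycle=256, rtol=1e-7, atol=1e-9)


@pytest.fixture(scope="session")
def default_curves():
    return wl.BezierCurveSet.default()


@pytest.fixture(scope="session")
def root_config():
    return wl.RunConfig()


@pytest.fixture(scope="session")
def root_result(root_config):
    """One full-accuracy root-model run shared across tests."""
    return wl.simulate_config(root_config)


def slope(curve, x, h=1e-6, side="center"):
    """Finite-difference slope; 'left'/'right' are second-order one-sided."""
    if side == "center":
        return (curve(x + h) - curve(x - h)) / (2 * h)
    if side == "right":
        return (-3 * curve(x) + 4 * curve(x + h) - curve(x + 2 * h)) / (2 * h)
    return (3 * curve(x) - 4 * curve(x - h) + curve(x - 2 * h)) / (2 * h)


def static_equilibrium(muscle, load, curves, a):
    """Independent bracketing solve of F_m(l_m) = k (x - x0) at zero velocity."""

    def residual(x):
        l_hat = (load.l_tot - x) / muscle.l0
        F = wl.muscle_force(a, l_hat, 0.0, curves, muscle.F0)
        return F - load.k * (x - load.x0)

    lo, hi = 1e-9, load.l_tot - 1e-9
    assert residual(lo) * residual(hi) < 0
    return brentq(residual, lo, hi, xtol=1e-14)
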