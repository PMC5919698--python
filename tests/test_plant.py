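"""Muscle geometry, oscillator linkage and the coupled equation of motion."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import workloop as wl
from conftest import static_equilibrium


@pytest.fixture(scope="module")
def muscle():
    return wl.derive_geometry(l0=0.02, sigma0=225000.0, rho=1060.0,
                              aspect_ratio=100.0, eps0_dot=10.0)


class TestGeometry:
    def test_cross_sectional_area(self, muscle):
        assert muscle.A == pytest.approx(0.25 * math.pi * (2e-4) ** 2, rel=1e-12)
        assert muscle.A == pytest.approx(3.1416e-8, rel=1e-4)

    def test_max_isometric_force(self, muscle):
        assert muscle.F0 == pytest.approx(7.0686e-3, rel=1e-4)

    def test_muscle_mass(self, muscle):
        assert muscle.m_m == pytest.approx(6.6602e-7, rel=1e-4)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            wl.derive_geometry(l0=-0.02, sigma0=225000.0, rho=1060.0,
                               aspect_ratio=100.0)


class TestOscillatorLinkage:
    def test_unit_example(self):
        # c2 F0 = 1 kg, c1 = 1/(2 pi), fd = 1 Hz -> k = 1 N/m, b = 2 N s/m
        linkage = wl.LinkageParams(c1=1.0 / (2 * math.pi), c2=1.0, c3=0.5, fd=1.0)
        load = wl.build_oscillator(linkage, F0=1.0, l_tot=0.04, l0=0.02)
        assert load.m == pytest.approx(1.0)
        assert load.k == pytest.approx(1.0, rel=1e-12)
        assert load.b == pytest.approx(2.0, rel=1e-12)
        assert load.x0 == pytest.approx(0.01)

    def test_critical_damping_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            linkage = wl.LinkageParams(
                c1=rng.uniform(0.05, 2), c2=rng.uniform(1e-3, 100),
                c3=rng.uniform(0.05, 0.95), fd=rng.uniform(0.1, 5),
            )
            load = wl.build_oscillator(linkage, F0=7.07e-3, l_tot=0.04, l0=0.02)
            # machine precision: within 2 ulp of b**2
            assert abs(load.b ** 2 - 4.0 * load.m * load.k) <= 2 * np.spacing(load.b ** 2)

    def test_natural_frequency(self):
        linkage = wl.LinkageParams(c1=0.7, c2=2.0, c3=0.3, fd=1.5)
        load = wl.build_oscillator(linkage, F0=7.07e-3, l_tot=0.04, l0=0.02)
        assert load.omega_n == pytest.approx(2 * math.pi * 0.7 * 1.5, rel=1e-12)

    def test_geometry_error(self):
        linkage = wl.LinkageParams(c1=0.5, c2=1.0, c3=0.5, fd=1.0)
        with pytest.raises(ValueError, match="l_tot"):
            wl.build_oscillator(linkage, F0=1.0, l_tot=0.02, l0=0.02)


class TestMuscleForce:
    def test_inactive_at_slack_length(self, muscle, default_curves):
        assert wl.muscle_force(0.0, 0.7, 0.0, default_curves, muscle.F0) == 0.0
        assert wl.muscle_force(0.0, 0.7, -0.5, default_curves, muscle.F0) == 0.0

    def test_isometric_at_optimum_without_passive(self, muscle):
        curves = wl.ConstantCurveSet(fv=1.0, fa=1.0, fp=0.0)
        assert wl.muscle_force(1.0, 1.0, 0.0, curves, muscle.F0) == pytest.approx(
            muscle.F0
        )
        assert wl.muscle_force(0.5, 1.0, 0.0, curves, muscle.F0) == pytest.approx(
            0.5 * muscle.F0
        )

    def test_never_negative_on_physiological_velocities(self, muscle, default_curves):
        rng = np.random.default_rng(2)
        for _ in range(200):
            F = wl.muscle_force(rng.uniform(0, 1), rng.uniform(0.3, 2.0),
                                rng.uniform(-1, 3), default_curves, muscle.F0)
            assert F >= 0.0


class TestSystemRhs:
    def _setup(self, muscle):
        linkage = wl.LinkageParams(c1=0.5, c2=5.0, c3=0.5, fd=1.0)
        load = wl.build_oscillator(linkage, muscle.F0, 0.04, 0.02)
        protocol = wl.ExcitationProtocol(f=1.0, D=0.3, u_max=1.0)
        act = wl.ActivationParams(tau_act=0.025, beta=0.6)
        return load, protocol, act

    def test_all_derivatives_zero_at_slack_rest(self, muscle, default_curves):
        # place the resting length so the muscle sits at its slack length
        load = wl.OscillatorLoad(m=0.01, k=1.0, b=0.2, x0=0.027, l_tot=0.04)
        protocol = wl.ExcitationProtocol(f=1.0, D=0.3, u_max=1e-12)
        act = wl.ActivationParams(tau_act=0.025, beta=0.6)
        # l_m = 0.013 -> l_hat = 0.65 <= 0.7: passive and active forces vanish
        d = wl.system_rhs(0.5, [0.027, 0.0, 0.0], muscle, load, default_curves,
                          protocol, act)
        assert d == pytest.approx((0.0, 0.0, 0.0), abs=1e-15)

    def test_static_acceleration(self, muscle, default_curves):
        load, protocol, act = self._setup(muscle)
        x, a = load.x0 + 0.002, 0.6
        d = wl.system_rhs(0.1, [x, 0.0, a], muscle, load, default_curves,
                          protocol, act)
        l_hat = (load.l_tot - x) / muscle.l0
        F = wl.muscle_force(a, l_hat, 0.0, default_curves, muscle.F0)
        assert d[1] == pytest.approx((F - load.k * (x - load.x0)) / load.m, rel=1e-12)

    def test_shortening_lands_on_concentric_branch(self, muscle, default_curves):
        load, protocol, act = self._setup(muscle)
        v = 0.05  # x increasing -> muscle shortening
        v_hat = -v / (muscle.l0 * muscle.eps0_dot)
        assert v_hat < 0
        fv = default_curves.force_velocity(v_hat)
        assert fv < 1.0  # concentric side produces less than isometric force

    def test_blowup_raises(self, muscle, default_curves):
        load, protocol, act = self._setup(muscle)
        with pytest.raises(wl.SimulationBlowupError):
            wl.system_rhs(0.0, [0.041, 0.0, 0.0], muscle, load, default_curves,
                          protocol, act)


class TestPlantDynamicsOracles:
    def test_unforced_decay_no_overshoot(self, muscle):
        # critically damped signature: released from an offset with no muscle
        # force, the mass returns to x0 monotonically
        linkage = wl.LinkageParams(c1=0.5, c2=5.0, c3=0.5, fd=1.0)
        load = wl.build_oscillator(linkage, muscle.F0, 0.04, 0.02)
        curves = wl.ConstantCurveSet(fv=0.0, fa=0.0, fp=0.0)
        protocol = wl.ExcitationProtocol(f=1.0, D=0.5, u_max=1e-12)
        act = wl.ActivationParams(tau_act=0.025, beta=0.6)
        sol = solve_ivp(
            lambda t, y: wl.system_rhs(t, y, muscle, load, curves, protocol, act),
            (0.0, 5.0), [load.x0 + 0.003, 0.0, 0.0],
            rtol=1e-10, atol=1e-13, dense_output=True,
        )
        x = sol.sol(np.linspace(0, 5, 2000))[0]
        assert np.all(x >= load.x0 - 1e-10)  # never crosses below rest
        assert np.all(np.diff(x) <= 1e-10)  # monotone return

    def test_static_equilibrium_matches_bracketing_solver(self, muscle, default_curves):
        linkage = wl.LinkageParams(c1=0.5, c2=5.0, c3=0.5, fd=1.0)
        load = wl.build_oscillator(linkage, muscle.F0, 0.04, 0.02)
        a_const = 0.8
        protocol = wl.ExcitationProtocol(f=1.0, D=1.0, u_max=a_const)
        act = wl.ActivationParams(tau_act=0.025, beta=0.6)
        sol = solve_ivp(
            lambda t, y: wl.system_rhs(t, y, muscle, load, default_curves,
                                       protocol, act, "instantaneous"),
            (0.0, 30.0), [load.x0, 0.0, 0.0], rtol=1e-12, atol=1e-14,
        )
        x_expected = static_equilibrium(muscle, load, default_curves, a_const)
        assert abs(sol.y[0, -1] - x_expected) < 1e-8

    def test_linear_plant_matches_closed_form(self, muscle):
        # constant intrinsic curves + instantaneous activation: the plant is a
        # critically damped oscillator under square-wave forcing
        linkage = wl.LinkageParams(c1=0.6, c2=4.0, c3=0.5, fd=1.0)
        load = wl.build_oscillator(linkage, muscle.F0, 0.04, 0.02)
        abar = 0.8
        protocol = wl.ExcitationProtocol(f=1.0, D=0.4, u_max=abar)
        act = wl.ActivationParams(tau_act=0.025, beta=0.6)
        curves = wl.ConstantCurveSet(fv=1.0, fa=1.0, fp=0.0)
        result = wl.run_forward(muscle, curves, load, protocol, act,
                                activation_mode="instantaneous",
                                rtol=1e-11, atol=1e-14)
        t_ref, x_ref, v_ref = wl.linear_plant_steady_response(
            load, abar * muscle.F0, protocol,
            n_samples=result.x.shape[1] - 1)
        err = np.max(np.abs(result.x[-1] - x_ref))
        assert err < 1e-8 * load.x0
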