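"""Bézier curve construction, evaluation, extrapolation and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import workloop as wl
from workloop.curves import (
    DEFAULT_FL_PARAMS,
    DEFAULT_FP_PARAMS,
    DEFAULT_FV_PARAMS,
    FL_FIT_BOUNDS,
    FP_FIT_BOUNDS,
    FV_FIT_BOUNDS,
)

from conftest import slope


def oracle_eval(segment, x, n=1_000_000):
    """Dense-sampling oracle: sample the parameter, interpolate ordinate."""
    s = np.linspace(0.0, 1.0, n)
    xs = segment._x(s)
    ys = segment._y(s)
    return float(np.interp(x, xs, ys))


class TestSegment:
    def test_identity_line(self):
        seg = wl.BezierSegment(((0, 0), (1 / 3, 1 / 3), (2 / 3, 2 / 3), (1, 1)))
        assert wl.eval_segment(seg, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_endpoint_interpolation_degenerate(self):
        seg = wl.BezierSegment(((0, 0), (0, 1), (1, 1), (1, 1)))
        assert wl.eval_segment(seg, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert wl.eval_segment(seg, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_against_dense_sampling_oracle(self):
        seg = wl.BezierSegment(((0, 0), (0.25, 0.1), (0.75, 0.9), (1, 1)))
        assert wl.eval_segment(seg, 0.37) == pytest.approx(
            oracle_eval(seg, 0.37), abs=1e-8
        )

    def test_random_segments_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            xs = np.sort(rng.uniform(-1, 1, 4))
            ys = rng.uniform(-1, 1, 4)
            seg = wl.BezierSegment(tuple(zip(xs, ys)))
            queries = rng.uniform(xs[0], xs[3], 50)
            for x in queries:
                assert seg.evaluate(x) == pytest.approx(oracle_eval(seg, x), abs=1e-8)

    def test_vectorized_matches_scalar(self):
        seg = wl.BezierSegment(((0, 0), (0.2, 0.5), (0.7, 0.6), (1, 1)))
        xs = np.linspace(0, 1, 101)
        np.testing.assert_allclose(
            seg.evaluate_many(xs), [seg.evaluate(x) for x in xs], atol=1e-10
        )

    def test_out_of_span_raises(self):
        seg = wl.BezierSegment(((0, 0), (0.3, 0.3), (0.6, 0.6), (1, 1)))
        with pytest.raises(ValueError, match="outside segment span"):
            wl.eval_segment(seg, 1.5)

    def test_wrong_count_and_nonmonotone_rejected(self):
        with pytest.raises(wl.CurveConstructionError, match="4 control points"):
            wl.BezierSegment(((0, 0), (1, 1), (2, 2)))
        with pytest.raises(wl.CurveConstructionError, match="non-decreasing"):
            wl.BezierSegment(((0, 0), (0.5, 1), (0.2, 1), (1, 1)))


class TestForceVelocity:
    def test_anchor_points(self, default_curves):
        fv = default_curves.force_velocity
        assert fv(-1.0) == pytest.approx(0.0, abs=1e-12)
        assert fv(0.0) == pytest.approx(1.0, abs=1e-12)
        assert fv(1.0) == pytest.approx(default_curves.f_max_ecc, abs=1e-12)

    def test_extrapolation_constant(self, default_curves):
        fv = default_curves.force_velocity
        assert fv(-2.0) == 0.0
        assert fv(-1.5) == 0.0
        assert fv(2.0) == default_curves.f_max_ecc

    def test_slope_continuous_at_isometric(self, default_curves):
        fv = default_curves.force_velocity
        # small step: the eccentric limb is strongly curved near v = 0
        left = slope(fv, 0.0, h=1e-7, side="left")
        right = slope(fv, 0.0, h=1e-7, side="right")
        assert left == pytest.approx(right, abs=1e-6)

    def test_zero_slope_at_eccentric_plateau(self, default_curves):
        fv = default_curves.force_velocity
        assert slope(fv, 1.0, side="left") == pytest.approx(0.0, abs=1e-6)

    def test_concentric_symmetry_about_diagonal(self, default_curves):
        # reflecting a concentric point (v, F) across F = -v gives (-F, -v),
        # which must also lie on the segment
        fv = default_curves.force_velocity
        for v in np.linspace(-1.0, 0.0, 100):
            F = fv(v)
            assert fv(-F) == pytest.approx(-v, abs=1e-8)

    def test_invalid_params_raise_named_errors(self):
        with pytest.raises(wl.CurveConstructionError, match="f_max_ecc"):
            wl.build_force_velocity(f_max_ecc=0.9)
        with pytest.raises(wl.CurveConstructionError, match="monotone"):
            wl.build_force_velocity(free_params=(-0.1, 0.5, 0.1, 0.4))
        with pytest.raises(wl.CurveConstructionError, match="eccentric"):
            wl.build_force_velocity(free_params=(-0.35, 0.125, 0.6, 0.4))


class TestActiveForceLength:
    def test_anchor_points(self, default_curves):
        fl = default_curves.active_force_length
        assert fl(1.0) == pytest.approx(1.0, abs=1e-12)
        assert fl(0.45) == pytest.approx(0.0, abs=1e-12)
        assert fl(1.65) == pytest.approx(0.0, abs=1e-12)
        assert fl(0.3) == 0.0
        assert fl(1.8) == 0.0

    def test_zero_slope_at_optimum_both_limbs(self, default_curves):
        fl = default_curves.active_force_length
        assert slope(fl, 1.0, side="left") == pytest.approx(0.0, abs=1e-6)
        assert slope(fl, 1.0, side="right") == pytest.approx(0.0, abs=1e-6)

    def test_zero_slope_at_endpoints(self, default_curves):
        fl = default_curves.active_force_length
        assert slope(fl, 0.45, side="right") == pytest.approx(0.0, abs=1e-6)
        assert slope(fl, 1.65, side="left") == pytest.approx(0.0, abs=1e-6)

    def test_bad_endpoints_rejected(self):
        with pytest.raises(wl.CurveConstructionError):
            wl.build_active_force_length(ascending_end=1.2)


class TestPassiveForceLength:
    def test_zero_below_slack(self, default_curves):
        fp = default_curves.passive_force_length
        assert fp(0.5) == 0.0
        assert fp(0.6) == 0.0
        assert fp(0.7) == pytest.approx(0.0, abs=1e-12)

    def test_zero_slope_at_slack(self, default_curves):
        fp = default_curves.passive_force_length
        assert slope(fp, 0.7, side="right") == pytest.approx(0.0, abs=1e-6)

    def test_linear_extrapolation_matches_chord(self, default_curves):
        fp = default_curves.passive_force_length
        seg = fp.segments[-1]
        (x2, y2), (x3, y3) = seg.control_points[2:]
        chord = (y3 - y2) / (x3 - x2)
        expected = fp(1.65) + chord * (1.8 - 1.65)
        assert fp(1.8) == pytest.approx(expected, rel=1e-12)
        # extrapolation is C1: end slope of the cubic equals the chord slope
        assert slope(fp, 1.65, side="left") == pytest.approx(chord, abs=1e-5)


class TestCurveContinuity:
    @pytest.mark.parametrize(
        "curve_name,joins",
        [
            ("force_velocity", (-1.0, 0.0, 1.0)),
            ("active_force_length", (0.45, 1.0, 1.65)),
            ("passive_force_length", (0.7, 1.65)),
        ],
    )
    def test_continuous_across_joins_and_edges(self, default_curves, curve_name, joins):
        curve = getattr(default_curves, curve_name)
        for x in joins:
            for d in (1e-7, 1e-9):
                assert curve(x + d) == pytest.approx(curve(x), abs=1e-5)
                assert curve(x - d) == pytest.approx(curve(x), abs=1e-5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(-2.5, 2.5))
    def test_small_step_small_change(self, x):
        curve = wl.build_force_velocity()
        delta = 1e-9
        assert abs(curve(x + delta) - curve(x)) < 1e-6

    def test_endpoint_interpolation_every_segment(self, default_curves):
        for name in ("force_velocity", "active_force_length", "passive_force_length"):
            for seg in getattr(default_curves, name).segments:
                (x0, y0), *_, (x3, y3) = seg.control_points
                assert seg.evaluate(x0) == pytest.approx(y0, abs=1e-12)
                assert seg.evaluate(x3) == pytest.approx(y3, abs=1e-12)

    def test_discontinuous_join_rejected(self):
        a = wl.BezierSegment(((0, 0), (0.2, 0.2), (0.4, 0.4), (0.5, 0.5)))
        b = wl.BezierSegment(((0.5, 0.6), (0.7, 0.7), (0.9, 0.9), (1, 1)))
        with pytest.raises(wl.CurveConstructionError, match="join"):
            wl.CurveDef((a, b), wl.Extrapolation("constant", 0.0),
                        wl.Extrapolation("constant", 1.0))


class TestFitting:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(11)
        truth = wl.build_force_velocity(free_params=DEFAULT_FV_PARAMS)
        xs = np.linspace(-1, 1, 50)
        data = np.column_stack([xs, truth.evaluate(xs)])
        fit = wl.fit_curve(
            data, lambda p: wl.build_force_velocity(free_params=p),
            FV_FIT_BOUNDS, seed=3,
        )
        assert fit.r_squared >= 0.999
        np.testing.assert_allclose(
            fit.free_parameters, DEFAULT_FV_PARAMS, rtol=0.01
        )

    def test_refit_of_own_output(self):
        truth = wl.build_passive_force_length(free_params=DEFAULT_FP_PARAMS)
        xs = np.concatenate([[0.7], np.linspace(0.8, 1.65, 20)])
        data = np.column_stack([xs, truth.evaluate(xs)])
        fit = wl.fit_curve(
            data, lambda p: wl.build_passive_force_length(free_params=p),
            FP_FIT_BOUNDS, seed=5, maxiter=150,
        )
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_r2_decreases_with_noise(self):
        truth = wl.build_active_force_length(free_params=DEFAULT_FL_PARAMS)
        xs = np.linspace(0.45, 1.65, 60)
        clean = truth.evaluate(xs)
        mean_r2 = []
        for sigma in (0.0, 0.05, 0.1):
            r2s = []
            for seed in (0, 1, 2):
                rng = np.random.default_rng(100 + seed)
                ys = clean + rng.normal(0, sigma, size=xs.shape)
                fit = wl.fit_curve(
                    np.column_stack([xs, ys]),
                    lambda p: wl.build_active_force_length(free_params=p),
                    FL_FIT_BOUNDS, seed=seed, maxiter=60, popsize=10,
                )
                r2s.append(fit.r_squared)
            mean_r2.append(np.mean(r2s))
        assert mean_r2[0] > mean_r2[1] > mean_r2[2]

    def test_degenerate_data_raises(self):
        data = np.column_stack([np.linspace(-1, 1, 10), np.ones(10)])
        with pytest.raises(wl.FitError, match="degenerate"):
            wl.fit_curve(data, lambda p: wl.build_force_velocity(free_params=p),
                         FV_FIT_BOUNDS, seed=0)

    def test_too_few_points_raises(self):
        data = np.column_stack([np.linspace(-1, 1, 5), np.linspace(0, 1, 5)])
        with pytest.raises(wl.FitError, match="at least 8"):
            wl.fit_curve(data, lambda p: wl.build_force_velocity(free_params=p),
                         FV_FIT_BOUNDS, seed=0)


class TestCsvRoundTrip:
    def test_curve_set_round_trip(self, default_curves, tmp_path):
        paths = wl.curve_set_to_csv(default_curves, tmp_path)
        loaded = wl.curve_set_from_csv(
            paths["force_velocity"],
            paths["active_force_length"],
            paths["passive_force_length"],
        )
        xs = np.linspace(-2, 2, 201)
        np.testing.assert_allclose(
            loaded.force_velocity.evaluate(xs),
            default_curves.force_velocity.evaluate(xs), atol=1e-12,
        )
        ls = np.linspace(0.3, 2.0, 201)
        for name in ("active_force_length", "passive_force_length"):
            np.testing.assert_allclose(
                getattr(loaded, name).evaluate(ls),
                getattr(default_curves, name).evaluate(ls), atol=1e-12,
            )
        assert loaded.f_max_ecc == pytest.approx(default_curves.f_max_ecc)
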