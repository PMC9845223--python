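"""Closed-form FS model: coefficients, circle geometry, inversion, ODE oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fsmotion.motion import (
    ExtendedModelSpec,
    KineticParams,
    MotionState,
    arrival_circle,
    arrival_point,
    coef_A,
    coef_B,
    invert_alpha,
    simulate_ode,
    vmax_from_radius,
)

ALPHAS = st.floats(0.1, 10.0)
TIMES = st.floats(0.2, 5.0)


class TestCoefficients:
    @pytest.mark.parametrize(
        "alpha, t, expected",
        [
            (0.7, 0.0, 0.0),
            (1e-12, 3.0, 3.0),  # series limit A -> t
            (1.23, 1.0, 0.575371888),
            (1.04, 2.0, 0.841413258),
        ],
    )
    def test_coef_A_values(self, alpha, t, expected):
        assert coef_A(alpha, t) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize(
        "alpha, vmax, t, expected",
        [
            (0.9, 5.0, 0.0, 0.0),
            (1.23, 14.53, 1.0, 6.16984647),
            (1.04, 11.19, 2.0, 12.96458565),
        ],
    )
    def test_coef_B_values(self, alpha, vmax, t, expected):
        assert coef_B(KineticParams(alpha, vmax), t) == pytest.approx(expected, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            coef_A(0.0, 1.0)
        with pytest.raises(ValueError):
            coef_A(-1.0, 1.0)
        with pytest.raises(ValueError):
            coef_A(1.0, -0.5)
        with pytest.raises(ValueError):
            coef_B(KineticParams(1.0, 5.0), -1.0)

    @given(alpha=ALPHAS, t=TIMES)
    def test_coef_A_bounds(self, alpha, t):
        a = coef_A(alpha, t)
        assert 0 < a < t
        assert a <= 1.0 / alpha  # equality only at floating-point underflow

    @given(alpha=ALPHAS, t=TIMES)
    def test_coef_A_monotone_decreasing_in_alpha(self, alpha, t):
        assert coef_A(alpha * 1.01, t) < coef_A(alpha, t)

    @given(alpha=ALPHAS, t=TIMES)
    def test_coefs_monotone_increasing_in_t(self, alpha, t):
        assert coef_A(alpha, t * 1.01) > coef_A(alpha, t)
        p = KineticParams(alpha, 6.0)
        assert coef_B(p, t * 1.01) > coef_B(p, t)

    def test_coef_B_asymptotically_linear(self):
        # B(t) ~ vmax * (t - 1/alpha) for large t
        p = KineticParams(1.3, 8.0)
        for t in (20.0, 50.0):
            assert coef_B(p, t) == pytest.approx(p.vmax * (t - 1 / p.alpha), rel=1e-6)


class TestArrivalGeometry:
    PARAMS = KineticParams(1.23, 14.53)

    def test_steady_state_is_uniform_motion(self):
        # starting at terminal velocity and driving forward: x = vmax * t
        v0 = np.array([self.PARAMS.vmax, 0.0])
        for t in (0.5, 1.0, 3.0):
            p = arrival_point(v0, (1.0, 0.0), self.PARAMS, t)
            assert p == pytest.approx([self.PARAMS.vmax * t, 0.0], abs=1e-9)

    def test_standing_start_moves_B_along_direction(self):
        p = arrival_point((0.0, 0.0), (0.0, 1.0), self.PARAMS, 1.0)
        assert p == pytest.approx([0.0, 6.16984647], abs=1e-6)

    def test_backward_drive(self):
        p = arrival_point((5.0, 0.0), (-1.0, 0.0), self.PARAMS, 1.0)
        assert p == pytest.approx([0.575371888 * 5 - 6.16984647, 0.0], abs=1e-6)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            arrival_point((1.0, 0.0), (1.0, 1.0), self.PARAMS, 1.0)

    @pytest.mark.parametrize(
        "v0, params, t, center, radius",
        [
            ((6.0, 0.0), KineticParams(1.23, 14.53), 1.0, (3.45223, 0.0), 6.16985),
            ((3.0, 0.0), KineticParams(1.04, 11.19), 2.0, (2.52424, 0.0), 12.96459),
            ((0.0, 0.0), KineticParams(1.3, 8.0), 1.0, (0.0, 0.0), 3.52327),
        ],
    )
    def test_arrival_circle_values(self, v0, params, t, center, radius):
        c = arrival_circle(v0, params, t)
        assert c.center == pytest.approx(center, abs=1e-5)
        assert c.radius == pytest.approx(radius, abs=1e-5)

    def test_circle_identity_360_directions(self):
        # every drive direction lands exactly at distance B from A * v0
        v0 = np.array([4.0, 1.0])
        t = 1.7
        circle = arrival_circle(v0, self.PARAMS, t)
        for theta in np.linspace(0, 2 * math.pi, 360, endpoint=False):
            n = np.array([math.cos(theta), math.sin(theta)])
            p = arrival_point(v0, n, self.PARAMS, t)
            assert np.linalg.norm(p - circle.center) == pytest.approx(
                circle.radius, abs=1e-12
            )


class TestInversion:
    @pytest.mark.parametrize(
        "slope, t, expected",
        [
            (0.58, 1.0, 1.2100),
            (0.84, 2.0, 1.0425),
        ],
    )
    def test_invert_alpha_values(self, slope, t, expected):
        assert invert_alpha(slope, t) == pytest.approx(expected, abs=5e-4)

    def test_invert_alpha_residual(self):
        alpha = invert_alpha(0.58, 1.0)
        assert abs(coef_A(alpha, 1.0) - 0.58) < 1e-9

    def test_invert_alpha_rejects_degenerate_slopes(self):
        with pytest.raises(ValueError):
            invert_alpha(2.0, 2.0)  # slope >= t
        with pytest.raises(ValueError):
            invert_alpha(0.0, 1.0)
        with pytest.raises(ValueError):
            invert_alpha(-0.1, 1.0)

    @given(alpha=ALPHAS, t=TIMES)
    def test_invert_alpha_round_trip(self, alpha, t):
        assert invert_alpha(coef_A(alpha, t), t) == pytest.approx(alpha, rel=1e-6)

    @pytest.mark.parametrize(
        "r_c, alpha, t, expected",
        [
            (0.0, 1.3, 1.0, 0.0),
            (6.16, 1.23, 1.0, 14.506),
            (12.94, 1.04, 2.0, 11.169),
        ],
    )
    def test_vmax_from_radius_values(self, r_c, alpha, t, expected):
        assert vmax_from_radius(r_c, alpha, t) == pytest.approx(expected, abs=1e-3)

    @given(alpha=ALPHAS, t=TIMES, vmax=st.floats(1.0, 15.0))
    def test_vmax_round_trip(self, alpha, t, vmax):
        p = KineticParams(alpha, vmax)
        assert vmax_from_radius(coef_B(p, t), alpha, t) == pytest.approx(
            vmax, rel=1e-9
        )

    def test_vmax_rejects_negative_radius(self):
        with pytest.raises(ValueError):
            vmax_from_radius(-1.0, 1.3, 1.0)


class TestODE:
    def test_drag_only_decay(self):
        # F = 0: speed decays exponentially, position -> x0 + v0 / alpha
        alpha = 1.5
        spec = ExtendedModelSpec(mass=70.0, driving_force=0.0, drag_coefficient=alpha * 70.0)
        init = MotionState(np.zeros(2), np.array([3.0, 0.0]), 0.0)
        traj = simulate_ode(spec, init, 20.0, dt=1e-3)
        assert traj.final.position == pytest.approx([3.0 / alpha, 0.0], abs=1e-6)
        assert np.linalg.norm(traj.final.velocity) < 1e-9

    def test_matches_closed_form(self):
        params = KineticParams(1.3, 8.0)
        n = np.array([0.6, 0.8])
        spec = ExtendedModelSpec.from_kinetic(params, direction=n)
        init = MotionState(np.zeros(2), np.array([2.0, 0.0]), 0.0)
        traj = simulate_ode(spec, init, 5.0, dt=1e-4)
        expected = coef_A(1.3, 5.0) * init.velocity + coef_B(params, 5.0) * n
        assert np.linalg.norm(traj.final.position - expected) < 1e-6

    def test_steady_state_uniform_motion(self):
        params = KineticParams(1.1, 6.0)
        n = np.array([1.0, 0.0])
        spec = ExtendedModelSpec.from_kinetic(params, direction=n)
        init = MotionState(np.zeros(2), params.vmax * n, 0.0)
        traj = simulate_ode(spec, init, 4.0, dt=1e-3)
        assert traj.final.position == pytest.approx([params.vmax * 4.0, 0.0], abs=1e-7)

    def test_variable_coefficients_run(self):
        # time-dependent drive: integrates without error, stays finite
        spec = ExtendedModelSpec(
            mass=70.0,
            driving_force=lambda t: 500.0 * (1.0 + 0.5 * math.sin(t)),
            drag_coefficient=lambda t: 80.0 + 10.0 * t,
            direction=lambda t: (math.cos(0.2 * t), math.sin(0.2 * t)),
        )
        init = MotionState(np.zeros(2), np.zeros(2), 0.0)
        traj = simulate_ode(spec, init, 3.0, dt=1e-3)
        assert np.all(np.isfinite(traj.positions))
        assert len(traj) == 3001

    def test_direction_normalized_defensively(self):
        # non-unit constant direction gives the same path as its normalization
        params = KineticParams(1.3, 8.0)
        spec1 = ExtendedModelSpec.from_kinetic(params, direction=(3.0, 4.0))
        spec2 = ExtendedModelSpec.from_kinetic(params, direction=(0.6, 0.8))
        init = MotionState(np.zeros(2), np.zeros(2), 0.0)
        t1 = simulate_ode(spec1, init, 2.0, dt=1e-3)
        t2 = simulate_ode(spec2, init, 2.0, dt=1e-3)
        assert np.allclose(t1.positions, t2.positions)

    def test_invalid_steps_rejected(self):
        spec = ExtendedModelSpec(mass=70.0, driving_force=500.0, drag_coefficient=90.0)
        init = MotionState(np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(ValueError):
            simulate_ode(spec, init, 1.0, dt=0.0)
        with pytest.raises(ValueError):
            simulate_ode(spec, init, -1.0, dt=0.1)
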