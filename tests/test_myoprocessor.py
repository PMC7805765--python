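"""Activation dynamics, Hill curves, geometry and torque composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myoexo.myoprocessor import (
    ActivationParams,
    GeometryModel,
    HillCurveParams,
    MuscleParams,
    TorqueSeries,
    activation,
    default_geometry,
    estimate_torque_series,
    fiber_state,
    force_length,
    force_velocity,
    hill_force,
    joint_torque,
    passive_force,
)
from myoexo.signal_processing import EmgEnvelope

CURVES = HillCurveParams()


class TestActivation:
    @pytest.mark.parametrize("A", [-5.0, -2.0, -0.5, 0.5, 2.0, 5.0])
    def test_endpoints_and_monotonicity(self, A):
        assert activation(0.0, A) == 0.0
        assert activation(1.0, A) == pytest.approx(1.0, abs=1e-15)
        u = np.linspace(0, 1, 1001)
        a = activation(u, A)
        assert np.all(np.diff(a) > 0)

    def test_midpoint_value(self):
        # closed form (e^-1 - 1)/(e^-2 - 1)
        assert activation(0.5, -2.0) == pytest.approx(0.7310585786300049,
                                                      abs=1e-12)

    def test_linear_limit(self):
        u = np.linspace(0, 1, 101)
        assert np.allclose(activation(u, 0.0), u)
        assert np.allclose(activation(u, 1e-9), u, atol=1e-6)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            activation(np.nan, -2.0)
        with pytest.raises(ValueError):
            ActivationParams(6.0)
        with pytest.warns(UserWarning):
            assert activation(1.2, -2.0) == pytest.approx(1.0)


class TestHillCurves:
    def test_force_length_peak_and_symmetry(self):
        assert force_length(1.0, CURVES) == 1.0
        d = np.linspace(0, 0.5, 20)
        assert np.allclose(force_length(1 + d, CURVES), force_length(1 - d, CURVES))

    def test_force_velocity_anchors(self):
        assert force_velocity(0.0, CURVES) == 1.0
        assert force_velocity(-1.0, CURVES) == 0.0
        assert force_velocity(-1.5, CURVES) == 0.0  # clamped past v_max
        v = np.linspace(-1.2, 3.0, 500)
        fv = force_velocity(v, CURVES)
        assert np.all(np.diff(fv) >= 0)
        assert np.all(fv < CURVES.f_ecc)

    def test_force_velocity_smooth_at_zero(self):
        h = 1e-6
        left = (force_velocity(0.0, CURVES) - force_velocity(-h, CURVES)) / h
        right = (force_velocity(h, CURVES) - force_velocity(0.0, CURVES)) / h
        assert left == pytest.approx(right, rel=1e-3)

    def test_passive_normalisation(self):
        assert passive_force(1.0, CURVES) == 0.0
        assert passive_force(0.7, CURVES) == 0.0
        assert passive_force(1 + CURVES.eps0, CURVES) == pytest.approx(1.0,
                                                                       abs=1e-15)


class TestFiberState:
    def test_unpennated_optimum(self):
        p = MuscleParams(f_max=100, l0=0.1, lst=0.2, phi0=0.0)
        st_ = fiber_state(0.3, 0.0, p)
        assert st_.lm == pytest.approx(0.1)
        assert st_.phi == pytest.approx(0.0)
        assert st_.vm == 0.0

    def test_pennated_closed_form(self):
        # lm = sqrt((lmt-lst)^2 + (l0 sin phi0)^2) evaluated at the stated
        # geometry; phi = atan2(l0 sin phi0, lmt-lst)
        p = MuscleParams(f_max=100, l0=0.12, lst=0.20, phi0=0.2)
        st_ = fiber_state(0.32, 0.0, p)
        h = 0.12 * np.sin(0.2)
        assert st_.lm == pytest.approx(np.hypot(0.12, h), abs=1e-12)
        assert st_.phi == pytest.approx(np.arctan2(h, 0.12), abs=1e-12)
        assert st_.phi == pytest.approx(0.196116, abs=1e-5)

    def test_velocity_projection(self):
        p = MuscleParams(f_max=100, l0=0.12, lst=0.20, phi0=0.3)
        st_ = fiber_state(0.30, -0.05, p)
        assert st_.vm == pytest.approx(-0.05 * np.cos(st_.phi))

    def test_slack_state(self):
        p = MuscleParams(f_max=100, l0=0.1, lst=0.2, phi0=0.0)
        with pytest.warns(UserWarning):
            st_ = fiber_state(0.15, 0.0, p)
        assert st_.slack
        assert st_.lm >= 0.3 * p.l0


class TestHillForce:
    P = MuscleParams(f_max=500.0, l0=0.1, lst=0.2, phi0=0.0)

    def test_maximal_isometric(self):
        assert hill_force(1.0, 0.1, 0.0, 0.0, self.P, CURVES) == pytest.approx(500.0)

    def test_passive_only_zero_at_optimum(self):
        assert hill_force(0.0, 0.1, 0.0, 0.0, self.P, CURVES) == 0.0

    def test_zero_at_max_shortening(self):
        vmax = CURVES.v_max * self.P.l0
        assert hill_force(1.0, 0.1, -vmax, 0.0, self.P, CURVES) == 0.0

    def test_never_negative(self):
        f = hill_force(0.0, 0.05, -0.5, 0.0, self.P, CURVES)
        assert f >= 0.0


class TestGeometry:
    def test_moment_arm_is_negative_length_derivative(self):
        geo = default_geometry()
        h = 1e-5
        for phi in np.linspace(0.1, 2.5, 9):
            fd = -(geo.lmt("biceps", phi + h) - geo.lmt("biceps", phi - h)) / (2 * h)
            assert geo.moment_arm("biceps", phi) == pytest.approx(fd, abs=1e-6)

    def test_default_signs_at_mid_flexion(self):
        geo = default_geometry()
        assert geo.moment_arm("biceps", np.pi / 2) > 0
        assert geo.moment_arm("triceps", np.pi / 2) < 0

    def test_constant_table_gives_zero_arm(self):
        from numpy.polynomial import Polynomial

        geo = GeometryModel({"m": Polynomial([0.3])})
        assert geo.moment_arm("m", 1.0) == 0.0

    def test_domain_clamp_warns(self):
        geo = default_geometry()
        with pytest.warns(UserWarning):
            v = geo.lmt("biceps", 3.5)
        assert v == geo.lmt("biceps", 2.6)


class TestJointTorque:
    def test_hand_computed_sum(self):
        assert joint_torque([100.0, 40.0], [0.03, -0.02]) == pytest.approx(2.2)
        assert joint_torque([50.0], [0.04]) == pytest.approx(2.0)
        assert joint_torque([0.0, 0.0], [0.03, -0.02]) == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            joint_torque([1.0, 2.0], [0.1])


class TestEstimateTorqueSeries:
    def _series(self, u_biceps, n=200, phi=np.pi / 2):
        muscles = {
            "biceps": MuscleParams(f_max=600.0, l0=0.116, lst=0.27),
            "triceps": MuscleParams(f_max=800.0, l0=0.134, lst=0.143, phi0=0.21),
        }
        env = EmgEnvelope(
            np.column_stack([np.full(n, u_biceps), np.zeros(n)]),
            fs=100.0, channels=("biceps", "triceps"))
        angle = np.full(n, phi)
        vel = np.zeros(n)
        return muscles, estimate_torque_series(env, angle, vel, muscles)

    def test_static_step_matches_closed_form(self):
        muscles, ts = self._series(1.0)
        geo = default_geometry()
        p = muscles["biceps"]
        st_ = fiber_state(geo.lmt("biceps", np.pi / 2), 0.0, p)
        f_b = hill_force(1.0, st_.lm, 0.0, st_.phi, p, CURVES)
        expected = geo.moment_arm("biceps", np.pi / 2) * f_b
        # triceps is passive here; add its (possibly nonzero) contribution
        pt = muscles["triceps"]
        st_t = fiber_state(geo.lmt("triceps", np.pi / 2), 0.0, pt)
        expected += geo.moment_arm("triceps", np.pi / 2) * hill_force(
            0.0, st_t.lm, 0.0, st_t.phi, pt, CURVES)
        assert np.allclose(ts.tau, expected)

    def test_fmax_linearity(self):
        muscles, ts = self._series(0.6)
        doubled = {k: p.with_(f_max=2 * p.f_max) for k, p in muscles.items()}
        env = EmgEnvelope(
            np.column_stack([np.full(200, 0.6), np.zeros(200)]),
            fs=100.0, channels=("biceps", "triceps"))
        ts2 = estimate_torque_series(env, np.full(200, np.pi / 2),
                                     np.zeros(200), doubled)
        assert np.allclose(ts2.tau, 2 * ts.tau)

    def test_constant_inputs_give_constant_output(self):
        _, ts = self._series(0.3)
        assert np.ptp(ts.tau) < 1e-12

    def test_length_mismatch_rejected(self):
        muscles = {"biceps": MuscleParams(f_max=600.0, l0=0.116, lst=0.27)}
        env = EmgEnvelope(np.zeros((100, 1)), fs=100.0, channels=("biceps",))
        with pytest.raises(ValueError):
            estimate_torque_series(env, np.zeros(99), np.zeros(99), muscles)


class TestTorqueSeries:
    def test_uniform_sampling_enforced(self):
        with pytest.raises(ValueError):
            TorqueSeries(np.array([0.0, 0.1, 0.3]), np.zeros(3))

    def test_role_validated(self):
        with pytest.raises(ValueError):
            TorqueSeries(np.arange(3.0), np.zeros(3), role="bogus")


@given(st.floats(min_value=0.0, max_value=1.0),
       st.floats(min_value=-5.0, max_value=-0.01))
@settings(deadline=None, max_examples=50)
def test_activation_stays_in_unit_interval(u, A):
    a = activation(u, A)
    assert 0.0 <= a <= 1.0
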