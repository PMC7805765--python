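"""Calibration trajectory, inverse dynamics and parameter fitting."""

import numpy as np
import pytest

from conftest import kinematic_envelope
from myoexo.calibration import (
    CalibrationBounds,
    CalibrationTrajectorySpec,
    TorqueCalibration,
    calibration_kinematics,
    planar_inverse_dynamics,
    reference_trajectory,
)
from myoexo.myoprocessor import ActivationParams
from myoexo.suit import PlantParams


class TestReferenceTrajectory:
    SPEC = CalibrationTrajectorySpec()
    FS = 100.0

    def test_rest_at_zero(self):
        theta = reference_trajectory(self.SPEC, self.FS)
        rest = theta[: int((self.SPEC.rest - self.SPEC.ramp) * self.FS)]
        assert np.allclose(rest, 0.0)

    def test_sin_peak_quarter_period_into_first_dwell(self):
        # f = 0.05 Hz: a quarter period (5 s) into the dwell the sinusoid
        # peaks at A0 + A = 90 deg
        theta = reference_trajectory(self.SPEC, self.FS)
        k = int((self.SPEC.rest + 5.0) * self.FS)
        assert np.degrees(theta[k]) == pytest.approx(90.0, abs=0.1)

    def test_total_duration(self):
        # 20 s rest + 10 dwells of 20 s
        assert self.SPEC.duration == pytest.approx(220.0)
        theta = reference_trajectory(self.SPEC, self.FS)
        assert theta.size == int(220.0 * self.FS)

    def test_continuity(self):
        theta = reference_trajectory(self.SPEC, self.FS)
        f_max = max(self.SPEC.freqs)
        bound = np.radians(self.SPEC.amplitude) * 2 * np.pi * f_max / self.FS
        assert np.max(np.abs(np.diff(theta))) < bound + 1e-6

    def test_velocity_consistent_with_angle(self):
        t, theta, omega, _ = calibration_kinematics(self.SPEC, 200.0)
        num = np.gradient(theta, t)
        # away from segment boundaries the analytic velocity matches
        interior = slice(100, -100)
        assert np.percentile(np.abs(num[interior] - omega[interior]), 99) < 0.05


class TestPlanarInverseDynamics:
    def test_static_hold_with_load(self):
        # m r_com = 0.225 kg m plus 3 kg at 0.30 m, held horizontal:
        # tau = 9.81 (0.225 + 0.9)
        plant = PlantParams(inertia=0.08, m_r_com=0.225, load_mass=3.0,
                            load_lever=0.30)
        n = 100
        ts = planar_inverse_dynamics(np.full(n, np.pi / 2), np.zeros(n), plant,
                                     accel=np.zeros(n), fs=100.0)
        assert np.allclose(ts.tau, 9.81 * 1.125)
        assert ts.tau[0] == pytest.approx(11.036, abs=1e-2)

    def test_vertical_arm_zero_gravity_torque(self):
        plant = PlantParams()
        ts = planar_inverse_dynamics(np.zeros(50), np.zeros(50), plant,
                                     accel=np.zeros(50), fs=100.0)
        assert np.allclose(ts.tau, 0.0)

    def test_pure_inertial_term(self):
        plant = PlantParams(m_r_com=0.225, g=0.0)
        alpha = np.full(50, 2.0)
        ts = planar_inverse_dynamics(np.zeros(50), np.zeros(50), plant,
                                     accel=alpha, fs=100.0)
        assert np.allclose(ts.tau, plant.total_inertia * 2.0)

    def test_differentiation_fallback(self):
        plant = PlantParams(m_r_com=0.0, g=0.0, inertia=0.1)
        fs = 100.0
        t = np.arange(500) / fs
        omega = np.sin(2 * np.pi * 0.5 * t)
        ts = planar_inverse_dynamics(np.zeros(500), omega, plant, fs=fs)
        expected = 0.1 * 2 * np.pi * 0.5 * np.cos(2 * np.pi * 0.5 * t)
        assert np.allclose(ts.tau[50:-50], expected[50:-50], atol=0.02)


def _offset_nominal(muscles):
    return {
        n: p.with_(f_max=p.f_max * 1.2, l0=p.l0 * 1.05, lst=p.lst * 0.97,
                   activation=ActivationParams(-1.5))
        for n, p in muscles.items()
    }


class TestTorqueCalibration:
    def test_identity_fit_objective_zero(self, subject, calibration_session):
        s = calibration_session
        model = TorqueCalibration(
            kinematic_envelope(s), s.angle, s.velocity, s.tau_id,
            dict(subject.muscles), curves=subject.curves,
            geometry=subject.geometry)
        assert model.objective(model._x_nominal()) < 1e-6

    def test_noiseless_recovery_from_offset_nominal(self, subject,
                                                    calibration_session):
        s = calibration_session
        model = TorqueCalibration(
            kinematic_envelope(s), s.angle, s.velocity, s.tau_id,
            _offset_nominal(subject.muscles), curves=subject.curves,
            geometry=subject.geometry)
        res = model.fit()
        assert res.objective < 1e-3
        fit = res.params["biceps"]
        tru = subject.muscles["biceps"]
        assert fit.f_max == pytest.approx(tru.f_max, rel=0.05)
        assert fit.activation.shape == pytest.approx(tru.activation.shape,
                                                     rel=0.10)
        assert "normalized torque RMSE" in res.summary()

    def test_bounds_excluding_truth_pin_at_bound(self, subject,
                                                 calibration_session):
        s = calibration_session
        # shift the F_max band +50% past the truth: the optimum must pin at
        # the lower bound and be flagged
        bounds = CalibrationBounds(f_max_rel=(1.5, 3.0))
        nominal = dict(subject.muscles)
        model = TorqueCalibration(
            kinematic_envelope(s), s.angle, s.velocity, s.tau_id, nominal,
            curves=subject.curves, geometry=subject.geometry, bounds=bounds)
        res = model.fit(n_starts=2)
        assert res.params["biceps"].f_max == pytest.approx(
            subject.muscles["biceps"].f_max * 1.5, rel=1e-3)
        assert res.at_bounds["biceps"]["f_max_factor"]

    def test_objective_scale_invariance(self, subject, calibration_session):
        from myoexo.myoprocessor import TorqueSeries

        s = calibration_session
        env = kinematic_envelope(s)
        nominal = _offset_nominal(subject.muscles)
        m1 = TorqueCalibration(env, s.angle, s.velocity, s.tau_id, nominal,
                               curves=subject.curves, geometry=subject.geometry)
        scaled = TorqueSeries(s.tau_id.t, 3.0 * s.tau_id.tau,
                              role="inverse_dynamics")
        # scaling the reference and predictions together leaves the
        # normalised error unchanged; here we check reference-RMS
        # normalisation directly on a common parameter vector
        x = m1._x_nominal()
        r1 = m1.objective(x)
        doubled = {n: p.with_(f_max=3.0 * p.f_max) for n, p in nominal.items()}
        m2 = TorqueCalibration(env, s.angle, s.velocity, scaled, doubled,
                               curves=subject.curves, geometry=subject.geometry)
        # tripling F_max triples tau_pred only in the active term, so use the
        # invariance of the identity fit instead
        assert m2.objective(m2._x_nominal()) == pytest.approx(r1, rel=1e-9)

    def test_multistart_recovery_count(self, subject, calibration_session):
        s = calibration_session
        model = TorqueCalibration(
            kinematic_envelope(s), s.angle, s.velocity, s.tau_id,
            _offset_nominal(subject.muscles), curves=subject.curves,
            geometry=subject.geometry)
        res = model.fit(n_starts=5)
        good = sum(1 for _, f, _ in res.starts if f < 1e-3)
        # early stop after an exact fit counts as success for skipped starts
        assert good >= 1 and res.objective < 1e-6

    def test_misaligned_inputs_rejected(self, subject, calibration_session):
        s = calibration_session
        with pytest.raises(ValueError):
            TorqueCalibration(kinematic_envelope(s), s.angle[:-1],
                              s.velocity[:-1], s.tau_id, dict(subject.muscles))

    def test_bse_finite(self, subject, calibration_session):
        s = calibration_session
        model = TorqueCalibration(
            kinematic_envelope(s), s.angle, s.velocity, s.tau_id,
            dict(subject.muscles), curves=subject.curves,
            geometry=subject.geometry)
        res = model.fit(n_starts=1)
        assert np.all(np.isfinite(res.bse()))
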