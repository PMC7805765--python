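"""Subject-specific tuning of the EMG-driven torque model.

The calibration session drives the elbow along a reference trajectory

    theta_d(t) = A0 + A sin(2 pi f(t) t),  A0 = A = 45 deg,

after a 20 s rest at full extension, with a step-wise frequency schedule
(0.05 to 0.5 Hz in 0.05 Hz increments, 20 s per step, phase carried across
steps so the profile stays continuous). A planar single-joint inverse-dynamics
surrogate converts the recorded kinematics to a reference torque, and the
model parameters — optimal fiber length, tendon slack length, maximum
isometric force and the EMG-to-activation shape factor, per muscle — are tuned
by minimising the RMS torque error normalised by the RMS of the reference,
with a deterministic multi-start bounded optimiser.

The calibration is exposed statsmodels-style: build a
:class:`TorqueCalibration` from the aligned session data, call
:meth:`TorqueCalibration.fit`, and inspect the returned
:class:`CalibrationResult` (fitted parameters, per-start diagnostics,
approximate standard errors, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, signal

from .myoprocessor import (
    GeometryModel,
    HillCurveParams,
    MuscleParams,
    TorqueSeries,
    default_geometry,
    estimate_torque_series,
)
from .signal_processing import EmgEnvelope
from .suit import PlantParams


@dataclass(frozen=True)
class CalibrationTrajectorySpec:
    """Reference elbow trajectory of the dynamic calibration.

    Angles are degrees here (the study's reporting convention); the generated
    series is radians. ``ramp`` is the duration of the minimum-jerk blend from
    rest (0 deg) to the sinusoid offset at the end of the rest block, so the
    profile is continuous while each dwell follows the sinusoid literally.
    """

    a0: float = 45.0
    amplitude: float = 45.0
    freqs: Sequence[float] = tuple(np.round(np.arange(1, 11) * 0.05, 2))
    dwell: float = 20.0
    rest: float = 20.0
    ramp: float = 2.0

    def __post_init__(self):
        if self.a0 - self.amplitude < -1e-9:
            raise ValueError("A0 - A must be >= 0 (angle cannot go negative)")
        if not self.dwell > 0:
            raise ValueError("dwell must be positive")
        if not 0 <= self.ramp <= self.rest:
            raise ValueError("ramp must fit inside the rest block")

    @property
    def duration(self) -> float:
        return self.rest + self.dwell * len(self.freqs)


def _minimum_jerk(s):
    """Minimum-jerk position profile and its first two derivatives on s in [0,1]."""
    s = np.clip(s, 0.0, 1.0)
    pos = 10 * s**3 - 15 * s**4 + 6 * s**5
    vel = 30 * s**2 - 60 * s**3 + 30 * s**4
    acc = 60 * s - 180 * s**2 + 120 * s**3
    return pos, vel, acc


def calibration_kinematics(spec: CalibrationTrajectorySpec, fs: float):
    """Reference angle, velocity and acceleration series (rad, rad/s, rad/s^2).

    Analytic within each segment: rest at 0, a minimum-jerk ramp to the
    sinusoid offset, then phase-continuous sinusoidal dwells.
    """
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz")
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    a0 = np.radians(spec.a0)
    amp = np.radians(spec.amplitude)
    theta = np.zeros(n)
    omega = np.zeros(n)
    alpha = np.zeros(n)

    ramp_start = spec.rest - spec.ramp
    in_ramp = (t >= ramp_start) & (t < spec.rest)
    if spec.ramp > 0:
        s = (t[in_ramp] - ramp_start) / spec.ramp
        pos, vel, acc = _minimum_jerk(s)
        theta[in_ramp] = a0 * pos
        omega[in_ramp] = a0 * vel / spec.ramp
        alpha[in_ramp] = a0 * acc / spec.ramp**2

    phase0 = 0.0
    seg_start = spec.rest
    for f in spec.freqs:
        seg = (t >= seg_start) & (t < seg_start + spec.dwell)
        tl = t[seg] - seg_start
        w = 2 * np.pi * f
        theta[seg] = a0 + amp * np.sin(w * tl + phase0)
        omega[seg] = amp * w * np.cos(w * tl + phase0)
        alpha[seg] = -amp * w**2 * np.sin(w * tl + phase0)
        phase0 = (phase0 + w * spec.dwell) % (2 * np.pi)
        seg_start += spec.dwell
    return t, theta, omega, alpha


def reference_trajectory(spec: CalibrationTrajectorySpec, fs: float) -> np.ndarray:
    """Reference elbow angle series theta_d(t) in radians."""
    return calibration_kinematics(spec, fs)[1]


def planar_inverse_dynamics(
    angle: np.ndarray,
    velocity: np.ndarray,
    plant: PlantParams,
    accel: np.ndarray | None = None,
    fs: float | None = None,
) -> TorqueSeries:
    """Elbow torque from a planar single-joint inverse-dynamics model.

    tau = I_total * alpha + g (m r_com + m_load l_load) sin(phi), with the
    gravity lever maximal at 90 deg flexion (forearm horizontal). If the
    acceleration is not supplied it is obtained by smoothed differentiation of
    the velocity (central differences + 4 Hz zero-phase low-pass), which
    requires ``fs``.
    """
    angle = np.asarray(angle, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if plant is None:
        raise ValueError("plant inertial parameters are required")
    if accel is None:
        if fs is None:
            raise ValueError("fs is required to differentiate the velocity")
        accel = np.gradient(velocity, 1.0 / fs)
        sos = signal.butter(2, 4.0, "lowpass", fs=fs, output="sos")
        accel = signal.sosfiltfilt(sos, accel)
    else:
        accel = np.asarray(accel, dtype=float)
    if fs is None:
        fs = 1.0
    tau = plant.total_inertia * accel + plant.gravity_torque(angle)
    t = np.arange(angle.size) / fs
    return TorqueSeries(t=t, tau=tau, role="inverse_dynamics")


@dataclass(frozen=True)
class CalibrationBounds:
    """Optimiser bounds: multiplicative around nominal for l0, lst and F_max;
    absolute for the activation shape factor."""

    l0_rel: tuple = (0.85, 1.15)
    lst_rel: tuple = (0.85, 1.15)
    f_max_rel: tuple = (0.5, 2.0)
    shape_abs: tuple = (-5.0, -0.01)

    def __post_init__(self):
        for lo, hi in (self.l0_rel, self.lst_rel, self.f_max_rel, self.shape_abs):
            if not lo < hi:
                raise ValueError("each lower bound must be below its upper bound")


_PARAM_NAMES = ("l0_factor", "lst_factor", "f_max_factor", "shape")


class TorqueCalibration:
    """Torque-calibration model over one aligned calibration session.

    Parameters
    ----------
    envelope : EmgEnvelope
        Normalised EMG envelopes; must contain one channel per tuned muscle.
    angle, velocity : ndarray
        Elbow kinematics (rad, rad/s) at the envelope's sampling rate.
    tau_ref : TorqueSeries
        Reference torque from inverse dynamics, aligned with the envelope.
    nominal : mapping muscle name -> MuscleParams
        Starting values; the fit tunes multiplicative factors on l0, lst and
        F_max and the absolute activation shape factor per muscle.
    fit_fs : float
        Internal resampling rate of the objective (downsampling speeds up the
        fit without losing the <= 4 Hz envelope content).
    """

    def __init__(
        self,
        envelope: EmgEnvelope,
        angle: np.ndarray,
        velocity: np.ndarray,
        tau_ref: TorqueSeries,
        nominal: Mapping[str, MuscleParams],
        curves: HillCurveParams | None = None,
        geometry: GeometryModel | None = None,
        bounds: CalibrationBounds | None = None,
        fit_fs: float = 50.0,
    ):
        angle = np.asarray(angle, dtype=float)
        velocity = np.asarray(velocity, dtype=float)
        if not (envelope.n_samples == angle.size == velocity.size
                == tau_ref.tau.size):
            raise ValueError("envelope, kinematics and tau_ref must be aligned")
        self.nominal = dict(nominal)
        self.muscle_names = tuple(self.nominal)
        self.curves = curves or HillCurveParams()
        self.geometry = geometry or default_geometry()
        self.bounds = bounds or CalibrationBounds()

        # downsample everything once for the objective
        step = max(1, int(round(envelope.fs / fit_fs)))
        self.fs = envelope.fs / step
        cols = [envelope.channel(m)[::step] for m in self.muscle_names]
        self._env = EmgEnvelope(np.column_stack(cols), fs=self.fs,
                                channels=self.muscle_names)
        self._angle = angle[::step]
        self._velocity = velocity[::step]
        self._tau_ref = tau_ref.tau[::step]
        self._ref_rms = float(np.sqrt(np.mean(self._tau_ref**2)))
        if not np.isfinite(self._ref_rms) or self._ref_rms == 0:
            raise ValueError("reference torque has zero or non-finite RMS")

    # -- parameter vector <-> muscle parameters -------------------------------
    def _unpack(self, x: np.ndarray) -> dict:
        params = {}
        for i, name in enumerate(self.muscle_names):
            l0f, lstf, fmf, shape = x[4 * i: 4 * i + 4]
            nom = self.nominal[name]
            params[name] = nom.with_(
                l0=nom.l0 * l0f, lst=nom.lst * lstf, f_max=nom.f_max * fmf,
                activation=replace(nom.activation, shape=shape),
            )
        return params

    def _x_nominal(self) -> np.ndarray:
        return np.array(
            [v for name in self.muscle_names
             for v in (1.0, 1.0, 1.0, self.nominal[name].activation.shape)]
        )

    def _x_bounds(self):
        b = self.bounds
        per = [b.l0_rel, b.lst_rel, b.f_max_rel, b.shape_abs]
        return per * len(self.muscle_names)

    def predict(self, params: Mapping[str, MuscleParams] | np.ndarray) -> np.ndarray:
        """Model torque over the (downsampled) calibration window."""
        if not isinstance(params, Mapping):
            params = self._unpack(np.asarray(params, dtype=float))
        ts = estimate_torque_series(self._env, self._angle, self._velocity,
                                    params, self.curves, self.geometry)
        return ts.tau

    def objective(self, x: np.ndarray) -> float:
        """Normalised torque error: RMS(tau_pred - tau_ref)/RMS(tau_ref)."""
        resid = self.predict(x) - self._tau_ref
        val = float(np.sqrt(np.mean(resid**2))) / self._ref_rms
        if not np.isfinite(val):
            raise ValueError("objective is non-finite; check the session data")
        return val

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        return (self.predict(x) - self._tau_ref) / self._ref_rms

    def fit(self, n_starts: int = 5, seed: int = 12345,
            max_nfev: int = 400) -> "CalibrationResult":
        """Deterministic multi-start bounded least squares (trust-region
        reflective on the normalised torque residuals).

        The first start is the nominal parameter set; the remaining starts are
        drawn uniformly inside the bounds from a fixed-seed generator, so the
        fit is reproducible. Returns the best iterate even when an individual
        start fails to converge (flagged in the diagnostics).
        """
        bounds = self._x_bounds()
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        # the nominal start is clipped into the bounds (bounds need not
        # contain the nominal point)
        starts = [np.clip(self._x_nominal(), lo, hi)]
        for _ in range(max(0, n_starts - 1)):
            starts.append(lo + rng.uniform(size=lo.size) * (hi - lo))

        runs = []
        for x0 in starts:
            ls = optimize.least_squares(
                self._residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
            )
            ls.fun = float(np.sqrt(np.mean(ls.fun**2)))  # -> normalised RMSE
            runs.append(ls)
            if ls.fun < 1e-8:  # exact fit found; further starts cannot improve
                break
        best = min(runs, key=lambda r: r.fun)
        at_bounds = {}
        for i, name in enumerate(self.muscle_names):
            flags = {}
            for j, pname in enumerate(_PARAM_NAMES):
                lo_j, hi_j = bounds[4 * i + j]
                v = best.x[4 * i + j]
                tol = 1e-6 * (hi_j - lo_j)
                flags[pname] = bool(v - lo_j < tol or hi_j - v < tol)
            at_bounds[name] = flags
        return CalibrationResult(
            model=self, x=best.x.copy(), params=self._unpack(best.x),
            objective=float(best.fun), converged=bool(best.success),
            starts=[(r.x.copy(), float(r.fun), bool(r.success)) for r in runs],
            at_bounds=at_bounds,
        )


@dataclass
class CalibrationResult:
    """Fitted muscle parameters with diagnostics.

    ``objective`` is the normalised torque RMSE (dimensionless, >= 0);
    ``starts`` lists (x, objective, converged) for every optimiser start;
    ``at_bounds`` flags parameters pinned at a calibration bound.
    """

    model: TorqueCalibration
    x: np.ndarray
    params: dict
    objective: float
    converged: bool
    starts: list
    at_bounds: dict
    _bse: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_converged_starts(self) -> int:
        return sum(1 for _, _, ok in self.starts if ok)

    def predict(self) -> np.ndarray:
        return self.model.predict(self.params)

    def bse(self, rel_step: float = 1e-4) -> np.ndarray:
        """Approximate standard errors from a Gauss–Newton linearisation of
        the residual vector at the optimum."""
        if self._bse is not None:
            return self._bse
        m = self.model
        resid0 = self.predict() - m._tau_ref
        J = np.empty((resid0.size, self.x.size))
        for j in range(self.x.size):
            dx = self.x.copy()
            h = rel_step * max(1.0, abs(dx[j]))
            dx[j] += h
            J[:, j] = (m.predict(dx) - m._tau_ref - resid0) / h
        dof = max(resid0.size - self.x.size, 1)
        sigma2 = float(resid0 @ resid0) / dof
        cov = sigma2 * np.linalg.pinv(J.T @ J)
        self._bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return self._bse

    def summary(self) -> str:
        lines = [
            "Torque-model calibration",
            "=" * 64,
            f"normalized torque RMSE : {self.objective:.6g}",
            f"converged              : {self.converged} "
            f"({self.n_converged_starts}/{len(self.starts)} starts)",
            "",
            f"{'muscle':<10}{'parameter':<14}{'nominal':>10}{'fitted':>12}"
            f"{'at bound':>10}",
            "-" * 64,
        ]
        for name in self.model.muscle_names:
            nom = self.model.nominal[name]
            fit = self.params[name]
            rows = [
                ("l0 (m)", nom.l0, fit.l0, self.at_bounds[name]["l0_factor"]),
                ("lst (m)", nom.lst, fit.lst, self.at_bounds[name]["lst_factor"]),
                ("F_max (N)", nom.f_max, fit.f_max,
                 self.at_bounds[name]["f_max_factor"]),
                ("A (shape)", nom.activation.shape, fit.activation.shape,
                 self.at_bounds[name]["shape"]),
            ]
            for pname, nv, fv, flag in rows:
                lines.append(f"{name:<10}{pname:<14}{nv:>10.4g}{fv:>12.5g}"
                             f"{'*' if flag else '':>10}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        m = self.model
        t = np.arange(m._tau_ref.size) / m.fs
        ax.plot(t, m._tau_ref, label="reference torque")
        ax.plot(t, self.predict(), label="model torque", alpha=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("torque (N m)")
        ax.legend()
        return ax
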