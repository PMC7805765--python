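"""Cable-driven exosuit: geometry, admittance control and closed-loop simulation.

The suit routes an artificial tendon across the elbow between two anchor
points. With forearm half-width ``a`` and elbow-to-anchor distance ``b``, the
cable displacement as a function of the elbow flexion angle is

    h_f(phi_e) = 2 sqrt(a^2 + b^2) cos(atan(a/b) + phi_e/2) - 2 b,

so h_f(0) = 0 (cable taut at full extension) and h_f decreases with flexion
(the anchors approach and the cable shortens). The cable moment arm is the
analytic derivative J = d h_f / d phi_e; tension can only pull, so the torque
the suit applies to the joint is tau_i = |J| f (flexion positive).

The torque loop is an admittance law Y(s) = omega_r/e_r = (Kp + Ki/s)/(1 + Kd s)
discretised with the bilinear (Tustin) transform. A surrogate inner loop — a
first-order velocity servo on the motor with velocity feedforward — reels the
cable; tension comes from a configurable series stiffness acting on the cable
stretch (the physical tendon is nearly inextensible, but a compliant series
element is required for a well-posed tension simulation). The wearer's forearm
is a rigid pendulum with gravity and an optional hand load, integrated with
fixed-step RK4 at the controller rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .myoprocessor import GEOMETRY_DOMAIN, TorqueSeries

GRAVITY = 9.81  # m/s^2


class ClosedLoopUnstableError(RuntimeError):
    """Raised when the closed-loop simulation diverges."""


@dataclass(frozen=True)
class SuitGeometry:
    """Anchor geometry: forearm half-width ``a`` and elbow-to-distal-anchor
    distance ``b`` (both metres)."""

    a: float = 0.04
    b: float = 0.12

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("suit geometry requires a > 0 and b > 0")


def _check_domain(phi_e):
    phi_e = np.asarray(phi_e, dtype=float)
    lo, hi = GEOMETRY_DOMAIN
    if np.any(phi_e < lo) or np.any(phi_e > hi):
        warnings.warn("elbow angle outside cable-geometry domain; clamped",
                      stacklevel=3)
    return np.clip(phi_e, lo, hi)


def cable_displacement(phi_e, g: SuitGeometry):
    """Cable displacement h_f(phi_e) in metres; 0 at full extension and
    monotonically decreasing with flexion."""
    phi_e = _check_domain(phi_e)
    hyp = np.hypot(g.a, g.b)
    out = 2.0 * hyp * np.cos(np.arctan2(g.a, g.b) + phi_e / 2.0) - 2.0 * g.b
    return out if np.ndim(out) else float(out)


def cable_moment_arm(phi_e, g: SuitGeometry):
    """Analytic cable moment arm J = d h_f / d phi_e (metres, negative)."""
    phi_e = _check_domain(phi_e)
    hyp = np.hypot(g.a, g.b)
    out = -hyp * np.sin(np.arctan2(g.a, g.b) + phi_e / 2.0)
    return out if np.ndim(out) else float(out)


def interaction_torque(f, phi_e, g: SuitGeometry):
    """Torque the suit applies to the elbow: tau_i = |J(phi_e)| f, flexion
    positive. The load cell measures tension only, so f must be >= 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("cable tension cannot be negative (tendon only pulls)")
    out = np.abs(cable_moment_arm(phi_e, g)) * f
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class ControllerGains:
    """Admittance PID gains plus surrogate inner-loop parameters.

    Kp (rad/s per N m), Ki (rad/s^2 per N m) and Kd (s) shape
    Y(s) = (Kp + Ki/s)/(1 + Kd s). ``motor_tau`` is the time constant of the
    first-order velocity servo; ``ff_vel``/``ff_acc`` scale the joint velocity
    and acceleration feedforward added to the commanded motor velocity.
    Defaults give a stiff, slightly underdamped torque step response with the
    default plant and suit geometry.
    """

    kp: float = 0.6
    ki: float = 6.0
    kd: float = 0.005
    motor_tau: float = 0.02
    ff_vel: float = 1.0
    ff_acc: float = 0.0

    def __post_init__(self):
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("PID gains must be non-negative")
        if not self.motor_tau > 0:
            raise ValueError("motor time constant must be positive")


class AdmittanceController:
    """Discrete-time admittance law (Tustin discretisation of Eq. Y(s)).

    State carries the trapezoidal integrator and the first-order derivative
    lag. With Ki = Kd = 0 the update reduces exactly to omega_r = Kp e_r.
    """

    def __init__(self, gains: ControllerGains):
        self.gains = gains
        self.reset()

    def reset(self):
        self._integ = 0.0
        self._e_prev = 0.0
        self._u_prev = 0.0
        self._y_prev = 0.0

    def step(self, e_r: float, dt: float) -> float:
        """One discrete update: torque error (N m) -> commanded velocity (rad/s)."""
        if not dt > 0:
            raise ValueError("dt must be positive")
        g = self.gains
        self._integ += 0.5 * g.ki * (e_r + self._e_prev) * dt
        u = g.kp * e_r + self._integ
        if g.kd == 0.0:
            y = u
        else:  # bilinear transform of 1/(1 + Kd s)
            y = ((2.0 * g.kd - dt) * self._y_prev + dt * (u + self._u_prev)) \
                / (2.0 * g.kd + dt)
        self._e_prev = e_r
        self._u_prev = u
        self._y_prev = y
        return y


@dataclass(frozen=True)
class PlantParams:
    """Rigid-pendulum surrogate of the wearer's forearm.

    inertia : forearm+hand inertia about the elbow (kg m^2), load excluded
    m_r_com : forearm mass times centre-of-mass distance (kg m)
    load_mass, load_lever : hand-held load (kg) and its lever about the elbow (m)
    damping : viscous joint damping (N m s/rad)

    The elbow angle is 0 at full extension with the upper arm vertical, so the
    gravity lever is sin(phi_e), maximal at 90 deg flexion.
    """

    inertia: float = 0.08
    m_r_com: float = 0.225
    load_mass: float = 0.0
    load_lever: float = 0.30
    damping: float = 0.5
    g: float = GRAVITY

    def __post_init__(self):
        if not self.inertia > 0:
            raise ValueError("inertia must be positive")

    @property
    def total_inertia(self) -> float:
        return self.inertia + self.load_mass * self.load_lever**2

    def gravity_torque(self, phi_e):
        """Flexion torque needed to hold the forearm against gravity (N m)."""
        lever = self.m_r_com + self.load_mass * self.load_lever
        out = self.g * lever * np.sin(np.asarray(phi_e, dtype=float))
        return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class AssistCondition:
    """Study assistance condition: label and torque scaling gain."""

    label: str
    gain: float

    LEVELS = {"NE": 0.0, "LA": 0.6, "MA": 0.9, "HA": 1.2}

    def __post_init__(self):
        if self.label not in self.LEVELS:
            raise ValueError(f"label must be one of {tuple(self.LEVELS)}")
        if abs(self.gain - self.LEVELS[self.label]) > 1e-12:
            raise ValueError(
                f"condition {self.label} must use gain {self.LEVELS[self.label]}"
            )

    @classmethod
    def from_label(cls, label: str) -> "AssistCondition":
        return cls(label, cls.LEVELS[label])


@dataclass
class SimulationLog:
    """Closed-loop trajectory log (uniform sampling at the controller rate)."""

    t: np.ndarray
    phi: np.ndarray
    omega: np.ndarray
    tension: np.ndarray
    tau_i: np.ndarray
    tau_r: np.ndarray
    e_r: np.ndarray
    condition: str

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "t_s": self.t, "phi_rad": self.phi, "omega_rad_s": self.omega,
            "tension_N": self.tension, "tau_i_Nm": self.tau_i,
            "tau_r_Nm": self.tau_r, "e_r_Nm": self.e_r,
        })

    def interaction_series(self) -> TorqueSeries:
        return TorqueSeries(self.t, self.tau_i, role="interaction")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
        ax[0].plot(self.t, np.degrees(self.phi), label="elbow angle (deg)")
        ax[0].set_ylabel("angle (deg)")
        ax[0].legend()
        ax[1].plot(self.t, self.tau_r, label=r"$\tau_r$ (scaled)")
        ax[1].plot(self.t, self.tau_i, label=r"$\tau_i$")
        ax[1].set_xlabel("time (s)")
        ax[1].set_ylabel("torque (N m)")
        ax[1].legend()
        return ax


def simulate_closed_loop(
    tau_r,
    plant: PlantParams,
    gains: ControllerGains,
    geometry: SuitGeometry,
    condition: AssistCondition,
    duration: float,
    dt: float = 1e-3,
    phi0: float = 0.0,
    omega0: float = 0.0,
    series_stiffness: float = 5000.0,
    prescribed_angle=None,
    tau_human=None,
) -> SimulationLog:
    """Simulate the torque-tracking loop end to end.

    Per step: the myoprocessor reference is scaled by the assistance gain,
    compared to the measured interaction torque, converted to a motor velocity
    by the admittance law, tracked by the surrogate velocity servo that reels
    the cable, and the resulting tension drives the pendulum plant (RK4,
    fixed step ``dt``).

    Parameters
    ----------
    tau_r : callable or ndarray
        Reference torque (N m) as a function of time, or a sample array at the
        controller rate.
    condition : AssistCondition
        With gain 0 (NE: device not worn) the actuation path is disabled and
        the plant follows its passive dynamics exactly.
    prescribed_angle : callable or None
        If given, the elbow follows this angle trajectory (the wearer imposes
        the posture, e.g. an isometric hold) and only the actuation states are
        integrated.
    tau_human : callable or None
        Optional additional joint torque produced by the wearer (dynamic
        plant only).
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if not dt > 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    if callable(tau_r):
        tau_r_samples = np.array([float(tau_r(tk)) for tk in t])
    else:
        tau_r_samples = np.asarray(tau_r, dtype=float)
        if tau_r_samples.size < n:
            raise ValueError("tau_r sample array shorter than the simulation")
        tau_r_samples = tau_r_samples[:n]

    ctrl = AdmittanceController(gains)
    k_s = float(series_stiffness)
    gain = condition.gain
    I_tot = plant.total_inertia

    phi = float(phi0)
    omega = float(omega0)
    v_m = 0.0   # motor cable reel-in velocity (m/s)
    x_m = 0.0   # motor cable reel-in position (m)

    log_phi = np.empty(n)
    log_omega = np.empty(n)
    log_f = np.empty(n)
    log_ti = np.empty(n)
    log_tr = np.empty(n)
    log_e = np.empty(n)

    def tension(phi_k, x_k):
        stretch = x_k + cable_displacement(phi_k, geometry)
        return k_s * max(0.0, stretch)

    def accel(phi_k, omega_k, ti_k, tk):
        th = float(tau_human(tk)) if tau_human is not None else 0.0
        return (ti_k - plant.gravity_torque(phi_k)
                - plant.damping * omega_k + th) / I_tot

    for k in range(n):
        tk = t[k]
        if prescribed_angle is not None:
            phi = float(prescribed_angle(tk))
            phi_next = float(prescribed_angle(tk + dt))
            omega = (phi_next - phi) / dt
        arm = abs(cable_moment_arm(phi, geometry)) if gain != 0.0 else 0.0
        f = tension(phi, x_m) if gain != 0.0 else 0.0
        tau_i = arm * f
        tau_ref = gain * tau_r_samples[k]
        e_r = tau_ref - tau_i

        log_phi[k] = phi
        log_omega[k] = omega
        log_f[k] = f
        log_ti[k] = tau_i
        log_tr[k] = tau_ref
        log_e[k] = e_r

        if gain != 0.0:
            omega_cmd = ctrl.step(e_r, dt) + gains.ff_vel * omega
            v_cmd = arm * omega_cmd
            # motor servo + reel position (exact update of the linear servo
            # over the step, commanded velocity held)
            alpha = np.exp(-dt / gains.motor_tau)
            x_m += v_cmd * dt + (v_m - v_cmd) * gains.motor_tau * (1.0 - alpha)
            v_m = v_cmd + (v_m - v_cmd) * alpha

        if prescribed_angle is None:
            # RK4 on (phi, omega); tension re-evaluated at each stage
            def deriv(p_k, w_k, tk_):
                if gain != 0.0:
                    ti_k = abs(cable_moment_arm(p_k, geometry)) * tension(p_k, x_m)
                else:
                    ti_k = 0.0
                return w_k, accel(p_k, w_k, ti_k, tk_)

            k1p, k1w = deriv(phi, omega, tk)
            k2p, k2w = deriv(phi + 0.5 * dt * k1p, omega + 0.5 * dt * k1w, tk + 0.5 * dt)
            k3p, k3w = deriv(phi + 0.5 * dt * k2p, omega + 0.5 * dt * k2w, tk + 0.5 * dt)
            k4p, k4w = deriv(phi + dt * k3p, omega + dt * k3w, tk + dt)
            phi += dt * (k1p + 2 * k2p + 2 * k3p + k4p) / 6.0
            omega += dt * (k1w + 2 * k2w + 2 * k3w + k4w) / 6.0

        if abs(omega) > 1e3:
            raise ClosedLoopUnstableError(
                f"divergence at t={tk:.3f} s: |omega|={abs(omega):.1f} rad/s "
                f"(gains {gains}, condition {condition.label})"
            )

    return SimulationLog(t=t, phi=log_phi, omega=log_omega, tension=log_f,
                         tau_i=log_ti, tau_r=log_tr, e_r=log_e,
                         condition=condition.label)
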