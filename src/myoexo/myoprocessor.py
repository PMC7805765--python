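"""EMG-driven elbow torque estimation (the "myoprocessor").

The chain maps a normalised EMG envelope u_j(t) and the elbow kinematics to an
estimated flexion/extension torque:

1. activation dynamics — a_j = (exp(A_j u_j) - 1)/(exp(A_j) - 1), the standard
   nonlinear EMG-to-activation map with shape factor A_j;
2. muscle–tendon (MTU) kinematics — per-muscle path length lmt(phi_e) from a
   smooth polynomial table, with moment arm r = -d lmt / d phi_e (flexors
   positive under the flexion-positive angle convention, 0 rad = full
   extension);
3. rigid-tendon Hill-type contraction dynamics — with the tendon fixed at its
   slack length, fiber length is algebraic in lmt; the tendon-line force is
   F = F_max [a f_l(l~) f_v(v~) + f_p(l~)] cos(phi_p), clamped at zero
   (muscles cannot push);
4. joint torque — tau_r = sum_j r_j F_j.

The active and passive curve shapes (Gaussian force–length, Hill-type
force–velocity with a smooth eccentric plateau, exponential passive curve) are
closed forms with configurable constants; defaults follow the standard
musculoskeletal-modelling literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from numpy.polynomial import Polynomial

from .signal_processing import EmgEnvelope

#: fitted range of the geometry tables (rad); 0 = full elbow extension
GEOMETRY_DOMAIN = (0.0, 2.6)

#: fiber length lower clamp when the MTU goes slack, as a fraction of l0
SLACK_CLAMP = 0.3


@dataclass(frozen=True)
class ActivationParams:
    """Shape factor A of the nonlinear EMG-to-activation map."""

    shape: float = -2.0

    def __post_init__(self):
        if not np.isfinite(self.shape) or abs(self.shape) > 5.0:
            raise ValueError("activation shape factor must be finite with |A| <= 5")


def activation(u, p: ActivationParams | float):
    """Map a normalised envelope value u in [0, 1] to activation a in [0, 1].

    a = (exp(A u) - 1)/(exp(A) - 1); a(0) = 0, a(1) = 1, strictly increasing.
    A == 0 is the linear limit a = u. Values of u above 1 are clipped with a
    warning (an envelope can transiently exceed the MVC normalisation).
    """
    A = p.shape if isinstance(p, ActivationParams) else float(p)
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("envelope contains non-finite values")
    if np.any(u > 1.0):
        warnings.warn("envelope values above 1 clipped to 1", stacklevel=2)
    u = np.clip(u, 0.0, 1.0)
    if A == 0.0:
        out = u
    else:
        out = np.expm1(A * u) / np.expm1(A)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MuscleParams:
    """Per-muscle rigid-tendon Hill-model constants.

    f_max : maximum isometric force (N)
    l0 : optimal fiber length (m)
    lst : tendon slack length (m); rigid tendon, so tendon length == lst
    phi0 : pennation angle at optimal fiber length (rad)
    """

    f_max: float
    l0: float
    lst: float
    phi0: float = 0.0
    activation: ActivationParams = field(default_factory=ActivationParams)

    def __post_init__(self):
        if not self.f_max > 0:
            raise ValueError("f_max must be positive")
        if not self.l0 > 0:
            raise ValueError("l0 must be positive")
        if self.lst < 0:
            raise ValueError("lst must be non-negative")
        if not (0.0 <= self.phi0 < np.pi / 2):
            raise ValueError("phi0 must lie in [0, pi/2)")

    def with_(self, **kw) -> "MuscleParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class HillCurveParams:
    """Constants of the normalised Hill curves.

    gamma : Gaussian force–length width (on normalised fiber length)
    v_max : maximum shortening velocity (optimal fiber lengths per second)
    k_v : concentric curvature of the force–velocity curve
    f_ecc : eccentric force plateau (>= 1)
    k_p : passive exponential shape
    eps0 : passive strain at one normalised force unit: f_p(1 + eps0) = 1
    """

    gamma: float = 0.45
    v_max: float = 10.0
    k_v: float = 0.25
    f_ecc: float = 1.4
    k_p: float = 4.0
    eps0: float = 0.6

    def __post_init__(self):
        ok = (self.gamma > 0 and self.v_max > 0 and 0 < self.k_v < 1
              and self.f_ecc >= 1 and self.k_p > 0 and self.eps0 > 0)
        if not ok:
            raise ValueError("invalid Hill curve constants")


def force_length(l_norm, c: HillCurveParams):
    """Active force–length: Gaussian peaking at 1 when l~ = 1."""
    l_norm = np.asarray(l_norm, dtype=float)
    out = np.exp(-np.square(l_norm - 1.0) / c.gamma)
    return out if out.ndim else float(out)


def force_velocity(v_norm, c: HillCurveParams):
    """Force–velocity multiplier on normalised fiber velocity v~ = vm/(v_max l0).

    Concentric branch (v~ in [-1, 0]): (1 + v~)/(1 - v~/k_v), reaching 0 at
    the maximum shortening velocity. Eccentric branch: a saturating hyperbola
    (f_ecc v~ + k_e)/(v~ + k_e) with k_e chosen for C1 continuity at v~ = 0,
    approaching the plateau f_ecc from below.
    """
    v = np.asarray(v_norm, dtype=float)
    conc = np.clip(1.0 + v, 0.0, None) / (1.0 - np.minimum(v, 0.0) / c.k_v)
    k_e = (c.f_ecc - 1.0) * c.k_v / (c.k_v + 1.0)
    vpos = np.maximum(v, 0.0)
    ecc = (c.f_ecc * vpos + k_e) / (vpos + k_e)
    out = np.where(v <= 0.0, conc, ecc)
    return out if out.ndim else float(out)


def passive_force(l_norm, c: HillCurveParams):
    """Parallel passive elastic force: zero below optimum, exponential above,
    normalised so that f_p(1 + eps0) = 1 exactly."""
    l_norm = np.asarray(l_norm, dtype=float)
    strain = np.clip(l_norm - 1.0, 0.0, None)
    out = np.expm1(c.k_p * strain / c.eps0) / np.expm1(c.k_p)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FiberState:
    """Rigid-tendon fiber kinematics: length (m), velocity (m/s, shortening
    negative), pennation (rad) and a slack flag."""

    lm: np.ndarray
    vm: np.ndarray
    phi: np.ndarray
    slack: np.ndarray


def fiber_state(lmt, vmt, p: MuscleParams) -> FiberState:
    """Fiber length/velocity/pennation from MTU length and velocity.

    Constant-thickness pennation model (l0 sin(phi0) conserved):
    lm = sqrt((lmt - lst)^2 + (l0 sin phi0)^2), phi = atan2(l0 sin phi0,
    lmt - lst), vm = vmt cos(phi). When lmt <= lst the MTU is slack: the
    fiber is clamped at SLACK_CLAMP*l0 and the force contribution is zeroed
    downstream.
    """
    lmt = np.asarray(lmt, dtype=float)
    vmt = np.asarray(vmt, dtype=float)
    h = p.l0 * np.sin(p.phi0)
    w = lmt - p.lst
    slack = w <= 0.0
    if np.any(slack):
        warnings.warn("MTU length at or below tendon slack length; "
                      "slack fiber state returned", stacklevel=2)
    w_eff = np.clip(w, 0.0, None)
    lm = np.maximum(np.hypot(w_eff, h), SLACK_CLAMP * p.l0)
    phi = np.arctan2(h, np.maximum(w_eff, 1e-12)) if h else np.zeros_like(w_eff)
    vm = vmt * np.cos(phi)
    return FiberState(lm=lm, vm=vm, phi=phi, slack=slack)


def hill_force(a, lm, vm, phi, p: MuscleParams, c: HillCurveParams) -> np.ndarray:
    """Tendon-line force F = F_max [a f_l f_v + f_p] cos(phi), clamped >= 0."""
    a = np.asarray(a, dtype=float)
    lm = np.asarray(lm, dtype=float)
    vm = np.asarray(vm, dtype=float)
    phi = np.asarray(phi, dtype=float)
    for name, arr in (("a", a), ("lm", lm), ("vm", vm), ("phi", phi)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    l_norm = lm / p.l0
    v_norm = vm / (c.v_max * p.l0)
    f = p.f_max * (a * force_length(l_norm, c) * force_velocity(v_norm, c)
                   + passive_force(l_norm, c)) * np.cos(phi)
    out = np.clip(f, 0.0, None)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MtuGeometrySample:
    """MTU length (m) and signed moment arm (m) at one or more elbow angles."""

    lmt: np.ndarray
    r: np.ndarray


@dataclass(frozen=True)
class GeometryModel:
    """Per-muscle smooth lmt(phi_e) tables; moment arms derived analytically.

    ``curves`` maps muscle name -> numpy Polynomial giving lmt in metres as a
    function of the elbow flexion angle in radians on GEOMETRY_DOMAIN.
    The moment arm is r = -d lmt / d phi_e, so flexors (lmt shortening with
    flexion) get positive arms and extensors negative ones. Evaluation outside
    the fitted domain is clamped with a warning.
    """

    curves: Mapping[str, Polynomial]
    domain: tuple = GEOMETRY_DOMAIN

    def __post_init__(self):
        object.__setattr__(self, "curves", dict(self.curves))

    def muscles(self):
        return tuple(self.curves)

    def _clamp(self, phi_e):
        phi_e = np.asarray(phi_e, dtype=float)
        if not np.all(np.isfinite(phi_e)):
            raise ValueError("elbow angle must be finite")
        lo, hi = self.domain
        if np.any(phi_e < lo) or np.any(phi_e > hi):
            warnings.warn(
                f"elbow angle outside fitted domain [{lo}, {hi}] rad; clamped",
                stacklevel=3,
            )
        return np.clip(phi_e, lo, hi)

    def lmt(self, muscle: str, phi_e):
        out = self.curves[muscle](self._clamp(phi_e))
        return out if np.ndim(out) else float(out)

    def moment_arm(self, muscle: str, phi_e):
        out = -self.curves[muscle].deriv()(self._clamp(phi_e))
        return out if np.ndim(out) else float(out)

    def sample(self, phi_e) -> dict:
        """Evaluate every muscle at ``phi_e`` -> {name: MtuGeometrySample}."""
        phi = self._clamp(phi_e)
        return {
            m: MtuGeometrySample(lmt=c(phi), r=-c.deriv()(phi))
            for m, c in self.curves.items()
        }


def _lmt_from_moment_arm(r_poly: Polynomial, lmt_at_zero: float) -> Polynomial:
    # r = -dlmt/dphi  =>  lmt = lmt(0) - integral of r
    integ = r_poly.integ()
    return Polynomial([lmt_at_zero]) - (integ - integ(0.0))


def default_geometry() -> GeometryModel:
    """Editable default elbow geometry for one flexor and one extensor.

    Physiologically plausible cubic lmt tables for the biceps and triceps long
    heads: the biceps moment arm peaks near 4 cm at mid-flexion (positive,
    flexor); the triceps arm is about -2 to -2.5 cm (negative, extensor).
    These are plumbing defaults, meant to be replaced by subject-specific
    tables in the subject configuration.
    """
    mid = 0.5 * (GEOMETRY_DOMAIN[0] + GEOMETRY_DOMAIN[1])
    # symmetric parabolas r(phi) = r_peak - k (phi - mid)^2
    lin = Polynomial([-mid, 1.0])
    r_biceps = Polynomial([0.040]) - (0.020 / mid**2) * lin**2
    r_triceps = -(Polynomial([0.025]) - (0.005 / mid**2) * lin**2)
    return GeometryModel({
        "biceps": _lmt_from_moment_arm(r_biceps, 0.400),
        "triceps": _lmt_from_moment_arm(r_triceps, 0.250),
    })


def joint_torque(forces, arms) -> float:
    """Net joint torque tau_r = sum_j r_j F_j (flexion positive)."""
    forces = np.atleast_1d(np.asarray(forces, dtype=float))
    arms = np.atleast_1d(np.asarray(arms, dtype=float))
    if forces.shape != arms.shape:
        raise ValueError("forces and moment arms must have matching shapes")
    return float(np.sum(arms * forces))


@dataclass(frozen=True)
class TorqueSeries:
    """Uniformly sampled joint-torque series with a role tag."""

    t: np.ndarray
    tau: np.ndarray
    role: str = "reference"

    ROLES = ("reference", "interaction", "inverse_dynamics", "biological", "assist")

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        if t.shape != tau.shape or t.ndim != 1:
            raise ValueError("t and tau must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(tau))):
            raise ValueError("torque series must be finite")
        if t.size > 2:
            dt = np.diff(t)
            if np.ptp(dt) > 1e-6 * np.median(dt):
                raise ValueError("torque series must be uniformly sampled")
        if self.role not in self.ROLES:
            raise ValueError(f"role must be one of {self.ROLES}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "tau", tau)

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0]) if self.t.size > 1 else np.nan

    def mean(self) -> float:
        return float(np.mean(self.tau))


def resample_series(t: np.ndarray, x: np.ndarray, fs_new: float):
    """Linear resampling of a uniformly sampled series onto a new rate."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    t_new = np.arange(t[0], t[-1] + 0.5 / fs_new, 1.0 / fs_new)
    return t_new, np.interp(t_new, t, x)


def muscle_forces(
    env: EmgEnvelope,
    angle: np.ndarray,
    velocity: np.ndarray,
    muscles: Mapping[str, MuscleParams],
    curves: HillCurveParams,
    geometry: GeometryModel,
):
    """Per-sample muscle forces and moment arms for every modelled muscle.

    Returns ``(forces, arms)``: two dicts muscle -> ndarray over samples.
    The MTU velocity comes from the geometry chain rule,
    vmt = (d lmt / d phi_e) * d phi_e/dt = -r * omega.
    """
    angle = np.asarray(angle, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if angle.shape != velocity.shape or angle.shape[0] != env.n_samples:
        raise ValueError("envelope and kinematics must share length")
    forces, arms = {}, {}
    for name, p in muscles.items():
        u = env.channel(name)
        a = activation(u, p.activation)
        lmt = geometry.lmt(name, angle)
        r = geometry.moment_arm(name, angle)
        vmt = -r * velocity
        fs_state = fiber_state(lmt, vmt, p)
        f = hill_force(a, fs_state.lm, fs_state.vm, fs_state.phi, p, curves)
        f = np.where(fs_state.slack, 0.0, f)
        forces[name] = f
        arms[name] = np.broadcast_to(r, f.shape).astype(float)
    return forces, arms


def estimate_torque_series(
    env: EmgEnvelope,
    angle: np.ndarray,
    velocity: np.ndarray,
    muscles: Mapping[str, MuscleParams],
    curves: HillCurveParams | None = None,
    geometry: GeometryModel | None = None,
) -> TorqueSeries:
    """Estimated elbow torque tau_r(t) from EMG envelopes and kinematics.

    Per-sample composition activation -> fiber state -> Hill force -> torque;
    the map is memoryless given the envelope, so it is causal and suitable for
    streaming (one-sample latency).
    """
    curves = curves or HillCurveParams()
    geometry = geometry or default_geometry()
    forces, arms = muscle_forces(env, angle, velocity, muscles, curves, geometry)
    tau = np.zeros(env.n_samples)
    for name in forces:
        tau += arms[name] * forces[name]
    return TorqueSeries(t=env.time(), tau=tau, role="reference")
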