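"""Synthetic subjects and sessions with known ground truth.

Every downstream stage (envelope extraction, torque estimation, calibration,
closed-loop simulation, outcome metrics) is exercised on data generated here,
so the whole pipeline is testable without any recorded data. The generator
emulates the study conditions:

* a lifting task — five repetitions of a 20 cm lift driven by minimum-jerk
  elbow trajectories, load 2% of body weight (cohort mean 78.5 kg);
* an isometric task — five 40 s holds at 90 deg separated by 20 s rests with a
  3.0 kg wrist load and imposed ARV/median-frequency drift rates;
* the dynamic calibration trajectory (45 deg offset/amplitude sinusoids with a
  step-wise 0.05–0.5 Hz frequency schedule).

Muscle excitations are solved so the forward torque model reproduces the
planar inverse-dynamics demand: the flexor carries positive demand over a 5%
tonic antagonist co-activation, and the extensor absorbs negative residuals
symmetrically. Where the demand is representable the recorded ground-truth
torque equals the inverse-dynamics torque exactly; the generator always
records the *forward-model* torque as the reference, so a perfect calibration
has exactly zero error.

Two EMG carriers are available. ``"noise"`` (default) is band-limited
15–450 Hz Gaussian noise — realistic amplitude statistics, used wherever
envelope tracking matters. ``"chirp"`` is a periodic constant-amplitude
triangular frequency sweep over 40–240 Hz (the dominant sEMG energy band,
with headroom inside the 15–450 Hz analysis band-pass) plus a small noise
floor: its power spectrum is flat with an analytically known median frequency
and its rectified mean is essentially deterministic, so slow imposed trends
remain identifiable in short analysis windows; it is the default for fatigue
studies. Neither carrier models motor-unit physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy import signal as sp_signal

from .calibration import (
    CalibrationTrajectorySpec,
    calibration_kinematics,
    planar_inverse_dynamics,
)
from .myoprocessor import (
    GeometryModel,
    HillCurveParams,
    MuscleParams,
    TorqueSeries,
    activation,
    default_geometry,
    fiber_state,
    force_length,
    force_velocity,
    passive_force,
)
from .signal_processing import EmgRecording, MvcRecord, rectified_envelope
from .suit import AssistCondition, ControllerGains, PlantParams, SuitGeometry

JOINT_LIMITS = (0.0, np.radians(150.0))  # rad

#: tonic antagonist co-activation level
CO_ACTIVATION = 0.05

#: cohort mean body weight (kg) used for body-scaled loads
BODY_MASS = 78.5


def default_muscles() -> dict:
    """Ground-truth muscle parameters of the default synthetic subject."""
    return {
        "biceps": MuscleParams(f_max=625.0, l0=0.116, lst=0.270, phi0=0.0),
        "triceps": MuscleParams(f_max=800.0, l0=0.134, lst=0.143, phi0=0.21),
    }


@dataclass(frozen=True)
class SyntheticSubject:
    """Fully specified synthetic participant (all ground truth known)."""

    muscles: Mapping[str, MuscleParams] = field(default_factory=default_muscles)
    curves: HillCurveParams = field(default_factory=HillCurveParams)
    geometry: GeometryModel = field(default_factory=default_geometry)
    plant: PlantParams = field(default_factory=PlantParams)
    suit: SuitGeometry = field(default_factory=SuitGeometry)
    gains: ControllerGains = field(default_factory=ControllerGains)
    mvc: Mapping[str, float] = field(
        default_factory=lambda: {"biceps": 1.0, "triceps": 1.0})
    envelope_noise: float = 0.0
    body_mass: float = BODY_MASS
    forearm_length: float = 0.30
    seed: int = 0

    def mvc_record(self) -> MvcRecord:
        return MvcRecord(dict(self.mvc))


@dataclass(frozen=True)
class TaskSpec:
    """Task description for one synthetic session.

    lifting : ``reps`` repetitions lifting a load of ``load_fraction`` of body
    weight through ``lift_height`` metres (minimum-jerk flexion/extension).
    isometric : ``reps`` holds of ``hold_s`` seconds at ``hold_angle_deg`` with
    ``rest_s`` rests and a ``wrist_load_kg`` load; ``arv_rate``/``mnf_rate``
    impose fatigue drifts (% of initial per second, within +/-3).
    calibration : the dynamic calibration trajectory.
    """

    task: str = "lifting"
    condition: AssistCondition = field(
        default_factory=lambda: AssistCondition.from_label("NE"))
    reps: int = 5
    lift_height: float = 0.20
    load_fraction: float = 0.02
    move_s: float = 1.5
    hold_between_s: float = 1.0
    hold_angle_deg: float = 90.0
    hold_s: float = 40.0
    rest_s: float = 20.0
    wrist_load_kg: float = 3.0
    arv_rate: float = 0.0
    mnf_rate: float = 0.0
    fs_kin: float = 100.0
    fs_emg: float = 1000.0
    carrier: str = "auto"  # auto | noise | chirp
    trajectory: CalibrationTrajectorySpec = field(
        default_factory=CalibrationTrajectorySpec)

    def __post_init__(self):
        if self.task not in ("lifting", "isometric", "calibration"):
            raise ValueError("task must be lifting, isometric or calibration")
        if max(abs(self.arv_rate), abs(self.mnf_rate)) > 3.0:
            raise ValueError("imposed fatigue drift rates must be within ±3 %/s")
        for v in (self.reps, self.lift_height, self.move_s, self.hold_s):
            if not v > 0:
                raise ValueError("task parameters must be positive")

    def resolved_carrier(self) -> str:
        if self.carrier != "auto":
            return self.carrier
        return "chirp" if self.task == "isometric" else "noise"


class InfeasibleTorqueError(ValueError):
    """The demanded torque exceeds what the modelled muscles can produce."""


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------

def _noise_carrier(n: int, fs: float, rng, flatten: bool = True) -> np.ndarray:
    x = rng.standard_normal(n)
    sos = sp_signal.butter(4, (15.0, 450.0), "bandpass", fs=fs, output="sos")
    c = sp_signal.sosfiltfilt(sos, x)
    if flatten:
        # divide out the carrier's own slow amplitude fluctuation so the
        # rectified-and-smoothed envelope is steady; without this the 4 Hz
        # envelope ripple of raw band noise (~7% of the mean) dominates the
        # tracking error budget
        env = rectified_envelope(c, fs, mode="zero_phase")[:, 0]
        c = c / np.maximum(env, 0.1 * np.mean(env))
    return c


#: full period of the triangular frequency sweep (s); 0.75 s means a 3 s
#: analysis epoch holds exactly four up-down sweeps
_CHIRP_PERIOD = 0.75
#: sweep band (Hz): inside the physiological sEMG energy band, with headroom
#: below the 450 Hz analysis edge so imposed spectral drifts up to ~±50%
#: remain inside the 15-450 Hz analysis band-pass
_CHIRP_BAND = (40.0, 240.0)


def _chirp_carrier(n: int, fs: float, rng) -> np.ndarray:
    # constant-amplitude triangular sweep across the band: the instantaneous
    # frequency spends equal time per hertz, so the power spectrum is flat,
    # and the triangle keeps the phase continuous at the turning points
    f0, f1 = _CHIRP_BAND
    t = np.arange(n) / fs
    half = _CHIRP_PERIOD / 2.0
    tau = np.mod(t, _CHIRP_PERIOD)
    up = tau < half
    rate = (f1 - f0) / half
    # integrated instantaneous frequency within one period
    phase_local = np.where(
        up,
        f0 * tau + 0.5 * rate * tau**2,
        (f0 + f1) * half / 2.0
        + f1 * (tau - half) - 0.5 * rate * (tau - half) ** 2,
    )
    per_period = (f0 + f1) * half  # integral of f over one full period
    cycles = np.floor(t / _CHIRP_PERIOD)
    x = np.sin(2 * np.pi * (phase_local + cycles * per_period)
               + rng.uniform(0, 2 * np.pi))
    return x + 0.05 * _noise_carrier(n, fs, rng)


def synth_emg(
    profile: np.ndarray,
    fs: float,
    seed: int,
    carrier: str = "noise",
    scale: float = 1.0,
) -> np.ndarray:
    """Amplitude-modulated band-limited carrier tracking an envelope profile.

    The carrier is normalised by its own steady-state envelope (extracted with
    the standard 35 Hz/4 Hz chain) so that the envelope pipeline recovers
    ``profile * scale`` within a few percent in steady state. Deterministic
    given ``seed``.
    """
    profile = np.asarray(profile, dtype=float)
    if np.any(profile < 0) or np.any(profile > 1):
        raise ValueError("activation profile must lie in [0, 1]")
    if fs < 1000:
        raise ValueError("fs must be >= 1000 Hz (the study's DAQ rate)")
    rng = np.random.default_rng(seed)
    n = profile.size
    make = _noise_carrier if carrier == "noise" else _chirp_carrier
    if carrier not in ("noise", "chirp"):
        raise ValueError("carrier must be 'noise' or 'chirp'")
    c = make(n, fs, rng)
    env = rectified_envelope(c, fs, mode="zero_phase")[:, 0]
    margin = int(0.5 * fs)
    interior = env[margin:-margin] if n > 3 * margin else env
    g = float(np.mean(interior))
    return scale * profile * c / g


def synth_fatigue_drift(
    rec: EmgRecording, arv_rate: float, mnf_rate: float
) -> EmgRecording:
    """Impose linear amplitude and spectral-compression trends on a recording.

    The amplitude ramps at ``arv_rate`` (% of the initial value per second,
    measured from the recording start) and the whole spectrum is scaled in
    time-varying fashion at ``mnf_rate`` %/s by resampling along a warped time
    axis (playing the carrier faster shifts its band, and its median, up by
    the same factor). Rates must be within +/-3 %/s.
    """
    if max(abs(arv_rate), abs(mnf_rate)) > 3.0:
        raise ValueError("drift rates must be within ±3 %/s")
    t = np.arange(rec.n_samples) / rec.fs
    s_end = 1.0 + mnf_rate / 100.0 * t[-1] if rec.n_samples else 1.0
    if s_end <= 0.05:
        raise ValueError("mnf_rate drives the spectral scale to zero over "
                         "this recording length")
    # warped time: tau(t) = t + (mnf_rate/200) t^2, so dtau/dt = 1 + r t/100
    tau = t + (mnf_rate / 200.0) * t**2
    # reflect-extend the base so the warped axis stays inside the data
    x = rec.samples
    if tau[-1] > t[-1] + 1e-12:
        extra = int(np.ceil((tau[-1] - t[-1]) * rec.fs)) + 2
        x = np.vstack([x, x[-2:-2 - extra:-1, :]])
    # resample on a 4x-oversampled grid with cubic interpolation: plain
    # linear interpolation at the native rate attenuates the top of the band
    # and biases the amplitude trend
    from scipy.interpolate import CubicSpline

    up = 4
    fine = sp_signal.resample_poly(x, up, 1, axis=0)
    spl = CubicSpline(np.arange(fine.shape[0]) / (rec.fs * up), fine, axis=0)
    warped = spl(tau)
    ramp = (1.0 + arv_rate / 100.0 * t)[:, None]
    return EmgRecording(warped * ramp, fs=rec.fs, channels=rec.channels,
                        t0=rec.t0)


# ---------------------------------------------------------------------------
# task kinematics
# ---------------------------------------------------------------------------

def _minjerk_segment(theta0, theta1, T, fs):
    n = int(round(T * fs))
    s = np.arange(n) / (T * fs)
    pos = 10 * s**3 - 15 * s**4 + 6 * s**5
    vel = (30 * s**2 - 60 * s**3 + 30 * s**4) / T
    acc = (60 * s - 180 * s**2 + 120 * s**3) / T**2
    d = theta1 - theta0
    return theta0 + d * pos, d * vel, d * acc


def _hold(theta, T, fs):
    n = int(round(T * fs))
    return np.full(n, theta), np.zeros(n), np.zeros(n)


def lifting_kinematics(task: TaskSpec, forearm_length: float, fs: float):
    """Minimum-jerk flexion/extension repetitions for the lifting task.

    The target elbow angle raises the hand by ``lift_height`` with the upper
    arm vertical: height gain = L_f (1 - cos phi_e).
    """
    c = 1.0 - task.lift_height / forearm_length
    if not -1.0 < c < 1.0:
        raise ValueError("lift height unreachable with this forearm length")
    target = float(np.arccos(c))
    if target > JOINT_LIMITS[1]:
        raise ValueError("lift target exceeds the elbow joint range")
    parts = [_hold(0.0, 2.0, fs)]
    for _ in range(task.reps):
        parts.append(_minjerk_segment(0.0, target, task.move_s, fs))
        parts.append(_hold(target, task.hold_between_s, fs))
        parts.append(_minjerk_segment(target, 0.0, task.move_s, fs))
        parts.append(_hold(0.0, task.hold_between_s, fs))
    theta = np.concatenate([p[0] for p in parts])
    omega = np.concatenate([p[1] for p in parts])
    alpha = np.concatenate([p[2] for p in parts])
    return theta, omega, alpha


def isometric_kinematics(task: TaskSpec, fs: float):
    """Ramp–hold–ramp–rest repetitions for the isometric task."""
    hold = np.radians(task.hold_angle_deg)
    parts = []
    for _ in range(task.reps):
        parts.append(_minjerk_segment(0.0, hold, 2.0, fs))
        parts.append(_hold(hold, task.hold_s, fs))
        parts.append(_minjerk_segment(hold, 0.0, 2.0, fs))
        parts.append(_hold(0.0, task.rest_s, fs))
    theta = np.concatenate([p[0] for p in parts])
    omega = np.concatenate([p[1] for p in parts])
    alpha = np.concatenate([p[2] for p in parts])
    return theta, omega, alpha


def hold_windows(task: TaskSpec):
    """(start, end) times in seconds of each isometric hold plateau."""
    out = []
    t = 0.0
    for _ in range(task.reps):
        t += 2.0
        out.append((t, t + task.hold_s))
        t += task.hold_s + 2.0 + task.rest_s
    return out


# ---------------------------------------------------------------------------
# activation inversion and session assembly
# ---------------------------------------------------------------------------

def solve_activations(
    tau_demand: np.ndarray,
    angle: np.ndarray,
    velocity: np.ndarray,
    muscles: Mapping[str, MuscleParams],
    curves: HillCurveParams,
    geometry: GeometryModel,
    flexor: str = "biceps",
    extensor: str = "triceps",
    co_activation: float = CO_ACTIVATION,
):
    """Per-sample activations reproducing a torque demand exactly.

    The tendon-line force is linear in the activation at fixed kinematics, so
    the agonist activation follows in closed form: the flexor absorbs positive
    residual demand over the tonic co-activation baseline, the extensor
    negative residual. Raises :class:`InfeasibleTorqueError` when a demand
    would need an activation above 1, naming the violating instant.
    """
    coeffs = {}
    passives = {}
    for name in (flexor, extensor):
        p = muscles[name]
        lmt = geometry.lmt(name, angle)
        r = geometry.moment_arm(name, angle)
        st = fiber_state(lmt, -r * velocity, p)
        l_norm = st.lm / p.l0
        v_norm = st.vm / (curves.v_max * p.l0)
        act = (p.f_max * force_length(l_norm, curves)
               * force_velocity(v_norm, curves) * np.cos(st.phi))
        pas = p.f_max * passive_force(l_norm, curves) * np.cos(st.phi)
        act = np.where(st.slack, 0.0, act)
        pas = np.where(st.slack, 0.0, pas)
        coeffs[name] = r * act   # torque per unit activation
        passives[name] = r * pas
    resid = (tau_demand - passives[flexor] - passives[extensor]
             - co_activation * (coeffs[flexor] + coeffs[extensor]))
    with np.errstate(divide="ignore", invalid="ignore"):
        a_flex = co_activation + np.where(
            resid > 0, resid / coeffs[flexor], 0.0)
        a_ext = co_activation + np.where(
            resid < 0, resid / coeffs[extensor], 0.0)
    for name, a in ((flexor, a_flex), (extensor, a_ext)):
        bad = ~np.isfinite(a) | (a > 1.0)
        if np.any(bad):
            raise InfeasibleTorqueError(
                f"demanded torque infeasible for {name} at sample "
                f"{int(np.flatnonzero(bad)[0])}"
            )
    return {flexor: np.clip(a_flex, 0.0, 1.0),
            extensor: np.clip(a_ext, 0.0, 1.0)}


def _inverse_activation(a: np.ndarray, shape: float) -> np.ndarray:
    if shape == 0.0:
        return a
    return np.log1p(a * np.expm1(shape)) / shape


@dataclass
class Session:
    """One generated session bundle with full ground truth."""

    task: TaskSpec
    subject: SyntheticSubject
    fs_kin: float
    fs_emg: float
    angle: np.ndarray        # rad, at fs_kin
    velocity: np.ndarray     # rad/s
    accel: np.ndarray        # rad/s^2
    tau_id: TorqueSeries     # inverse-dynamics torque
    tau_truth: TorqueSeries  # forward-model torque of the true activations
    emg: EmgRecording        # raw synthetic EMG at fs_emg
    mvc: MvcRecord
    activations: dict        # muscle -> ndarray at fs_kin
    profiles: dict           # muscle -> envelope profile (fraction of MVC)
    truth: dict              # everything else worth asserting against

    def time_kin(self) -> np.ndarray:
        return np.arange(self.angle.size) / self.fs_kin

    def write(self, directory):
        from . import io as mio

        mio.write_session(self, directory)


def synth_session(subject: SyntheticSubject, task: TaskSpec,
                  envelope_noise: float | None = None) -> Session:
    """Generate a complete synthetic session for one subject and task."""
    fs_k, fs_e = task.fs_kin, task.fs_emg
    if task.task == "lifting":
        theta, omega, alpha = lifting_kinematics(task, subject.forearm_length, fs_k)
        load = task.load_fraction * subject.body_mass
    elif task.task == "isometric":
        theta, omega, alpha = isometric_kinematics(task, fs_k)
        load = task.wrist_load_kg
    else:
        _, theta, omega, alpha = calibration_kinematics(task.trajectory, fs_k)
        load = 0.0
    if np.any(theta < JOINT_LIMITS[0] - 1e-9) or np.any(theta > JOINT_LIMITS[1] + 1e-9):
        raise ValueError("generated kinematics violate the joint limits")

    plant = PlantParams(
        inertia=subject.plant.inertia, m_r_com=subject.plant.m_r_com,
        load_mass=load, load_lever=subject.plant.load_lever,
        damping=subject.plant.damping, g=subject.plant.g,
    )
    tau_id = planar_inverse_dynamics(theta, omega, plant, accel=alpha, fs=fs_k)
    acts = solve_activations(tau_id.tau, theta, omega, subject.muscles,
                             subject.curves, subject.geometry)

    noise = subject.envelope_noise if envelope_noise is None else envelope_noise
    rng = np.random.default_rng(np.random.SeedSequence([subject.seed, 7]))
    profiles = {}
    for name, a in acts.items():
        u = _inverse_activation(a, subject.muscles[name].activation.shape)
        if noise > 0:
            lp = sp_signal.butter(2, 1.0, "lowpass", fs=fs_k, output="sos")
            pert = sp_signal.sosfiltfilt(lp, rng.standard_normal(u.size))
            pert /= max(np.std(pert), 1e-12)
            u = np.clip(u * (1.0 + noise * pert), 0.0, 1.0)
        profiles[name] = u

    # forward torque of the (possibly noise-perturbed) true excitations;
    # noiseless generation reproduces tau_id exactly wherever feasible
    from .myoprocessor import estimate_torque_series
    from .signal_processing import EmgEnvelope

    env_true = EmgEnvelope(
        np.column_stack([profiles[m] for m in subject.muscles]),
        fs=fs_k, channels=tuple(subject.muscles))
    tau_truth = estimate_torque_series(env_true, theta, omega, subject.muscles,
                                       subject.curves, subject.geometry)

    # EMG synthesis at the DAQ rate
    t_kin = np.arange(theta.size) / fs_k
    n_e = int(round(theta.size * fs_e / fs_k))
    t_emg = np.arange(n_e) / fs_e
    seeds = np.random.SeedSequence([subject.seed, 11]).generate_state(
        len(subject.muscles))
    carrier = task.resolved_carrier()
    chans = []
    for (name, u), s in zip(profiles.items(), seeds):
        u_e = np.interp(t_emg, t_kin, u)
        chans.append(synth_emg(u_e, fs_e, int(s % 2**31), carrier=carrier,
                               scale=subject.mvc[name]))
    emg = EmgRecording(np.column_stack(chans), fs=fs_e,
                       channels=tuple(profiles))

    drift_applied = []
    if task.task == "isometric" and (task.arv_rate or task.mnf_rate):
        x = emg.samples.copy()
        for (t0, t1) in hold_windows(task):
            i0, i1 = int(round(t0 * fs_e)), int(round(t1 * fs_e))
            sub = EmgRecording(x[i0:i1], fs=fs_e, channels=emg.channels)
            x[i0:i1] = synth_fatigue_drift(sub, task.arv_rate,
                                           task.mnf_rate).samples
            drift_applied.append((t0, t1))
        emg = EmgRecording(x, fs=fs_e, channels=emg.channels)

    truth = {
        "seed": subject.seed,
        "task": task.task,
        "condition": task.condition.label,
        "assist_gain": task.condition.gain,
        "load_kg": load,
        "carrier": carrier,
        "envelope_noise": noise,
        "arv_rate": task.arv_rate,
        "mnf_rate": task.mnf_rate,
        "drift_windows_s": drift_applied,
        "muscles": {m: asdict(p) for m, p in subject.muscles.items()},
    }
    return Session(task=task, subject=subject, fs_kin=fs_k, fs_emg=fs_e,
                   angle=theta, velocity=omega, accel=alpha, tau_id=tau_id,
                   tau_truth=tau_truth, emg=emg, mvc=subject.mvc_record(),
                   activations=acts, profiles=profiles, truth=truth)
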