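"""File-format plumbing: delimited time-series, subject YAML, run manifests.

Conventions: time series are CSV with a first column ``time_s`` and one column
per channel, with units named in the header; a YAML sidecar carries the
sampling rate and units. Angles are stored in degrees (the study's reporting
convention) and converted to radians at load; torques are N m; envelopes are
fractions of MVC internally and %MVC in reports.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .myoprocessor import (
    ActivationParams,
    GeometryModel,
    HillCurveParams,
    MuscleParams,
)
from .signal_processing import EmgRecording, MvcRecord
from .suit import ControllerGains, PlantParams, SuitGeometry

__version__ = "0.1.0"


def write_timeseries(path, t: np.ndarray, columns: dict, meta: dict | None = None):
    """Write a time series CSV (+ optional YAML sidecar with fs/units)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": np.asarray(t, dtype=float)})
    for name, values in columns.items():
        df[name] = np.asarray(values, dtype=float)
    df.to_csv(path, index=False)
    if meta is not None:
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_timeseries(path):
    """Read a time series CSV -> (t, DataFrame of channels, sidecar dict)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path} has no 'time_s' column")
    t = df.pop("time_s").to_numpy()
    sidecar = {}
    side = path.with_suffix(".yaml")
    if side.exists():
        sidecar = yaml.safe_load(side.read_text()) or {}
    return t, df, sidecar


def read_emg(path) -> EmgRecording:
    t, df, meta = read_timeseries(path)
    fs = float(meta.get("fs_hz") or round(1.0 / np.median(np.diff(t))))
    return EmgRecording(df.to_numpy(), fs=fs, channels=tuple(df.columns),
                        t0=float(t[0]))


# ---------------------------------------------------------------------------
# subject configuration
# ---------------------------------------------------------------------------

_SUBJECT_KEYS = {"muscles", "hill_curves", "suit_geometry", "controller_gains",
                 "plant", "mvc", "geometry", "seed"}


@dataclass
class SubjectConfig:
    """Typed view of the subject YAML."""

    muscles: dict
    curves: HillCurveParams
    suit: SuitGeometry
    gains: ControllerGains
    plant: PlantParams
    mvc: MvcRecord
    geometry: GeometryModel | None = None
    seed: int = 0


def subject_to_dict(cfg: SubjectConfig) -> dict:
    d = {
        "muscles": {
            name: {
                "f_max_N": float(p.f_max), "l0_m": float(p.l0),
                "lst_m": float(p.lst), "phi0_rad": float(p.phi0),
                "activation_shape": float(p.activation.shape),
            } for name, p in cfg.muscles.items()
        },
        "hill_curves": {k: float(v) for k, v in asdict(cfg.curves).items()},
        "suit_geometry": {"a_m": float(cfg.suit.a), "b_m": float(cfg.suit.b)},
        "controller_gains": {k: float(v) for k, v in asdict(cfg.gains).items()},
        "plant": {k: float(v) for k, v in asdict(cfg.plant).items()},
        "mvc": {k: float(v) for k, v in cfg.mvc.values.items()},
        "seed": int(cfg.seed),
    }
    if cfg.geometry is not None:
        d["geometry"] = {
            m: list(map(float, poly.convert().coef))
            for m, poly in cfg.geometry.curves.items()
        }
    return d


def subject_from_dict(d: dict) -> SubjectConfig:
    unknown = set(d) - _SUBJECT_KEYS
    if unknown:
        raise ValueError(f"unknown subject config keys: {sorted(unknown)}")
    muscles = {
        name: MuscleParams(
            f_max=m["f_max_N"], l0=m["l0_m"], lst=m["lst_m"],
            phi0=m.get("phi0_rad", 0.0),
            activation=ActivationParams(m.get("activation_shape", -2.0)),
        ) for name, m in d["muscles"].items()
    }
    geometry = None
    if "geometry" in d:
        from numpy.polynomial import Polynomial

        geometry = GeometryModel(
            {m: Polynomial(c) for m, c in d["geometry"].items()})
    return SubjectConfig(
        muscles=muscles,
        curves=HillCurveParams(**d.get("hill_curves", {})),
        suit=SuitGeometry(a=d["suit_geometry"]["a_m"], b=d["suit_geometry"]["b_m"]),
        gains=ControllerGains(**d.get("controller_gains", {})),
        plant=PlantParams(**d.get("plant", {})),
        mvc=MvcRecord(d["mvc"]),
        geometry=geometry,
        seed=int(d.get("seed", 0)),
    )


def save_subject(path, cfg: SubjectConfig):
    Path(path).write_text(yaml.safe_dump(subject_to_dict(cfg), sort_keys=False))


def load_subject(path) -> SubjectConfig:
    return subject_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# session bundles and manifests
# ---------------------------------------------------------------------------

def write_session(session, directory):
    """Write a generated session as CSVs + ground-truth YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t_kin = session.time_kin()
    write_timeseries(
        directory / "kinematics.csv", t_kin,
        {
            "elbow_angle_deg": np.degrees(session.angle),
            "elbow_velocity_deg_s": np.degrees(session.velocity),
            "elbow_accel_deg_s2": np.degrees(session.accel),
        },
        meta={"fs_hz": session.fs_kin,
              "units": {"elbow_angle_deg": "deg",
                        "elbow_velocity_deg_s": "deg/s",
                        "elbow_accel_deg_s2": "deg/s^2"}},
    )
    write_timeseries(
        directory / "emg.csv", session.emg.time(),
        {ch: session.emg.channel(ch) for ch in session.emg.channels},
        meta={"fs_hz": session.fs_emg, "units": "V"},
    )
    write_timeseries(
        directory / "torque_reference.csv", session.tau_id.t,
        {"tau_inverse_dynamics_Nm": session.tau_id.tau,
         "tau_model_truth_Nm": session.tau_truth.tau},
        meta={"fs_hz": session.fs_kin, "units": "N m"},
    )
    cfg = SubjectConfig(
        muscles=dict(session.subject.muscles), curves=session.subject.curves,
        suit=session.subject.suit, gains=session.subject.gains,
        plant=session.subject.plant, mvc=session.mvc,
        geometry=session.subject.geometry, seed=session.subject.seed,
    )
    save_subject(directory / "subject.yaml", cfg)
    truth = dict(session.truth)
    (directory / "ground_truth.yaml").write_text(
        yaml.safe_dump(_plain(truth), sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    seed: int | None
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: list = field(default_factory=list)
    version: str = __version__
    timestamp: float = field(default_factory=time.time)

    def write(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def manifest_for(command: str, seed, input_paths, outputs) -> RunManifest:
    inputs = {str(p): sha256_file(p) for p in input_paths if Path(p).exists()}
    return RunManifest(command=command, seed=seed, inputs=inputs,
                       outputs=[str(o) for o in outputs])
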