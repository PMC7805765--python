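import warnings

import numpy as np
import pytest

from myoexo.synth import SyntheticSubject, TaskSpec, synth_session


@pytest.fixture(autouse=True)
def _quiet_domain_warnings():
    # domain-clamp and slack warnings are expected in closed-loop sweeps
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def subject():
    return SyntheticSubject(seed=1)


@pytest.fixture(scope="session")
def calibration_session(subject):
    return synth_session(subject, TaskSpec(task="calibration"))


@pytest.fixture(scope="session")
def lifting_session(subject):
    return synth_session(subject, TaskSpec(task="lifting"))


@pytest.fixture(scope="session")
def isometric_session(subject):
    return synth_session(subject, TaskSpec(task="isometric", reps=1))


def kinematic_envelope(session):
    """Ground-truth envelope (the generator's excitation profiles) at fs_kin."""
    from myoexo.signal_processing import EmgEnvelope

    cols = np.column_stack([session.profiles[m] for m in session.subject.muscles])
    return EmgEnvelope(cols, fs=session.fs_kin,
                       channels=tuple(session.subject.muscles))


def emg_envelope(session, mode="zero_phase"):
    """EMG-derived envelope resampled onto the kinematic rate."""
    from myoexo.signal_processing import EmgEnvelope, envelope_pipeline

    env = envelope_pipeline(session.emg, session.mvc, mode=mode)
    t_e = env.time()
    t_k = session.time_kin()
    vals = np.column_stack([
        np.interp(t_k, t_e, env.values[:, i]) for i in range(len(env.channels))
    ])
    return EmgEnvelope(vals, fs=session.fs_kin, channels=env.channels)
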