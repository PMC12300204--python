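import numpy as np
import pytest

import gazeid as gz
from gazeid.pipeline import build_sample_set

COHORT_SEED = 1
N_SUBJECTS = 8
N_SESSIONS = 3
N_POSITIONS = 20


@pytest.fixture(scope="session")
def schedule():
    return gz.generate_schedule(count=N_POSITIONS, dwell_ms=1000, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_recordings(schedule):
    """8 well-separated subjects x 3 sessions on a common 20-position schedule."""
    profiles = gz.make_cohort(N_SUBJECTS, seed=COHORT_SEED)
    return gz.simulate_dataset(profiles, N_SESSIONS, schedule, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_samples(cohort_recordings, schedule):
    return build_sample_set(cohort_recordings, schedule, N_POSITIONS)


@pytest.fixture(scope="session")
def cohort_design():
    return gz.ExperimentDesign(S=N_SESSIONS, U=N_SUBJECTS, X=N_POSITIONS)


@pytest.fixture
def quiet_profile():
    """Deterministic oculomotor profile: no noise, no drift, fixed latency."""
    return gz.SubjectProfile(
        latency_mean=170.0,
        latency_sd=0.0,
        fixation_noise_sd=0.0,
        drift_rate=0.0,
        undershoot_frac=0.0,
    )


@pytest.fixture
def tiny_recording():
    n = 3000
    rng = np.random.default_rng(0)
    return gz.GazeRecording(
        timestamps=np.arange(n, dtype=float),
        gaze_x=rng.normal(0, 1, n),
        gaze_y=rng.normal(0, 1, n),
        valid=np.ones(n, dtype=bool),
        target_x=np.zeros(n),
        target_y=np.zeros(n),
        subject_id="S00",
        session_id="R00",
    )
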