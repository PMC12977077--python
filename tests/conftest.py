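import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import aperturepass as ap

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def real_truth():
    return ap.preset("real_env")


@pytest.fixture(scope="session")
def combined_truth():
    return ap.preset("combined")


@pytest.fixture(scope="session")
def reference_participant():
    """A noise-free 40/34 cm participant rotating to the left."""
    return ap.ParticipantProfile(
        participant_id="ref",
        shoulder_width_cm=40.0,
        hip_width_cm=34.0,
        random_intercept=0.0,
        max_rotation_deg=85.0,
        rotation_side=+1,
    )


@pytest.fixture(scope="session")
def small_exp1(real_truth):
    """Three real-environment participants, full design, default noise."""
    return ap.simulate_experiment("exp1", real_truth, 3, seed=11)


def make_sequence_outcomes(alphas_deg, task_id="task1", gseq=1):
    """Hand-built single-sequence outcome rows for trajectory synthesis."""
    n = len(alphas_deg)
    return pd.DataFrame(
        {
            "participant_id": ["ref"] * n,
            "task_id": [task_id] * n,
            "sequence_index_global": [gseq] * n,
            "trial_index_in_sequence": np.arange(1, n + 1),
            "true_alpha_deg": np.asarray(alphas_deg, dtype=float),
        }
    )


@pytest.fixture(scope="session")
def ramp_trajectory(reference_participant):
    """Nine passes with peak yaw 0, 10, ..., 80 degrees."""
    outcomes = make_sequence_outcomes(np.arange(9) * 10.0)
    traj = ap.synthesize_marker_trajectory(reference_participant, outcomes)
    return traj, outcomes
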