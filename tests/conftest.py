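"""Shared fixtures: small simulated studies reused across test modules."""

import numpy as np
import pytest

from swaygrade.pipeline import simulate_angle_store
from swaygrade.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_store():
    """10-participant, 2-sensor study processed through sway + EKF once."""
    config = CohortConfig(n_participants=10, n_exercises=3,
                          reps_per_exercise=2,
                          placements=("lumbar", "left_thigh"))
    return simulate_angle_store(config, seed=0)


@pytest.fixture(scope="session")
def cohort47():
    return generate_cohort(47, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
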