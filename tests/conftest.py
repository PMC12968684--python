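import numpy as np
import pytest

from rtseiz import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for unit/pipeline tests: 2 normal + 2 CAE, 2 min each."""
    spec = SyntheticSpec(
        n_patients={"normal": 2, "CAE": 2},
        recording_minutes=2.0,
        events_per_patient={"CAE": 2},
        seed=5,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """The desk-scale study cohort used by the learnability checks:
    8 normal / 6 CAE / 3 GN / 3 FC patients, 10 minutes each, with
    per-type event rates and durations mirroring the clinical table."""
    spec = SyntheticSpec(
        n_patients={"normal": 8, "CAE": 6, "GN": 3, "FC": 3},
        recording_minutes=10.0,
        events_per_patient={"CAE": 6, "GN": 5, "FC": 2},
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
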