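import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avbrisk import CohortSpec, PatientSnapshot
from avbrisk.cohort import cohort_to_frame, generate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_snapshot(**overrides) -> PatientSnapshot:
    """A clinically unremarkable admission; override what the test needs."""
    base = dict(
        patient_id="T0001",
        age=55.0,
        sex="male",
        bilirubin=1.0,
        albumin=4.0,
        inr=1.1,
        creatinine=0.8,
        sodium=140.0,
        potassium=4.2,
        wbc=7.0,
        hemoglobin=10.0,
        mean_arterial_pressure=80.0,
        he_grade=0,
        ascites_grade=0,
        spo2_fio2=460.0,
    )
    base.update(overrides)
    return PatientSnapshot(**base)


@pytest.fixture(scope="session")
def default_cohort_10k():
    """Study-calibrated cohort at n=10,000; shared across statistical tests."""
    spec = CohortSpec(n=10_000, seed=20230512)
    snapshots, records = generate_cohort(spec)
    return spec, snapshots, records


@pytest.fixture(scope="session")
def default_frame_10k(default_cohort_10k):
    spec, snapshots, records = default_cohort_10k
    return spec, cohort_to_frame(snapshots, records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
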