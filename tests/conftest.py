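import itertools

import pytest
from hypothesis import HealthCheck, settings

from mimicscale.cohort import Cohort, PatientRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

_counter = itertools.count(1)

_DEFAULTS = dict(
    age=66,
    sex="male",
    sbp=160,
    dbp=90,
    nihss=9,
    facial_droop=False,
    isolated_sensory_deficit=False,
    atrial_fibrillation=False,
    hypertension=False,
    hyperlipidemia=False,
    diabetes=False,
    migraine=False,
    seizure_history=False,
    psychiatric_history=False,
    label="stroke",
)


@pytest.fixture
def make_record():
    """Factory producing valid PatientRecords with overridable fields."""

    def _make(**overrides) -> PatientRecord:
        kwargs = {**_DEFAULTS, **overrides}
        kwargs.setdefault("patient_id", f"T{next(_counter):06d}")
        return PatientRecord(**kwargs)

    return _make


@pytest.fixture
def small_cohort(make_record) -> Cohort:
    """Ten-record mixed cohort exercising every field."""
    records = [
        make_record(age=45, sex="female", migraine=True, label="mimic", nihss=4),
        make_record(age=80, atrial_fibrillation=True, hypertension=True, nihss=20),
        make_record(age=30, seizure_history=True, label="mimic", sbp=120),
        make_record(age=55, hyperlipidemia=True, diabetes=True, label="tia", nihss=2),
        make_record(age=70, facial_droop=True, nihss=15),
        make_record(age=62, psychiatric_history=True, label="mimic", dbp=70),
        make_record(age=49, isolated_sensory_deficit=True, sbp=145),
        make_record(age=91, hypertension=True, nihss=32),
        make_record(age=38, sex="female", sbp=139, nihss=1, label="tia"),
        make_record(age=66),
    ]
    return Cohort(records=records)
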