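import numpy as np
import pytest

from cardiofuzz import CohortTable, PatientRecord, build_default_model
from cardiofuzz.anfis import with_coefficients


@pytest.fixture
def default_model():
    return build_default_model()


@pytest.fixture
def reference_model():
    """A fixed random-consequent model whose outputs stay inside [0, 0.9]."""
    rng = np.random.default_rng(7)
    return with_coefficients(
        build_default_model(output_name="ef"), rng.uniform(0.1, 0.3, size=(27, 3))
    )


@pytest.fixture
def small_cohort():
    """Hand-written six-record cohort spanning the published variable ranges."""
    records = [
        PatientRecord(ntprobnp=10.0, na=123.0, k=2.4, ef=12.0, epi_cysc=14.0),
        PatientRecord(ntprobnp=5000.0, na=150.0, k=7.8, ef=75.0, epi_cysc=146.0),
        PatientRecord(ntprobnp=100.0, na=135.0, k=3.5, ef=55.0, epi_cysc=90.0),
        PatientRecord(ntprobnp=300.0, na=140.0, k=4.5, ef=60.0, epi_cysc=100.0),
        PatientRecord(ntprobnp=1500.0, na=130.0, k=5.5, ef=35.0, epi_cysc=40.0),
        PatientRecord(ntprobnp=2500.0, na=145.0, k=6.0, ef=25.0, epi_cysc=25.0),
    ]
    return CohortTable.from_records(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
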