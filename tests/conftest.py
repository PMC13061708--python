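import datetime

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import auxokit as ak

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pah_table():
    return ak.PAHCoefficientTable.load_default()


@pytest.fixture(scope="session")
def cfg():
    return ak.ClassificationConfig()


@pytest.fixture
def male_profile():
    return ak.AthleteProfile(
        athlete_id="m1",
        sex=ak.Sex.MALE,
        birth_date=datetime.date(2011, 6, 1),
        mother_height_cm=165.0,
        father_height_cm=179.0,
    )


@pytest.fixture
def male_session():
    # decimal age at 2024-06-01 is 13.0023 yr
    return ak.MeasurementSession(
        date=datetime.date(2024, 6, 1),
        standing_height_cm=160.0,
        sitting_height_cm=82.0,
        weight_kg=48.0,
        source=ak.Source.EXPERT,
    )


@pytest.fixture(scope="session")
def zero_noise_cohort():
    err = ak.ErrorModel(
        expert_sd_cm=0.0, app_sd_cm=0.0, app_bias_cm=0.0, weight_sd_kg=0.0, seed=42
    )
    return ak.generate_cohort(err=err)


@pytest.fixture(scope="session")
def noisy_cohort():
    return ak.generate_cohort(err=ak.ErrorModel(seed=7))


def make_fixture_table(b0=10.0, b1=0.9, b2=0.1, b3=0.1):
    """Single-row-per-sex coefficient table for contract tests."""
    rows = [
        {"sex": sex, "age_yr": age, "b0": b0, "b1": b1, "b2": b2, "b3": b3}
        for sex in ("male", "female")
        for age in [a / 2 for a in range(8, 36)]
    ]
    return ak.PAHCoefficientTable(pd.DataFrame(rows))
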