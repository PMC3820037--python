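import numpy as np
import pandas as pd
import pytest

from frailcast.cohort import derive_features
from frailcast.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_df() -> pd.DataFrame:
    """Small synthetic cohort with derived features; shared across tests."""
    return generate_cohort(SyntheticConfig(n=3000, seed=20240901))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


@pytest.fixture()
def minimal_record() -> dict:
    """One fully observed participant at reference levels."""
    return dict(
        id="P1", age=50.0, sex="male", family_history_diabetes=False,
        height=175.0, weight_baseline=70.0, weight_prev=70.0, weight_followup=70.0,
        bmi=22.9, waist=85.0, sbp=115.0, dbp=70.0, antihypertensive_rx=False,
        corticosteroid_rx=False, history_high_glucose=False, smoking="non",
        physical_activity_4h=True, daily_fruit_veg=True, fasting_glucose=5.0,
        postload_2h_glucose=5.5, hdl=55.0, triglycerides=80.0,
        physician_dx_diabetes=False, diabetes_medication=False,
        prevalent_diabetes=False, incident_diabetes=False,
    )


@pytest.fixture()
def minimal_frame(minimal_record) -> pd.DataFrame:
    return derive_features(pd.DataFrame([minimal_record]))
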