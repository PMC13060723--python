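import datetime as dt

import pandas as pd
import pytest

from panctriage.cohort import CohortConfig, EventTimeline
from panctriage.features import FeatureConfig
from panctriage.symptoms import SymptomEvent, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture()
def feature_config():
    return FeatureConfig()


@pytest.fixture()
def cohort_config():
    return CohortConfig()


def make_timeline(
    patient_id="P1",
    sex="female",
    birth=dt.date(1950, 6, 15),
    events=(),
    diagnosis=None,
    bmi=None,
    seifa=None,
):
    """events: iterable of (date, code) pairs."""
    evs = sorted(
        (SymptomEvent(patient_id, d, c) for d, c in events),
        key=lambda e: (e.event_date, e.symptom_code),
    )
    dx = (diagnosis, "C25.9") if isinstance(diagnosis, dt.date) else diagnosis
    return EventTimeline(
        patient_id=patient_id,
        sex=sex,
        birth_date=birth,
        events=list(evs),
        bmi=bmi,
        seifa_percentile=seifa,
        cancer_diagnosis=dx,
    )


def pathology_df(rows):
    """rows: (patient_id, date, analyte, value, units)."""
    return pd.DataFrame(
        rows, columns=["patient_id", "result_date", "analyte", "value", "units"]
    )


def prescriptions_df(rows):
    """rows: (patient_id, date, medication_name)."""
    return pd.DataFrame(rows, columns=["patient_id", "script_date", "medication_name"])


def encounters_df(rows):
    """rows: (patient_id, date, reason_text)."""
    return pd.DataFrame(rows, columns=["patient_id", "encounter_date", "reason_text"])
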