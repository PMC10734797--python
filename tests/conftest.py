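import datetime as dt

import pytest

from pedss.catalog import CodeSystem, default_catalog
from pedss.engine import AssessmentWindow, ClaimEvent, Qualifier, Setting

INDEX = dt.date(2017, 6, 1)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def window():
    return AssessmentWindow(INDEX)


def ev(
    code,
    system=CodeSystem.ICD10GM,
    setting=Setting.INPATIENT_DX,
    qualifier=Qualifier.NONE,
    date=INDEX,
    patient_id="p1",
):
    """Shorthand claim-event builder for tests."""
    return ClaimEvent(patient_id, date, system, code, setting, qualifier)


def outpatient_pair(code, date=INDEX, qualifier=Qualifier.CONFIRMED, patient_id="p1"):
    """Two confirmed outpatient diagnoses on distinct service dates."""
    return [
        ev(code, setting=Setting.OUTPATIENT_DX, qualifier=qualifier, date=date,
           patient_id=patient_id),
        ev(code, setting=Setting.OUTPATIENT_DX, qualifier=qualifier,
           date=date + dt.timedelta(days=7), patient_id=patient_id),
    ]
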