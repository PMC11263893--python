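import datetime as dt

import numpy as np
import pandas as pd
import pytest

from claimgraph.cohort import CaseDefinition
from claimgraph.io import ClaimRecord, Demographics, PatientTimeline


def record(day: str, code: str, ctype: str = "diagnosis") -> ClaimRecord:
    return ClaimRecord(dt.date.fromisoformat(day), code, ctype)


def timeline(pid, days_codes, birth_year=1940, gender="F"):
    """days_codes: list of (iso-date, code[, code_type]) tuples."""
    recs = [record(*dc) for dc in days_codes]
    return PatientTimeline(pid, Demographics(pid, birth_year, gender), recs)


@pytest.fixture
def case_def():
    return CaseDefinition()


@pytest.fixture
def tiny_claims_frames():
    claims = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P1", "P2", "P2"],
            "service_date": ["2015-01-03", "2015-01-20", "2015-03-02",
                             "2016-02-01", "2016-02-15"],
            "code": ["250.00", "401.1", "71020", "E11.9", "metformin 500mg"],
            "code_type": ["diagnosis", "diagnosis", "procedure",
                          "diagnosis", "medication"],
        }
    )
    demo = pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3"],
            "birth_year": [1940, 1945, 1950],
            "gender": ["F", "M", "F"],
        }
    )
    return claims, demo


@pytest.fixture
def rng():
    return np.random.default_rng(0)
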