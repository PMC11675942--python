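import os

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from glp1gi import load_fixture
from glp1gi.reports import REPORT_COLUMNS, _coerce_frame

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

HERE = os.path.dirname(__file__)


@pytest.fixture(scope="session")
def fixture():
    return load_fixture()


@pytest.fixture(scope="session")
def faers_dir():
    return os.path.join(HERE, "data", "faers_mini")


def make_reports(rows):
    """Build a normalized report frame from compact row dicts."""
    defaults = {
        "case_version": 1,
        "role_code": "primary_suspect",
        "event_soc": "gastrointestinal",
        "sex": "female",
        "age_years": 60.0,
        "reporting_year": 2020,
        "reporter": "consumer",
        "country": "US",
        "indication": "diabetes_mellitus",
        "outcomes": "",
    }
    full = []
    for i, row in enumerate(rows):
        d = dict(defaults, report_id=f"r{i}", **row)
        d.setdefault("case_id", d["report_id"])
        full.append(d)
    return _coerce_frame(pd.DataFrame(full, columns=REPORT_COLUMNS))


@pytest.fixture
def ten_reports():
    """Ten single-event reports, four of them concomitant-role."""
    rows = []
    for i in range(10):
        rows.append(
            {
                "drug": ["exenatide", "liraglutide"][i % 2],
                "event_pt": "nausea",
                "role_code": "concomitant" if i < 4 else "primary_suspect",
                "sex": "female" if i < 6 else "male",
            }
        )
    return make_reports(rows)
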