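"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from aadpheno.codelists import Outcome
from aadpheno.simulate import default_class_map, default_codelists, representative_bnf
from aadpheno.tables import Cohort, MedClass

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DOB_MIN = dt.date(2007, 3, 1)
DOB_MAX = dt.date(2010, 12, 31)
FOLLOWUP_DAYS = 4018  # ~11 years


@pytest.fixture(scope="session")
def codelists():
    return default_codelists()


@pytest.fixture(scope="session")
def class_map():
    return default_class_map()


# ---------------------------------------------------------------------------
# strategies for small random cohorts
# ---------------------------------------------------------------------------

dobs = st.dates(min_value=DOB_MIN, max_value=DOB_MAX)
day_offsets = st.integers(min_value=0, max_value=FOLLOWUP_DAYS)
med_classes = st.sampled_from(list(MedClass))

child_spec = st.fixed_dictionaries(
    {
        "dob": dobs,
        "events": st.dictionaries(
            st.sampled_from(list(Outcome)),
            st.lists(day_offsets, max_size=6),
            max_size=3,
        ),
        "rx": st.lists(st.tuples(day_offsets, med_classes), max_size=14),
    }
)

cohort_specs = st.lists(child_spec, min_size=1, max_size=10)


def build_cohort(spec: list[dict]) -> Cohort:
    """Materialise a strategy-drawn cohort spec into real tables."""
    lists = default_codelists()
    children, events, rx = [], [], []
    for i, ch in enumerate(spec):
        cid = f"K{i:03d}"
        dob = ch["dob"]
        children.append(
            {
                "child_id": cid,
                "dob": dob,
                "followup_end": dob + dt.timedelta(days=FOLLOWUP_DAYS),
            }
        )
        for outcome, offsets in ch["events"].items():
            code = sorted(lists[outcome].includes())[0]
            for off in offsets:
                events.append(
                    {
                        "child_id": cid,
                        "event_date": dob + dt.timedelta(days=off),
                        "code": code,
                        "term": "",
                    }
                )
        for off, cls in ch["rx"]:
            rx.append(
                {
                    "child_id": cid,
                    "issue_date": dob + dt.timedelta(days=off),
                    "bnf_code": representative_bnf(cls),
                    "med_class": cls,
                }
            )
    return Cohort(
        children=pd.DataFrame(children, columns=["child_id", "dob", "followup_end"]),
        events=pd.DataFrame(events, columns=["child_id", "event_date", "code", "term"]),
        prescriptions=pd.DataFrame(
            rx, columns=["child_id", "issue_date", "bnf_code", "med_class"]
        ),
    )


@pytest.fixture
def toy_cohort_files(tmp_path, class_map):
    """Three tiny consistent CSV files plus a class-map CSV on disk."""
    children = tmp_path / "children.csv"
    events = tmp_path / "events.csv"
    rx = tmp_path / "prescriptions.csv"
    cmap = tmp_path / "class_map.csv"
    children.write_text(
        "child_id,dob,followup_end\n"
        "A,2008-01-10,2019-01-10\n"
        "B,2009-06-01,2020-06-01\n"
        "C,2007-11-20,2018-11-20\n"
    )
    events.write_text(
        "child_id,event_date,code,term\n"
        "A,2014-03-15,H33..,Asthma\n"
        "B,2011-06-15,M111.,Atopic dermatitis\n"
    )
    rx.write_text(
        "child_id,issue_date,bnf_code\n"
        "A,2014-03-20,0301011AA\n"
        "B,2011-06-20,1302010AA\n"
    )
    rows = ["bnf_prefix,med_class"] + [
        f"{p},{m.value}" for p, m in sorted(class_map.items())
    ]
    cmap.write_text("\n".join(rows) + "\n")
    return children, events, rx, cmap
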