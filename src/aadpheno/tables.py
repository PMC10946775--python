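"""Data model and delimited-text I/O for longitudinal primary-care extracts.

Three tables describe a cohort: children (one row per child, with date of
birth and end of follow-up), coded events (dated CTV3-style diagnosis codes
with their term text) and prescriptions (dated issues classified into
medication classes via a BNF-prefix map).  All dates are ISO-8601 in files.
Codes are opaque, case-sensitive identifiers; only term *text* is ever
matched case-insensitively (see :mod:`aadpheno.codelists`).

Rows that fail validation are never silently dropped: the loader collects
them into a rejects report (``source_file, row_number, reason``) so a
pipeline run is auditable end to end.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MedClass",
    "ChildRecord",
    "CodedEvent",
    "PrescriptionEvent",
    "Cohort",
    "FormatError",
    "load_cohort",
    "filter_min_followup_age",
    "load_class_map",
    "map_bnf_to_class",
    "write_cohort",
    "age_in_completed_years",
    "in_hay_fever_season",
    "HAY_FEVER_SEASON",
]

#: Inclusive month-day bounds of the hay fever (grass/tree pollen) season.
HAY_FEVER_SEASON = ((3, 1), (7, 31))


class MedClass(str, Enum):
    """Closed set of medication classes used by the case definitions."""

    BRONCHODILATOR = "bronchodilator"
    INHALED_CORTICOSTEROID = "inhaled_corticosteroid"
    LEUKOTRIENE_RECEPTOR_ANTAGONIST = "leukotriene_receptor_antagonist"
    TOPICAL_CORTICOSTEROID = "topical_corticosteroid"
    EMOLLIENT = "emollient"
    TOPICAL_CALCINEURIN_INHIBITOR = "topical_calcineurin_inhibitor"
    SYSTEMIC_CORTICOSTEROID = "systemic_corticosteroid"
    IMMUNOREGULATOR = "immunoregulator"
    ANTIHISTAMINE = "antihistamine"
    INTRANASAL_CORTICOSTEROID = "intranasal_corticosteroid"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes pooled for the asthma repeated-prescription rule.
ASTHMA_CLASSES = frozenset(
    {
        MedClass.BRONCHODILATOR,
        MedClass.INHALED_CORTICOSTEROID,
        MedClass.LEUKOTRIENE_RECEPTOR_ANTAGONIST,
    }
)

#: Eczema-related treatment classes (prescription window rule).
ECZEMA_CLASSES = frozenset(
    {
        MedClass.TOPICAL_CORTICOSTEROID,
        MedClass.EMOLLIENT,
        MedClass.TOPICAL_CALCINEURIN_INHIBITOR,
        MedClass.SYSTEMIC_CORTICOSTEROID,
        MedClass.IMMUNOREGULATOR,
    }
)

#: Allergic-rhinitis treatment classes (seasonal prescription rule).
RHINITIS_CLASSES = frozenset(
    {MedClass.ANTIHISTAMINE, MedClass.INTRANASAL_CORTICOSTEROID}
)


@dataclass(frozen=True)
class ChildRecord:
    child_id: str
    dob: dt.date
    followup_end: dt.date | None = None


@dataclass(frozen=True)
class CodedEvent:
    child_id: str
    event_date: dt.date
    code: str
    term: str = ""


@dataclass(frozen=True)
class PrescriptionEvent:
    child_id: str
    issue_date: dt.date
    bnf_code: str
    med_class: MedClass


class FormatError(ValueError):
    """A file is structurally unusable (e.g. a required column is missing)."""


@dataclass
class Cohort:
    """Validated in-memory cohort: three DataFrames plus the rejects report.

    ``children`` has columns ``child_id, dob, followup_end``; ``events`` has
    ``child_id, event_date, code, term``; ``prescriptions`` has
    ``child_id, issue_date, bnf_code, med_class`` (``med_class`` holds
    :class:`MedClass` values).  Date columns hold ``datetime.date`` objects.
    """

    children: pd.DataFrame
    events: pd.DataFrame
    prescriptions: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: _empty_rejects()
    )

    def __post_init__(self) -> None:
        ids = self.children["child_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate child_id values: {dupes[:5]}")

    @property
    def n_children(self) -> int:
        return len(self.children)

    def child_records(self) -> list[ChildRecord]:
        return [
            ChildRecord(r.child_id, r.dob, r.followup_end)
            for r in self.children.itertuples(index=False)
        ]


def _empty_rejects() -> pd.DataFrame:
    return pd.DataFrame(columns=["source_file", "row_number", "reason"])


# ---------------------------------------------------------------------------
# Calendar primitives
# ---------------------------------------------------------------------------

def _anniversary(dob: dt.date, year: int) -> dt.date:
    """The birthday in ``year``; Feb-29 birthdays fall on Mar 1 off leap years."""
    if dob.month == 2 and dob.day == 29 and not calendar.isleap(year):
        return dt.date(year, 3, 1)
    return dt.date(year, dob.month, dob.day)


def age_in_completed_years(dob: dt.date, on: dt.date) -> int:
    """Number of whole birthdays elapsed by ``on`` (the birthday itself counts).

    Raises ``ValueError`` when ``on`` precedes ``dob``.
    """
    if on < dob:
        raise ValueError(f"date {on} precedes date of birth {dob}")
    age = on.year - dob.year
    if on < _anniversary(dob, on.year):
        age -= 1
    return age


def nth_birthday(dob: dt.date, n: int) -> dt.date:
    """Date of the ``n``-th birthday (Feb-29 convention as above)."""
    return _anniversary(dob, dob.year + n)


def in_hay_fever_season(d: dt.date) -> bool:
    """True iff ``d`` falls on 1 March–31 July inclusive, any year."""
    lo, hi = HAY_FEVER_SEASON
    return lo <= (d.month, d.day) <= hi


# ---------------------------------------------------------------------------
# BNF class map
# ---------------------------------------------------------------------------

def load_class_map(path: str | Path) -> dict[str, MedClass]:
    """Read a ``bnf_prefix,med_class`` CSV into a prefix→class mapping."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["bnf_prefix", "med_class"], str(path))
    mapping: dict[str, MedClass] = {}
    for row in df.itertuples(index=False):
        mapping[str(row.bnf_prefix)] = MedClass(row.med_class)
    return mapping


def map_bnf_to_class(
    bnf_code: str, class_map: Mapping[str, MedClass]
) -> MedClass | None:
    """Resolve a BNF code to its medication class by longest-prefix match."""
    best: str | None = None
    for prefix in class_map:
        if bnf_code.startswith(prefix) and (best is None or len(prefix) > len(best)):
            best = prefix
    return class_map[best] if best is not None else None


# ---------------------------------------------------------------------------
# Loading with row-level validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], source: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing required column(s) {missing}")


def _parse_date(value: object) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        return None


def load_cohort(
    children_path: str | Path,
    events_path: str | Path,
    prescriptions_path: str | Path,
    class_map: Mapping[str, MedClass] | str | Path,
) -> Cohort:
    """Load and validate the three cohort tables.

    Row-level problems (unparseable dates, unknown child ids, events outside
    a child's follow-up interval, unmapped BNF codes) are routed to the
    rejects report; structural problems (missing columns) raise
    :class:`FormatError`.  Row numbers in the report are 1-based data rows
    (the header is row 0).
    """
    if not isinstance(class_map, Mapping):
        class_map = load_class_map(class_map)

    rejects: list[tuple[str, int, str]] = []

    children_df = pd.read_csv(children_path, dtype=str)
    _require_columns(children_df, ["child_id", "dob"], str(children_path))
    if "followup_end" not in children_df.columns:
        children_df["followup_end"] = None

    kept_children: list[dict] = []
    window: dict[str, tuple[dt.date, dt.date | None]] = {}
    for i, row in enumerate(children_df.itertuples(index=False), start=1):
        cid = str(row.child_id) if not pd.isna(row.child_id) else ""
        dob = _parse_date(row.dob)
        fu = _parse_date(row.followup_end)
        if not cid:
            rejects.append((str(children_path), i, "empty child_id"))
            continue
        if dob is None:
            rejects.append((str(children_path), i, "unparseable dob"))
            continue
        if fu is None and not pd.isna(row.followup_end) and row.followup_end:
            rejects.append((str(children_path), i, "unparseable followup_end"))
            continue
        if fu is not None and fu < dob:
            rejects.append((str(children_path), i, "followup_end before dob"))
            continue
        if cid in window:
            rejects.append((str(children_path), i, "duplicate child_id"))
            continue
        window[cid] = (dob, fu)
        kept_children.append({"child_id": cid, "dob": dob, "followup_end": fu})

    def _in_window(cid: str, d: dt.date) -> str | None:
        dob, fu = window[cid]
        if d < dob:
            return "date before dob"
        if fu is not None and d > fu:
            return "date after followup_end"
        return None

    events_df = pd.read_csv(events_path, dtype=str)
    _require_columns(events_df, ["child_id", "event_date", "code"], str(events_path))
    if "term" not in events_df.columns:
        events_df["term"] = ""
    kept_events: list[dict] = []
    for i, row in enumerate(events_df.itertuples(index=False), start=1):
        cid = str(row.child_id) if not pd.isna(row.child_id) else ""
        d = _parse_date(row.event_date)
        code = "" if pd.isna(row.code) else str(row.code)
        if cid not in window:
            rejects.append((str(events_path), i, f"unknown child_id {cid!r}"))
            continue
        if d is None:
            rejects.append((str(events_path), i, "unparseable event_date"))
            continue
        if not code:
            rejects.append((str(events_path), i, "empty code"))
            continue
        why = _in_window(cid, d)
        if why is not None:
            rejects.append((str(events_path), i, f"event_date {why}"))
            continue
        term = "" if pd.isna(row.term) else str(row.term)
        kept_events.append(
            {"child_id": cid, "event_date": d, "code": code, "term": term}
        )

    rx_df = pd.read_csv(prescriptions_path, dtype=str)
    _require_columns(
        rx_df, ["child_id", "issue_date", "bnf_code"], str(prescriptions_path)
    )
    kept_rx: list[dict] = []
    for i, row in enumerate(rx_df.itertuples(index=False), start=1):
        cid = str(row.child_id) if not pd.isna(row.child_id) else ""
        d = _parse_date(row.issue_date)
        bnf = "" if pd.isna(row.bnf_code) else str(row.bnf_code)
        if cid not in window:
            rejects.append((str(prescriptions_path), i, f"unknown child_id {cid!r}"))
            continue
        if d is None:
            rejects.append((str(prescriptions_path), i, "unparseable issue_date"))
            continue
        why = _in_window(cid, d)
        if why is not None:
            rejects.append((str(prescriptions_path), i, f"issue_date {why}"))
            continue
        med = map_bnf_to_class(bnf, class_map)
        if med is None:
            rejects.append(
                (str(prescriptions_path), i, f"unmapped bnf_code {bnf!r}")
            )
            continue
        kept_rx.append(
            {"child_id": cid, "issue_date": d, "bnf_code": bnf, "med_class": med}
        )

    return Cohort(
        children=pd.DataFrame(
            kept_children, columns=["child_id", "dob", "followup_end"]
        ),
        events=pd.DataFrame(
            kept_events, columns=["child_id", "event_date", "code", "term"]
        ),
        prescriptions=pd.DataFrame(
            kept_rx, columns=["child_id", "issue_date", "bnf_code", "med_class"]
        ),
        rejects=pd.DataFrame(
            rejects, columns=["source_file", "row_number", "reason"]
        ),
    )


def filter_min_followup_age(cohort: Cohort, min_years: int) -> Cohort:
    """Drop children not observed to at least ``min_years`` completed years
    (optional filter, off by default in the pipeline: children with short
    follow-up otherwise remain and are simply harder to classify as cases)."""
    keep = set()
    for r in cohort.children.itertuples(index=False):
        end = r.followup_end
        if end is None or age_in_completed_years(r.dob, end) >= min_years:
            keep.add(r.child_id)
    return Cohort(
        children=cohort.children[
            cohort.children["child_id"].isin(keep)
        ].reset_index(drop=True),
        events=cohort.events[
            cohort.events["child_id"].isin(keep)
        ].reset_index(drop=True),
        prescriptions=cohort.prescriptions[
            cohort.prescriptions["child_id"].isin(keep)
        ].reset_index(drop=True),
        rejects=cohort.rejects,
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _iso(d: object) -> str:
    return d.isoformat() if isinstance(d, dt.date) else ""


def write_cohort(
    cohort: Cohort,
    children_path: str | Path,
    events_path: str | Path,
    prescriptions_path: str | Path,
    rejects_path: str | Path | None = None,
) -> None:
    """Write the cohort back to canonical CSVs (ISO dates, LF endings)."""
    ch = cohort.children.copy()
    ch["dob"] = ch["dob"].map(_iso)
    ch["followup_end"] = ch["followup_end"].map(_iso)
    ch.to_csv(children_path, index=False, lineterminator="\n")

    ev = cohort.events.copy()
    ev["event_date"] = ev["event_date"].map(_iso)
    ev.to_csv(events_path, index=False, lineterminator="\n")

    # med_class is derived from the BNF map, so the on-disk table keeps only
    # the source columns and read→write round-trips byte-identically.
    rx = cohort.prescriptions[["child_id", "issue_date", "bnf_code"]].copy()
    rx["issue_date"] = rx["issue_date"].map(_iso)
    rx.to_csv(prescriptions_path, index=False, lineterminator="\n")

    if rejects_path is not None:
        cohort.rejects.to_csv(rejects_path, index=False, lineterminator="\n")
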