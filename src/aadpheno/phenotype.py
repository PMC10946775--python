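"""Rule-based case definitions for childhood asthma, eczema and rhinitis.

Each outcome has two definitions over a child's coded diagnosis events and
prescription issues:

* **Asthma, 1st definition** — a selected asthma code at completed age ≥ 6,
  OR a code at ages 3–5 together with at least 3 prescriptions of asthma
  medication (bronchodilators, inhaled corticosteroids or leukotriene
  receptor antagonists, pooled) in at least one age-year from age 6.  The
  repeated-prescription arm exists because wheeze under 6 often resolves,
  so an early code alone is weak evidence.
* **Asthma, 2nd definition** — any selected code at age ≥ 3, irrespective
  of prescriptions.
* **Eczema, 1st definition** — a first eczema code at age ≥ 1 (infant
  rashes are excluded wholesale) plus at least two eczema-related
  prescription items within 90 days before to 365 days after that first
  code, both endpoints inclusive.
* **Eczema, 2nd definition** — any eczema code at age ≥ 1.
* **Allergic rhinitis, 1st definition** — any rhinitis or allergic
  conjunctivitis code at any age.
* **Allergic rhinitis, 2nd definition** (the more specific one) — a
  qualifying code dated inside the hay fever season (1 March–31 July) plus
  at least one antihistamine or intranasal corticosteroid issue inside a
  hay fever season; by default the two seasons need not be the same year.

Ages are completed years; "per year" counts prescriptions per age-year
(birthday to next birthday).  Every positive classification carries an
evidence list naming the rule branch and the triggering dates, so a case
can be audited back to its records.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codelists import Codelist, Outcome
from .tables import (
    ASTHMA_CLASSES,
    ECZEMA_CLASSES,
    RHINITIS_CLASSES,
    ChildRecord,
    Cohort,
    MedClass,
    age_in_completed_years,
    in_hay_fever_season,
    nth_birthday,
)

__all__ = [
    "RuleConstants",
    "RuleFlags",
    "CaseStatus",
    "prescriptions_per_age_year",
    "classify_asthma_def1",
    "classify_asthma_def2",
    "classify_eczema_def1",
    "classify_eczema_def2",
    "classify_rhinitis_def1",
    "classify_rhinitis_def2",
    "classify_cohort",
    "VARIANTS",
]

VARIANTS = ("def1", "def2")


@dataclass(frozen=True)
class RuleConstants:
    """Numeric constants of the case definitions (defaults match the rules
    described in the module docstring; change only to explore variants)."""

    asthma_code_age: int = 6
    asthma_early_ages: tuple[int, int] = (3, 5)  # completed years, inclusive
    asthma_min_rx_per_year: int = 3
    asthma_rx_from_age: int = 6
    asthma_def2_min_age: int = 3
    eczema_min_age: int = 1
    eczema_min_rx: int = 2
    eczema_days_before: int = 90
    eczema_days_after: int = 365
    rhinitis_min_seasonal_rx: int = 1


@dataclass(frozen=True)
class RuleFlags:
    """Switches for the alternative readings of ambiguous rule prose."""

    #: Pool the three asthma drug classes when counting "3 per year" (the
    #: "or" read as a union).  False = each class must reach 3 on its own.
    pool_asthma_classes: bool = True
    #: Require the seasonal rhinitis code and prescription to fall in the
    #: same calendar year.  False = any two seasons qualify.
    rhinitis_same_year: bool = False


DEFAULT_CONSTANTS = RuleConstants()
DEFAULT_FLAGS = RuleFlags()


@dataclass(frozen=True)
class CaseStatus:
    child_id: str
    outcome: Outcome
    variant: str
    is_case: bool
    evidence: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if self.is_case and not self.evidence:
            raise ValueError("a case must carry evidence")


# ---------------------------------------------------------------------------
# input normalisation helpers
# ---------------------------------------------------------------------------

def _event_dates(events: Iterable) -> list[dt.date]:
    out = []
    for e in events:
        out.append(e.event_date if hasattr(e, "event_date") else e)
    return sorted(out)


def _rx_items(rx: Iterable) -> list[tuple[dt.date, MedClass]]:
    out = []
    for r in rx:
        if hasattr(r, "issue_date"):
            out.append((r.issue_date, MedClass(r.med_class)))
        else:
            d, m = r
            out.append((d, MedClass(m)))
    return sorted(out, key=lambda t: (t[0], t[1].value))


def _status(child, outcome, variant, evidence):
    return CaseStatus(
        child_id=child.child_id,
        outcome=outcome,
        variant=variant,
        is_case=bool(evidence),
        evidence=tuple(evidence),
    )


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def prescriptions_per_age_year(
    child: ChildRecord,
    rx: Iterable,
    classes: frozenset[MedClass] | set[MedClass],
    from_age: int,
) -> dict[int, int]:
    """Count prescription items per age-year [k-th, (k+1)-th birthday), k ≥ from_age.

    Items of the given classes are pooled.  Ages with zero items are absent
    from the map.
    """
    counts: dict[int, int] = {}
    start = nth_birthday(child.dob, from_age)
    for d, med in _rx_items(rx):
        if med not in classes or d < start:
            continue
        k = age_in_completed_years(child.dob, d)
        counts[k] = counts.get(k, 0) + 1
    return counts


def _per_class_age_year_ok(child, rx, classes, from_age, threshold):
    """Strict mode: some single class reaches the threshold in some age-year."""
    for cls in classes:
        counts = prescriptions_per_age_year(child, rx, {cls}, from_age)
        if any(v >= threshold for v in counts.values()):
            return True
    return False


# ---------------------------------------------------------------------------
# the six classifiers
# ---------------------------------------------------------------------------

def classify_asthma_def1(
    child: ChildRecord,
    events: Iterable,
    rx: Iterable,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    flags: RuleFlags = DEFAULT_FLAGS,
) -> CaseStatus:
    """Asthma, 1st definition: code at ≥6y, or code at 3–5y plus ≥3 asthma
    prescriptions in at least one age-year from age 6.

    ``events`` must already be restricted to the asthma codelist includes.
    """
    dates = _event_dates(events)
    items = [(d, m) for d, m in _rx_items(rx) if m in ASTHMA_CLASSES]
    evidence = []

    late = [d for d in dates if age_in_completed_years(child.dob, d) >= constants.asthma_code_age]
    if late:
        evidence.append(
            {"branch": "code_at_6_or_older", "dates": [d.isoformat() for d in late]}
        )
    else:
        lo, hi = constants.asthma_early_ages
        early = [
            d for d in dates
            if lo <= age_in_completed_years(child.dob, d) <= hi
        ]
        if early:
            if flags.pool_asthma_classes:
                counts = prescriptions_per_age_year(
                    child, items, ASTHMA_CLASSES, constants.asthma_rx_from_age
                )
                years = sorted(
                    k for k, v in counts.items()
                    if v >= constants.asthma_min_rx_per_year
                )
            else:
                years = []
                if _per_class_age_year_ok(
                    child, items, ASTHMA_CLASSES,
                    constants.asthma_rx_from_age,
                    constants.asthma_min_rx_per_year,
                ):
                    years = ["per-class"]
            if years:
                evidence.append(
                    {
                        "branch": "code_at_3_to_5_plus_repeat_rx",
                        "dates": [d.isoformat() for d in early],
                        "qualifying_age_years": years,
                    }
                )
    return _status(child, Outcome.ASTHMA, "def1", evidence)


def classify_asthma_def2(
    child: ChildRecord,
    events: Iterable,
    constants: RuleConstants = DEFAULT_CONSTANTS,
) -> CaseStatus:
    """Asthma, 2nd definition: any selected code at age ≥3, prescriptions ignored."""
    hits = [
        d for d in _event_dates(events)
        if age_in_completed_years(child.dob, d) >= constants.asthma_def2_min_age
    ]
    evidence = (
        [{"branch": "code_at_3_or_older", "dates": [d.isoformat() for d in hits]}]
        if hits else []
    )
    return _status(child, Outcome.ASTHMA, "def2", evidence)


def first_eligible_eczema_code(
    child: ChildRecord, events: Iterable, constants: RuleConstants = DEFAULT_CONSTANTS
) -> dt.date | None:
    """Date of the first eczema code at age ≥1; earlier codes never count."""
    for d in _event_dates(events):
        if age_in_completed_years(child.dob, d) >= constants.eczema_min_age:
            return d
    return None


def classify_eczema_def1(
    child: ChildRecord,
    events: Iterable,
    rx: Iterable,
    constants: RuleConstants = DEFAULT_CONSTANTS,
) -> CaseStatus:
    """Eczema, 1st definition: first code at age ≥1 plus ≥2 eczema-related
    prescription items within [first code − 90 d, first code + 365 d]."""
    first = first_eligible_eczema_code(child, events, constants)
    evidence = []
    if first is not None:
        lo = first - dt.timedelta(days=constants.eczema_days_before)
        hi = first + dt.timedelta(days=constants.eczema_days_after)
        in_window = [
            (d, m) for d, m in _rx_items(rx)
            if m in ECZEMA_CLASSES and lo <= d <= hi
        ]
        if len(in_window) >= constants.eczema_min_rx:
            evidence.append(
                {
                    "branch": "first_code_plus_2_rx_in_window",
                    "first_code": first.isoformat(),
                    "dates": [d.isoformat() for d, _ in in_window],
                }
            )
    return _status(child, Outcome.ECZEMA, "def1", evidence)


def classify_eczema_def2(
    child: ChildRecord,
    events: Iterable,
    constants: RuleConstants = DEFAULT_CONSTANTS,
) -> CaseStatus:
    """Eczema, 2nd definition: any code at age ≥1, prescriptions ignored."""
    hits = [
        d for d in _event_dates(events)
        if age_in_completed_years(child.dob, d) >= constants.eczema_min_age
    ]
    evidence = (
        [{"branch": "code_at_1_or_older", "dates": [d.isoformat() for d in hits]}]
        if hits else []
    )
    return _status(child, Outcome.ECZEMA, "def2", evidence)


def classify_rhinitis_def1(child: ChildRecord, events: Iterable) -> CaseStatus:
    """Rhinitis, 1st definition: any rhinitis/conjunctivitis code at any age."""
    hits = _event_dates(events)
    evidence = (
        [{"branch": "code_any_age", "dates": [d.isoformat() for d in hits]}]
        if hits else []
    )
    return _status(child, Outcome.ALLERGIC_RHINITIS, "def1", evidence)


def classify_rhinitis_def2(
    child: ChildRecord,
    events: Iterable,
    rx: Iterable,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    flags: RuleFlags = DEFAULT_FLAGS,
) -> CaseStatus:
    """Rhinitis, 2nd definition: seasonal code plus ≥1 seasonal antihistamine
    or intranasal corticosteroid issue (seasons may differ in year unless the
    same-year flag is set)."""
    codes = [d for d in _event_dates(events) if in_hay_fever_season(d)]
    items = [
        (d, m) for d, m in _rx_items(rx)
        if m in RHINITIS_CLASSES and in_hay_fever_season(d)
    ]
    evidence = []
    if flags.rhinitis_same_year:
        years = sorted(
            {d.year for d in codes} & {d.year for d, _ in items}
        )
        ok = len(years) > 0 and len(items) >= constants.rhinitis_min_seasonal_rx
        if ok:
            codes = [d for d in codes if d.year in years]
            items = [(d, m) for d, m in items if d.year in years]
    else:
        ok = bool(codes) and len(items) >= constants.rhinitis_min_seasonal_rx
    if ok:
        evidence.append(
            {
                "branch": "seasonal_code_plus_seasonal_rx",
                "dates": [d.isoformat() for d in codes],
                "rx_dates": [d.isoformat() for d, _ in items],
            }
        )
    return _status(child, Outcome.ALLERGIC_RHINITIS, "def2", evidence)


# ---------------------------------------------------------------------------
# cohort driver
# ---------------------------------------------------------------------------

def _filter_events(events: pd.DataFrame, codes: frozenset[str]) -> dict[str, list]:
    by_child: dict[str, list] = {}
    if len(events):
        hit = events[events["code"].isin(codes)]
        for r in hit.itertuples(index=False):
            by_child.setdefault(r.child_id, []).append(r.event_date)
    return by_child


def classify_cohort(
    cohort: Cohort,
    codelists: Mapping[Outcome, Codelist],
    outcomes: Sequence[Outcome] | None = None,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    flags: RuleFlags = DEFAULT_FLAGS,
) -> pd.DataFrame:
    """Classify every child under both definitions of each requested outcome.

    Returns a DataFrame with one row per child × outcome × variant and
    columns ``child_id, outcome, variant, is_case, evidence_json``; the
    result is deterministic given the inputs (children in table order,
    outcomes in enum order, evidence dates sorted).
    """
    if outcomes is None:
        outcomes = [o for o in Outcome if o in codelists]
    missing = [o for o in outcomes if o not in codelists]
    if missing:
        raise ValueError(f"no codelist supplied for outcome(s) {missing}")

    events_by: dict[Outcome, dict[str, list]] = {
        o: _filter_events(cohort.events, codelists[o].includes()) for o in outcomes
    }
    rx_by_child: dict[str, list] = {}
    for r in cohort.prescriptions.itertuples(index=False):
        rx_by_child.setdefault(r.child_id, []).append(
            (r.issue_date, MedClass(r.med_class))
        )

    rows = []
    for child in cohort.child_records():
        rx = rx_by_child.get(child.child_id, [])
        for outcome in outcomes:
            ev = events_by[outcome].get(child.child_id, [])
            if outcome is Outcome.ASTHMA:
                statuses = (
                    classify_asthma_def1(child, ev, rx, constants, flags),
                    classify_asthma_def2(child, ev, constants),
                )
            elif outcome is Outcome.ECZEMA:
                statuses = (
                    classify_eczema_def1(child, ev, rx, constants),
                    classify_eczema_def2(child, ev, constants),
                )
            else:
                statuses = (
                    classify_rhinitis_def1(child, ev),
                    classify_rhinitis_def2(child, ev, rx, constants, flags),
                )
            for s in statuses:
                rows.append(
                    {
                        "child_id": s.child_id,
                        "outcome": s.outcome.value,
                        "variant": s.variant,
                        "is_case": s.is_case,
                        "evidence_json": json.dumps(list(s.evidence)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["child_id", "outcome", "variant", "is_case", "evidence_json"]
    )
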