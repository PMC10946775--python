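"""Code-vs-prescription concordance: 2×2 tables, PPV/NPV, binomial CIs.

For each outcome and medication class, every child in the cohort is
cross-tabulated by *code status* (does the child carry a relevant diagnosis
code, under the outcome's age restriction) against *prescription status*
(does the child meet the class's exposure criterion).  The prescriptions
act as the "test" and the codes as the reference, so

* PPV = a / (a + b): proportion with a relevant code among the prescribed;
* NPV = d / (c + d): proportion without a code among the unprescribed,

with a = code+/prescribed+, b = code−/prescribed+, c = code+/prescribed−,
d = code−/prescribed−.  A low PPV for a class flags medicines widely used
without (or before) a coded diagnosis — typical of over-the-counter
remedies such as emollients and antihistamines — while prescription-only
asthma inhalers track the codes closely.

Confidence intervals default to Clopper–Pearson (exact), which stays
meaningful at the boundaries: at x = n the interval is
(0.025**(1/n), 1.0) rather than the degenerate point a normal
approximation produces.  Wilson and Wald are available as alternatives.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .codelists import Codelist, Outcome
from .phenotype import prescriptions_per_age_year
from .tables import (
    ChildRecord,
    Cohort,
    MedClass,
    age_in_completed_years,
    in_hay_fever_season,
)

__all__ = [
    "TwoByTwo",
    "PredictiveValues",
    "ExposureCriteria",
    "UndefinedProportionError",
    "ppv",
    "npv",
    "binomial_ci",
    "predictive_values",
    "code_status",
    "code_status_from_classification",
    "CODE_ONLY_VARIANT",
    "prescribed_status",
    "build_two_by_two",
    "predictive_value_table",
    "render_markdown",
    "round_half_up",
    "TABLE_CLASSES",
    "CODE_STATUS_MIN_AGE",
]

#: Medication classes reported per outcome (the "any" union row pools them).
TABLE_CLASSES: dict[Outcome, tuple[MedClass, ...]] = {
    Outcome.ASTHMA: (
        MedClass.BRONCHODILATOR,
        MedClass.INHALED_CORTICOSTEROID,
        MedClass.LEUKOTRIENE_RECEPTOR_ANTAGONIST,
    ),
    Outcome.ECZEMA: (
        MedClass.TOPICAL_CORTICOSTEROID,
        MedClass.EMOLLIENT,
        MedClass.TOPICAL_CALCINEURIN_INHIBITOR,
        MedClass.SYSTEMIC_CORTICOSTEROID,
    ),
    Outcome.ALLERGIC_RHINITIS: (
        MedClass.ANTIHISTAMINE,
        MedClass.INTRANASAL_CORTICOSTEROID,
    ),
}

#: Minimum completed age for a code to count towards code-only status
#: (asthma codes under 3 and eczema codes under 1 are not trusted).
CODE_STATUS_MIN_AGE: dict[Outcome, int] = {
    Outcome.ASTHMA: 3,
    Outcome.ECZEMA: 1,
    Outcome.ALLERGIC_RHINITIS: 0,
}


class UndefinedProportionError(ZeroDivisionError):
    """A predictive value has an empty denominator; nothing can be reported."""


@dataclass(frozen=True)
class TwoByTwo:
    """Concordance counts: a=code+/rx+, b=code−/rx+, c=code+/rx−, d=code−/rx−."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class PredictiveValues:
    ppv: float
    npv: float
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    method: str = "exact"

    def __post_init__(self) -> None:
        for point, (lo, hi) in ((self.ppv, self.ppv_ci), (self.npv, self.npv_ci)):
            if not (0.0 <= lo <= point + 1e-12 and point - 1e-12 <= hi <= 1.0):
                raise ValueError("interval must bracket the point estimate in [0,1]")


@dataclass(frozen=True)
class ExposureCriteria:
    """Prescription-exposure thresholds used for the concordance table.

    Asthma: ≥3 items of the class in at least one age-year from age 6
    (the repeated-prescription criterion of the asthma rules).  Eczema: ≥2
    items at any completed age 0–7.  Allergic rhinitis: ≥1 item issued
    during a hay fever season at completed age 0–6.
    """

    asthma_min_items: int = 3
    asthma_from_age: int = 6
    eczema_min_items: int = 2
    eczema_max_age: int = 7
    rhinitis_min_items: int = 1
    rhinitis_max_age: int = 6


DEFAULT_CRITERIA = ExposureCriteria()


# ---------------------------------------------------------------------------
# proportions and intervals
# ---------------------------------------------------------------------------

def ppv(t: TwoByTwo) -> float:
    """Positive predictive value a/(a+b); undefined when nobody is prescribed."""
    if t.a + t.b == 0:
        raise UndefinedProportionError("no prescribed children: PPV undefined")
    return t.a / (t.a + t.b)


def npv(t: TwoByTwo) -> float:
    """Negative predictive value d/(c+d); undefined when everyone is prescribed."""
    if t.c + t.d == 0:
        raise UndefinedProportionError("no unprescribed children: NPV undefined")
    return t.d / (t.c + t.d)


_METHOD_MAP = {"exact": "beta", "wilson": "wilson", "wald": "normal"}


def binomial_ci(
    x: int, n: int, level: float = 0.95, method: str = "exact"
) -> tuple[float, float]:
    """Two-sided binomial confidence interval for x successes in n trials.

    ``method`` is one of ``exact`` (Clopper–Pearson), ``wilson`` or ``wald``.
    The exact interval has lower bound 0 at x=0 and upper bound 1 at x=n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    if method not in _METHOD_MAP:
        raise ValueError(f"unknown method {method!r}; use exact|wilson|wald")
    lo, hi = proportion_confint(x, n, alpha=1 - level, method=_METHOD_MAP[method])
    # statsmodels leaves NaN at the degenerate boundaries of the beta interval
    lo = 0.0 if pd.isna(lo) else float(lo)
    hi = 1.0 if pd.isna(hi) else float(hi)
    if method == "wald":  # clip the normal interval into the unit range
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return lo, hi


def predictive_values(
    t: TwoByTwo, level: float = 0.95, method: str = "exact"
) -> PredictiveValues:
    """PPV and NPV with confidence intervals for one 2×2 table."""
    return PredictiveValues(
        ppv=ppv(t),
        npv=npv(t),
        ppv_ci=binomial_ci(t.a, t.a + t.b, level, method),
        npv_ci=binomial_ci(t.d, t.c + t.d, level, method),
        method=method,
    )


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.615 → 0.62 at 2 digits), as report tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# per-child statuses
# ---------------------------------------------------------------------------

def code_status(
    cohort: Cohort, codelist: Codelist, outcome: Outcome
) -> dict[str, bool]:
    """Code-only disease status per child: any codelist code at or above the
    outcome's minimum age."""
    min_age = CODE_STATUS_MIN_AGE[outcome]
    codes = codelist.includes()
    dob = dict(zip(cohort.children["child_id"], cohort.children["dob"]))
    status = {cid: False for cid in dob}
    if len(cohort.events):
        hit = cohort.events[cohort.events["code"].isin(codes)]
        for r in hit.itertuples(index=False):
            if age_in_completed_years(dob[r.child_id], r.event_date) >= min_age:
                status[r.child_id] = True
    return status


#: The code-only classification variant per outcome (these coincide with
#: code-only disease status: asthma/eczema 2nd definitions, rhinitis 1st).
CODE_ONLY_VARIANT: dict[Outcome, str] = {
    Outcome.ASTHMA: "def2",
    Outcome.ECZEMA: "def2",
    Outcome.ALLERGIC_RHINITIS: "def1",
}


def code_status_from_classification(
    status: pd.DataFrame, outcome: Outcome
) -> dict[str, bool]:
    """Extract code-only status from a classification table (the output of
    :func:`aadpheno.phenotype.classify_cohort`)."""
    variant = CODE_ONLY_VARIANT[outcome]
    sub = status[
        (status["outcome"] == outcome.value) & (status["variant"] == variant)
    ]
    out = {}
    for r in sub.itertuples(index=False):
        val = r.is_case
        if isinstance(val, str):
            val = val.strip().lower() in ("true", "1", "yes")
        out[r.child_id] = bool(val)
    return out


def prescribed_status(
    child: ChildRecord,
    rx: Iterable[tuple[dt.date, MedClass]],
    outcome: Outcome,
    med_class: MedClass | str,
    criteria: ExposureCriteria = DEFAULT_CRITERIA,
) -> bool:
    """Does the child meet the exposure criterion for one medication class,
    or for the pooled ``"any"`` union (true iff any component class meets
    its own criterion)?"""
    if med_class == "any":
        return any(
            prescribed_status(child, rx, outcome, cls, criteria)
            for cls in TABLE_CLASSES[outcome]
        )
    med_class = MedClass(med_class)
    items = [(d, m) for d, m in rx if m == med_class]
    if outcome is Outcome.ASTHMA:
        counts = prescriptions_per_age_year(
            child, items, {med_class}, criteria.asthma_from_age
        )
        return any(v >= criteria.asthma_min_items for v in counts.values())
    if outcome is Outcome.ECZEMA:
        n = sum(
            1 for d, _ in items
            if age_in_completed_years(child.dob, d) <= criteria.eczema_max_age
        )
        return n >= criteria.eczema_min_items
    n = sum(
        1 for d, _ in items
        if in_hay_fever_season(d)
        and age_in_completed_years(child.dob, d) <= criteria.rhinitis_max_age
    )
    return n >= criteria.rhinitis_min_items


def _rx_by_child(cohort: Cohort) -> dict[str, list[tuple[dt.date, MedClass]]]:
    by: dict[str, list] = {}
    for r in cohort.prescriptions.itertuples(index=False):
        by.setdefault(r.child_id, []).append((r.issue_date, MedClass(r.med_class)))
    return by


def build_two_by_two(
    cohort: Cohort,
    code_status_map: Mapping[str, bool],
    outcome: Outcome,
    med_class: MedClass | str,
    criteria: ExposureCriteria = DEFAULT_CRITERIA,
) -> TwoByTwo:
    """Cross-tabulate code status against prescription status; every child in
    the cohort lands in exactly one cell."""
    rx_by = _rx_by_child(cohort)
    a = b = c = d = 0
    for child in cohort.child_records():
        code_pos = bool(code_status_map[child.child_id])
        rx_pos = prescribed_status(
            child, rx_by.get(child.child_id, []), outcome, med_class, criteria
        )
        if code_pos and rx_pos:
            a += 1
        elif rx_pos:
            b += 1
        elif code_pos:
            c += 1
        else:
            d += 1
    return TwoByTwo(a, b, c, d)


# ---------------------------------------------------------------------------
# report table
# ---------------------------------------------------------------------------

def _fmt_pv(point: float, ci: tuple[float, float]) -> str:
    return (
        f"{round_half_up(point, 2):.2f} "
        f"({round_half_up(ci[0], 2):.2f}, {round_half_up(ci[1], 2):.2f})"
    )


def table_row(
    t: TwoByTwo,
    outcome: Outcome,
    med_class: MedClass | str,
    level: float = 0.95,
    method: str = "exact",
) -> dict:
    """One report row: counts, column percentages (1 dp), PPV/NPV (2 dp, CI).

    Undefined predictive values are rendered as blank cells.
    """
    name = med_class if isinstance(med_class, str) else med_class.value
    row: dict = {
        "outcome": outcome.value,
        "med_class": name,
        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
        "pct_code_yes_rx_yes": round_half_up(100 * t.a / (t.a + t.c), 1)
        if t.a + t.c else float("nan"),
        "pct_code_no_rx_yes": round_half_up(100 * t.b / (t.b + t.d), 1)
        if t.b + t.d else float("nan"),
    }
    try:
        p = ppv(t)
        ci = binomial_ci(t.a, t.a + t.b, level, method)
        row["ppv"], row["ppv_lo"], row["ppv_hi"] = p, ci[0], ci[1]
        row["ppv_fmt"] = _fmt_pv(p, ci)
    except UndefinedProportionError:
        row["ppv"] = row["ppv_lo"] = row["ppv_hi"] = float("nan")
        row["ppv_fmt"] = ""
    try:
        q = npv(t)
        ci = binomial_ci(t.d, t.c + t.d, level, method)
        row["npv"], row["npv_lo"], row["npv_hi"] = q, ci[0], ci[1]
        row["npv_fmt"] = _fmt_pv(q, ci)
    except UndefinedProportionError:
        row["npv"] = row["npv_lo"] = row["npv_hi"] = float("nan")
        row["npv_fmt"] = ""
    return row


_COLUMNS = [
    "outcome", "med_class", "a", "b", "c", "d",
    "pct_code_yes_rx_yes", "pct_code_no_rx_yes",
    "ppv", "ppv_lo", "ppv_hi", "ppv_fmt",
    "npv", "npv_lo", "npv_hi", "npv_fmt",
]


def predictive_value_table(
    cohort: Cohort,
    codelists: Mapping[Outcome, Codelist],
    criteria: ExposureCriteria = DEFAULT_CRITERIA,
    level: float = 0.95,
    method: str = "exact",
    outcomes: Sequence[Outcome] | None = None,
) -> pd.DataFrame:
    """Full concordance report: one row per (outcome, medication class) plus
    a pooled "any" row per outcome."""
    if outcomes is None:
        outcomes = [o for o in Outcome if o in codelists]
    rows = []
    if cohort.n_children:
        for outcome in outcomes:
            status = code_status(cohort, codelists[outcome], outcome)
            for med in (*TABLE_CLASSES[outcome], "any"):
                t = build_two_by_two(cohort, status, outcome, med, criteria)
                rows.append(table_row(t, outcome, med, level, method))
    return pd.DataFrame(rows, columns=_COLUMNS)


def render_markdown(table: pd.DataFrame) -> str:
    """Human-readable markdown rendering of the concordance report."""
    lines = [
        "| Outcome | Medication | code+/rx+ | code−/rx+ | code+/rx− | code−/rx− "
        "| PPV (95% CI) | NPV (95% CI) |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for r in table.itertuples(index=False):
        lines.append(
            f"| {r.outcome} | {r.med_class} | {r.a} | {r.b} | {r.c} | {r.d} "
            f"| {r.ppv_fmt} | {r.npv_fmt} |"
        )
    return "\n".join(lines)
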