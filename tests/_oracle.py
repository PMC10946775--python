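"""Independent brute-force re-implementations used as oracles.

Everything here is written directly from the prose of the case
definitions with naive day-by-day loops, deliberately sharing no code
with the package, so agreement between the two is informative.
"""

from __future__ import annotations

import calendar
import datetime as dt

ASTHMA_RX = {"bronchodilator", "inhaled_corticosteroid",
             "leukotriene_receptor_antagonist"}
ECZEMA_RX = {"topical_corticosteroid", "emollient",
             "topical_calcineurin_inhibitor", "systemic_corticosteroid",
             "immunoregulator"}
RHINITIS_RX = {"antihistamine", "intranasal_corticosteroid"}


def age_by_day_count(dob: dt.date, on: dt.date) -> int:
    """Walk every day from dob to `on`, counting anniversary days
    (Feb-29 birthdays anniversary on Mar 1 in non-leap years)."""
    assert on >= dob
    age = 0
    day = dob + dt.timedelta(days=1)
    while day <= on:
        if dob.month == 2 and dob.day == 29 and not calendar.isleap(day.year):
            hit = (day.month, day.day) == (3, 1)
        else:
            hit = (day.month, day.day) == (dob.month, dob.day)
        if hit:
            age += 1
        day += dt.timedelta(days=1)
    return age


def season_day_set() -> set[tuple[int, int]]:
    """Explicit enumeration of the hay-fever season (month, day) pairs,
    built by walking a leap year so Feb 29 exists."""
    days = set()
    day = dt.date(2012, 1, 1)
    while day.year == 2012:
        if dt.date(2012, 3, 1) <= day <= dt.date(2012, 7, 31):
            days.add((day.month, day.day))
        day += dt.timedelta(days=1)
    return days


_SEASON = season_day_set()


def in_season(d: dt.date) -> bool:
    return (d.month, d.day) in _SEASON


# ---------------------------------------------------------------------------
# the six classifiers, straight from the prose
# ---------------------------------------------------------------------------
# events: list of dates (already on the outcome codelist)
# rx: list of (date, class-name string)


def asthma_def1(dob, events, rx) -> bool:
    """Code at age >=6; or code at 3-5 plus >=3 asthma items in some
    age-year >=6 (classes pooled)."""
    if any(age_by_day_count(dob, d) >= 6 for d in events):
        return True
    if not any(3 <= age_by_day_count(dob, d) <= 5 for d in events):
        return False
    per_year: dict[int, int] = {}
    for d, cls in rx:
        if cls in ASTHMA_RX:
            k = age_by_day_count(dob, d)
            if k >= 6:
                per_year[k] = per_year.get(k, 0) + 1
    return any(v >= 3 for v in per_year.values())


def asthma_def2(dob, events, rx=()) -> bool:
    return any(age_by_day_count(dob, d) >= 3 for d in events)


def eczema_def1(dob, events, rx) -> bool:
    eligible = sorted(d for d in events if age_by_day_count(dob, d) >= 1)
    if not eligible:
        return False
    first = eligible[0]
    n = sum(
        1 for d, cls in rx
        if cls in ECZEMA_RX
        and first - dt.timedelta(days=90) <= d <= first + dt.timedelta(days=365)
    )
    return n >= 2


def eczema_def2(dob, events, rx=()) -> bool:
    return any(age_by_day_count(dob, d) >= 1 for d in events)


def rhinitis_def1(dob, events, rx=()) -> bool:
    return len(events) > 0


def rhinitis_def2(dob, events, rx) -> bool:
    has_code = any(in_season(d) for d in events)
    has_rx = any(cls in RHINITIS_RX and in_season(d) for d, cls in rx)
    return has_code and has_rx


ORACLES = {
    ("asthma", "def1"): asthma_def1,
    ("asthma", "def2"): asthma_def2,
    ("eczema", "def1"): eczema_def1,
    ("eczema", "def2"): eczema_def2,
    ("allergic_rhinitis", "def1"): rhinitis_def1,
    ("allergic_rhinitis", "def2"): rhinitis_def2,
}


def exact_ci_by_inversion(x: int, n: int, level: float = 0.95):
    """Clopper-Pearson bounds by direct numeric inversion of the binomial
    tail probabilities (bisection, no beta-distribution shortcut)."""
    from scipy.stats import binom

    alpha = 1 - level

    def solve(f, lo, hi):
        flo = f(lo)
        for _ in range(200):
            mid = (lo + hi) / 2
            fm = f(mid)
            if (fm < 0) == (flo < 0):
                lo, flo = mid, fm
            else:
                hi = mid
        return (lo + hi) / 2

    # lower bound: P(X >= x | p) = alpha/2 (sf increasing in p)
    lower = 0.0 if x == 0 else solve(
        lambda p: binom.sf(x - 1, n, p) - alpha / 2, 0.0, 1.0
    )
    # upper bound: P(X <= x | p) = alpha/2 (cdf decreasing in p)
    upper = 1.0 if x == n else solve(
        lambda p: binom.cdf(x, n, p) - alpha / 2, 0.0, 1.0
    )
    return lower, upper
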