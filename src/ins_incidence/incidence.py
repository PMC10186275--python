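"""Person-time-windowed incidence and its stratifications.

Incidence is expressed as cases per 100,000 children at risk per year:

    I = true_cases / children_at_risk * (12 / months) * 100,000

with a fixed census denominator (no mid-period interpolation).  Strata are
demographic (sex, age bands with half-open boundaries), pandemic period
(before/from March 2020), or exposure to a policy measure, where both the
cases and the calendar months of the observation window are partitioned by
whether the measure was in effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

from .correction import TrueCaseEstimate
from .registry import (
    CaseRecord,
    MeasureInterval,
    ObservationWindow,
    PopulationStratum,
    measure_in_effect,
)

__all__ = [
    "IncidenceEstimate",
    "ExposureSplit",
    "compute_incidence",
    "incidence_from_estimate",
    "stratify",
    "split_by_measure",
    "months_in_effect",
    "measure_age_floor",
    "measure_population",
    "COVID_BOUNDARY",
]

#: First day of the pandemic period: cases presenting on or after this date
#: count as "during" the Covid-19 pandemic.
COVID_BOUNDARY = date(2020, 3, 1)

STRATIFICATION_SCHEMES = ("sex", "age7", "age12", "covid_period")


@dataclass(frozen=True)
class IncidenceEstimate:
    """Incidence per 100,000 children/year over a stated window, with CI."""

    stratum_label: str
    true_cases: float
    children_at_risk: int
    months: float
    incidence: float
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class ExposureSplit:
    """Cases and person-time of one window partitioned by a policy measure."""

    measure_name: str
    months_exposed: float
    months_unexposed: float
    cases_exposed: int
    cases_unexposed: int


def compute_incidence(true_cases: float, children_at_risk: int, months: float) -> float:
    """Cases per 100,000 children per year.

    Annualises the corrected case count over ``months`` of observation and
    scales to a population of 100,000 children at risk.
    """
    if true_cases < 0:
        raise ValueError("true_cases must be non-negative")
    if children_at_risk <= 0:
        raise ValueError("children_at_risk must be positive")
    if months <= 0:
        raise ValueError("months must be positive")
    return true_cases / children_at_risk * (12.0 / months) * 100_000.0


def incidence_from_estimate(
    est: TrueCaseEstimate,
    children_at_risk: int,
    months: float,
    stratum_label: str = "all",
) -> IncidenceEstimate:
    """Propagate a corrected-count estimate to the incidence scale.

    The incidence transform is linear in the case count, so the Monte Carlo
    percentile interval maps directly onto the incidence scale.
    """
    scale = 1.0 / children_at_risk * (12.0 / months) * 100_000.0
    return IncidenceEstimate(
        stratum_label=stratum_label,
        true_cases=est.point,
        children_at_risk=children_at_risk,
        months=months,
        incidence=compute_incidence(est.point, children_at_risk, months),
        ci_low=est.ci_low * scale,
        ci_high=est.ci_high * scale,
    )


def _population_lookup(
    population: Sequence[PopulationStratum], label: str
) -> int:
    for s in population:
        if s.stratum_label == label:
            return s.children_at_risk
    raise KeyError(f"no population stratum labelled {label!r}")


def stratify(
    cases: Sequence[CaseRecord],
    population: Sequence[PopulationStratum],
    scheme: str,
) -> dict[str, tuple[int, int]]:
    """Partition cases (and denominators) by a stratification scheme.

    Returns a mapping ``stratum_label -> (case_count, children_at_risk)``.
    Age bands are half-open, e.g. ``under7`` is [1, 7) so a child aged
    exactly 7.0 belongs to ``7plus``.  The pandemic-period scheme splits at
    March 1st, 2020 and uses the whole population as denominator for both
    periods.
    """
    if scheme not in STRATIFICATION_SCHEMES:
        raise ValueError(f"scheme must be one of {STRATIFICATION_SCHEMES}, got {scheme!r}")

    if scheme == "sex":
        labels = {"boys": lambda c: c.sex == "male", "girls": lambda c: c.sex == "female"}
        denominators = {"boys": "boys", "girls": "girls"}
    elif scheme == "age7":
        labels = {"under7": lambda c: c.age_years < 7, "7plus": lambda c: c.age_years >= 7}
        denominators = {"under7": "under7", "7plus": "7plus"}
    elif scheme == "age12":
        labels = {"under12": lambda c: c.age_years < 12, "12plus": lambda c: c.age_years >= 12}
        denominators = {"under12": "under12", "12plus": "12plus"}
    else:  # covid_period
        labels = {
            "before": lambda c: c.presentation_date < COVID_BOUNDARY,
            "during": lambda c: c.presentation_date >= COVID_BOUNDARY,
        }
        denominators = {"before": "all", "during": "all"}

    out: dict[str, tuple[int, int]] = {}
    for label, pred in labels.items():
        n = sum(1 for c in cases if pred(c))
        out[label] = (n, _population_lookup(population, denominators[label]))
    assert sum(n for n, _ in out.values()) == len(cases), "strata must partition the cases"
    return out


def months_in_effect(
    calendar: Sequence[MeasureInterval],
    measure_name: str,
    window: ObservationWindow,
    month_threshold_days: int = 15,
    region: str | None = None,
) -> float:
    """Whole calendar months of the window during which a measure was in effect.

    A month counts as exposed when the measure was in effect on at least
    ``month_threshold_days`` of its days inside the window.  Age floors are
    ignored here: exposure person-time for an age-floored measure is taken
    over the age-restricted population, whose calendar is the same.
    """
    intervals = [
        m
        for m in calendar
        if m.measure_name == measure_name and (region is None or m.region == region)
    ]
    months = 0
    first = window.start.replace(day=1)
    cursor = first
    while cursor < window.end:
        nxt = (cursor.replace(day=28) + timedelta(days=4)).replace(day=1)
        days = 0
        day = max(cursor, window.start)
        stop = min(nxt, window.end)
        while day < stop:
            if any(m.start <= day < m.end for m in intervals):
                days += 1
            day += timedelta(days=1)
        if days >= month_threshold_days:
            months += 1
        cursor = nxt
    return float(months)


def split_by_measure(
    cases: Sequence[CaseRecord],
    calendar: Sequence[MeasureInterval],
    measure_name: str,
    window: ObservationWindow,
    month_threshold_days: int = 15,
    months_override: float | None = None,
    region: str | None = None,
) -> ExposureSplit:
    """Partition cases and window months by exposure to one policy measure.

    A case is exposed iff the measure was in effect on its presentation date
    (and, for age-floored measures, the child had reached the age floor).
    ``months_override`` injects an externally stated exposed-month total in
    place of the threshold-rule computation; the unexposed months are always
    the complement within the window.
    """
    if window.months <= 0:
        raise ValueError("window must span a positive number of months")
    has_intervals = any(
        m.measure_name == measure_name and (region is None or m.region == region)
        for m in calendar
    )
    if has_intervals:
        exposed = sum(
            1
            for c in cases
            if measure_in_effect(
                calendar, measure_name, c.presentation_date, c.age_years, region
            )
        )
    else:
        exposed = 0  # empty calendar: the measure was never in effect
    if months_override is not None:
        m_exp = float(months_override)
    else:
        m_exp = months_in_effect(calendar, measure_name, window, month_threshold_days, region)
    if not 0 <= m_exp <= window.months:
        raise ValueError("exposed months must lie within the observation window")
    return ExposureSplit(
        measure_name=measure_name,
        months_exposed=m_exp,
        months_unexposed=window.months - m_exp,
        cases_exposed=exposed,
        cases_unexposed=len(cases) - exposed,
    )


def measure_age_floor(
    calendar: Sequence[MeasureInterval],
    measure_name: str,
    region: str | None = None,
) -> float | None:
    """Lowest age floor of a measure's intervals, or None when unrestricted."""
    floors = {
        m.age_floor
        for m in calendar
        if m.measure_name == measure_name and (region is None or m.region == region)
    }
    floors.discard(None)
    return min(floors) if floors else None


def measure_population(
    population: Sequence[PopulationStratum],
    calendar: Sequence[MeasureInterval],
    measure_name: str,
    region: str | None = None,
) -> int:
    """Denominator for a measure: the age-floored population when applicable.

    A measure applying only from, say, age 12 contributes person-time only in
    the >= 12 population, so its incidence denominator is that stratum.
    """
    floors = {
        m.age_floor
        for m in calendar
        if m.measure_name == measure_name and (region is None or m.region == region)
    }
    floors.discard(None)
    if not floors:
        return _population_lookup(population, "all")
    floor = min(floors)
    label = {12.0: "12plus", 6.0: "6plus"}.get(float(floor))
    if label is None:
        raise KeyError(f"no population stratum for age floor {floor}")
    return _population_lookup(population, label)
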