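"""Data model and I/O for case registries, denominators, surveys, and measure calendars.

The registry layer defines the vocabulary of the whole pipeline:

* :class:`CaseRecord` — one incident case of childhood idiopathic nephrotic
  syndrome (INS), identified by presentation date, age, sex, and reporting
  hospital.
* :class:`PopulationStratum` — the population at risk (children aged 1-16
  years) for one demographic stratum, fixed at a census date.
* :class:`ResponseSurvey` — how many hospitals were surveyed and how many
  responded; the response rate is the reporting probability used downstream
  for under-reporting correction.
* :class:`MeasureInterval` — a dated interval during which a policy measure
  (school closure, lockdown, mask mandate, ...) was in effect, optionally
  restricted to children above an age floor.
* :class:`ObservationWindow` — the study window over which person-time is
  accumulated.

All calendar intervals are half-open ``[start, end)``.  CSV schemas are
comma-separated UTF-8 with ISO-8601 dates and a mandatory header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CaseRecord",
    "PopulationStratum",
    "ResponseSurvey",
    "MeasureInterval",
    "ObservationWindow",
    "read_cases",
    "write_cases",
    "read_population",
    "write_population",
    "read_survey",
    "write_survey",
    "read_measures",
    "write_measures",
    "validate_calendar",
    "measure_in_effect",
]

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

#: Recognised stratum labels for the population-at-risk table.  ``6plus`` is an
#: extension used for mask mandates that applied from age 6.
STRATUM_LABELS = ("all", "boys", "girls", "under7", "7plus", "under12", "12plus", "6plus")


@dataclass(frozen=True, order=True)
class CaseRecord:
    """One incident INS case."""

    presentation_date: date
    age_years: float
    sex: str
    hospital_id: str
    region: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_years < 0:
            raise ValueError(f"age_years must be non-negative, got {self.age_years}")


@dataclass(frozen=True)
class PopulationStratum:
    """Children at risk in one stratum of a region at the census date."""

    region: str
    stratum_label: str
    children_at_risk: int
    census_date: date

    def __post_init__(self) -> None:
        if self.stratum_label not in STRATUM_LABELS:
            raise ValueError(
                f"stratum_label must be one of {STRATUM_LABELS}, got {self.stratum_label!r}"
            )
        if self.children_at_risk <= 0:
            raise ValueError("children_at_risk must be a positive integer")


@dataclass(frozen=True)
class ResponseSurvey:
    """Hospital survey ascertainment: units surveyed, units responding.

    ``response_rate`` is derived as ``units_responded / units_surveyed`` when
    not supplied explicitly; a supplied value wins (some cohorts report an
    effective rate that accounts for referral of cases from non-responding
    hospitals).
    """

    units_surveyed: int
    units_responded: int
    response_rate: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.units_surveyed < 1:
            raise ValueError("units_surveyed must be >= 1")
        if not 0 <= self.units_responded <= self.units_surveyed:
            raise ValueError("units_responded must lie in [0, units_surveyed]")
        if self.response_rate is None:
            object.__setattr__(
                self, "response_rate", self.units_responded / self.units_surveyed
            )
        if not 0 < self.response_rate <= 1:
            raise ValueError(f"response_rate must lie in (0, 1], got {self.response_rate}")


@dataclass(frozen=True)
class MeasureInterval:
    """A policy measure in effect over the half-open interval [start, end).

    ``age_floor`` restricts the measure to children of at least that age
    (mask mandates typically applied from age 12, later from age 6).
    """

    measure_name: str
    start: date
    end: date
    region: str
    age_floor: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start must precede end: {self.start} >= {self.end}")

    def contains(self, day: date, age_years: float | None = None) -> bool:
        if not self.start <= day < self.end:
            return False
        if self.age_floor is not None and age_years is not None:
            return age_years >= self.age_floor
        return True


@dataclass(frozen=True)
class ObservationWindow:
    """Study observation window [start, end) with its length in calendar months.

    ``months`` is derived at whole-month resolution from the endpoints when
    omitted, and may be overridden (some published person-time totals use
    half months).
    """

    start: date
    end: date
    months: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")
        if self.months is None:
            object.__setattr__(self, "months", float(whole_months(self.start, self.end)))
        if self.months <= 0:
            raise ValueError("window months must be positive")

    def contains(self, day: date) -> bool:
        return self.start <= day < self.end


def whole_months(start: date, end: date) -> int:
    """Number of whole calendar months spanned by [start, end)."""
    return (end.year - start.year) * 12 + (end.month - start.month)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CASE_COLUMNS = ["presentation_date", "age_years", "sex", "hospital_id", "region"]


def _parse_date(value, path: Path, row: int, column: str) -> date:
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"{path}, row {row}: malformed {column} {value!r}") from exc


def read_cases(
    path: str | Path,
    window: ObservationWindow | None = None,
    age_bounds: tuple[float, float] = (1.0, 17.0),
) -> list[CaseRecord]:
    """Read a case registry CSV, apply eligibility filters, drop exact duplicates.

    Eligibility keeps records with ``age_bounds[0] <= age < age_bounds[1]``
    and, when a window is given, a presentation date inside it.  Duplicate
    rows (identical on every case field) are removed, and the number of
    removals and filtered records is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty and not set(CASE_COLUMNS) <= set(df.columns):
        return []
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    records: list[CaseRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        day = _parse_date(row.presentation_date, path, i, "presentation_date")
        sex = str(row.sex).strip().lower()
        if sex not in SEXES:
            raise ValueError(f"{path}, row {i}: invalid sex {row.sex!r}")
        try:
            age = float(row.age_years)
        except ValueError as exc:
            raise ValueError(f"{path}, row {i}: malformed age_years {row.age_years!r}") from exc
        records.append(
            CaseRecord(day, age, sex, str(row.hospital_id), str(row.region))
        )

    n_raw = len(records)
    deduped = list(dict.fromkeys(records))
    n_dup = n_raw - len(deduped)

    lo, hi = age_bounds
    kept = [
        r
        for r in deduped
        if lo <= r.age_years < hi and (window is None or window.contains(r.presentation_date))
    ]
    logger.info(
        "read_cases(%s): %d rows, %d duplicates removed, %d ineligible, %d kept",
        path, n_raw, n_dup, len(deduped) - len(kept), len(kept),
    )
    return kept


def write_cases(cases: Iterable[CaseRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "presentation_date": c.presentation_date.isoformat(),
                "age_years": c.age_years,
                "sex": c.sex,
                "hospital_id": c.hospital_id,
                "region": c.region,
            }
            for c in cases
        ],
        columns=CASE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_population(path: str | Path) -> list[PopulationStratum]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        out.append(
            PopulationStratum(
                region=str(row.region),
                stratum_label=str(row.stratum_label),
                children_at_risk=int(row.children_at_risk),
                census_date=_parse_date(row.census_date, path, i, "census_date"),
            )
        )
    return out


def write_population(strata: Iterable[PopulationStratum], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "region": s.region,
                "stratum_label": s.stratum_label,
                "children_at_risk": s.children_at_risk,
                "census_date": s.census_date.isoformat(),
            }
            for s in strata
        ]
    ).to_csv(path, index=False)


def read_survey(path: str | Path) -> dict[str, ResponseSurvey]:
    """Read the survey-response table; returns one ResponseSurvey per region."""
    df = pd.read_csv(Path(path))
    out: dict[str, ResponseSurvey] = {}
    for row in df.itertuples(index=False):
        rate = getattr(row, "response_rate", None)
        rate = float(rate) if rate is not None and not pd.isna(rate) else None
        out[str(row.region)] = ResponseSurvey(
            units_surveyed=int(row.units_surveyed),
            units_responded=int(row.units_responded),
            response_rate=rate,
        )
    return out


def write_survey(surveys: dict[str, ResponseSurvey], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "region": region,
                "units_surveyed": s.units_surveyed,
                "units_responded": s.units_responded,
                "response_rate": s.response_rate,
            }
            for region, s in surveys.items()
        ]
    ).to_csv(path, index=False)


def read_measures(path: str | Path) -> list[MeasureInterval]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    calendar = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        floor = getattr(row, "age_floor", None)
        floor = float(floor) if floor is not None and not pd.isna(floor) else None
        calendar.append(
            MeasureInterval(
                measure_name=str(row.measure_name),
                start=_parse_date(row.start, path, i, "start"),
                end=_parse_date(row.end, path, i, "end"),
                region=str(row.region),
                age_floor=floor,
            )
        )
    validate_calendar(calendar)
    return calendar


def write_measures(calendar: Iterable[MeasureInterval], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "region": m.region,
                "measure_name": m.measure_name,
                "start": m.start.isoformat(),
                "end": m.end.isoformat(),
                "age_floor": m.age_floor,
            }
            for m in calendar
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Calendar algebra
# ---------------------------------------------------------------------------


def validate_calendar(calendar: Sequence[MeasureInterval]) -> None:
    """Reject overlapping intervals for the same (region, measure) pair."""
    by_key: dict[tuple[str, str], list[MeasureInterval]] = {}
    for m in calendar:
        by_key.setdefault((m.region, m.measure_name), []).append(m)
    for (region, name), intervals in by_key.items():
        intervals = sorted(intervals, key=lambda m: m.start)
        for a, b in zip(intervals, intervals[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals for measure {name!r} in region {region!r}: "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )


def measure_in_effect(
    calendar: Sequence[MeasureInterval],
    measure_name: str,
    day: date,
    age_years: float | None = None,
    region: str | None = None,
) -> bool:
    """True iff ``measure_name`` is in effect on ``day`` for a child of that age.

    Intervals are half-open, so a measure is *not* in effect on its stored end
    date.  When the interval carries an age floor the child's age must reach it.
    """
    known = {m.measure_name for m in calendar if region is None or m.region == region}
    if measure_name not in known:
        raise KeyError(
            f"unknown measure {measure_name!r}; known measures: {sorted(known)}"
        )
    return any(
        m.contains(day, age_years)
        for m in calendar
        if m.measure_name == measure_name and (region is None or m.region == region)
    )
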