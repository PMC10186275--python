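"""Synthetic reconstructions of the two cohort registries.

The cohort studies publish only aggregate tables: total and stratified case
counts, population denominators, survey response, the measure calendar, and
exposure-partitioned person-time.  This module rebuilds *case-level*
registries that reproduce those aggregates exactly — every stratum margin
(sex, age bands, yearly totals, pandemic period) and every policy-exposure
count (school closures, lockdowns, mask mandates) — so the full pipeline can
be exercised end to end.  Individual dates, ages, and hospital assignments
within a stratum are synthetic: they are deterministic constructions, not
patient data, and carry no information beyond the published margins.

Two registries are provided:

* ``netherlands_registry()`` — nationwide Dutch cohort, 2018-2021 (48 months),
  128 cases, 89 surveyed paediatric wards, 90% effective survey response.
* ``paris_registry()`` — Paris-area cohort, 2017-2021 (60 months), 324 cases,
  34 hospitals, 100% response.

Exposure-month totals that the published tables state but that are not
derivable from a single day-count rule (e.g. 42/6 open/closed school months
in the Dutch cohort) are carried as ``month_overrides``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

from .registry import (
    CaseRecord,
    MeasureInterval,
    ObservationWindow,
    PopulationStratum,
    ResponseSurvey,
    validate_calendar,
    write_cases,
    write_measures,
    write_population,
    write_survey,
)

__all__ = ["RegionInputs", "netherlands_registry", "paris_registry", "write_fixture"]

_CENSUS = date(2021, 1, 1)

# ages cycled within a band keep rows distinct and the band margins exact
_AGE_CYCLES = {
    "u6": [1.5, 2.0, 3.0, 4.5, 5.0],
    "u7": [2.0, 3.5, 4.0, 5.5, 6.0],
    "6_7": [6.2, 6.5, 6.8],
    "7_12": [7.5, 8.0, 9.5, 10.0, 11.5],
    "12p": [12.5, 13.0, 14.5, 15.0, 16.0],
}


@dataclass(frozen=True)
class RegionInputs:
    """Everything the pipeline needs for one region."""

    region: str
    window: ObservationWindow
    cases: tuple[CaseRecord, ...]
    population: tuple[PopulationStratum, ...]
    survey: ResponseSurvey
    calendar: tuple[MeasureInterval, ...]
    #: measure_name -> exposed months as stated in the published person-time table
    month_overrides: dict[str, float] = field(default_factory=dict)
    #: comparison plan: ((scheme_a, stratum_a), (scheme_b, stratum_b))
    comparisons: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = ()


def _finalize(
    specs: list[tuple[date, str]],
    region: str,
    n_female: int,
    n_hospitals: int,
) -> tuple[CaseRecord, ...]:
    """Assign ages (band cycles), alternating sex up to the female margin,
    and cycling hospital ids; sorted by presentation date."""
    specs = sorted(specs, key=lambda s: s[0])
    band_counters: dict[str, int] = {}
    cases = []
    females = 0
    for i, (day, band) in enumerate(specs):
        cycle = _AGE_CYCLES[band]
        k = band_counters.get(band, 0)
        band_counters[band] = k + 1
        if i % 2 == 1 and females < n_female:
            sex = "female"
            females += 1
        else:
            sex = "male"
        cases.append(
            CaseRecord(
                presentation_date=day,
                age_years=cycle[k % len(cycle)],
                sex=sex,
                hospital_id=f"H{i % n_hospitals:03d}",
                region=region,
            )
        )
    assert females == n_female, "female margin not reachable with alternation"
    return tuple(cases)


def _block(
    specs: list[tuple[date, str]],
    year: int,
    month: int,
    bands: Sequence[str],
    days: Sequence[int] | None = None,
    start: int = 3,
    step: int = 3,
) -> None:
    for i, band in enumerate(bands):
        day = days[i] if days is not None else start + step * i
        specs.append((date(year, month, day), band))


# ---------------------------------------------------------------------------
# Netherlands, 2018-2021
# ---------------------------------------------------------------------------


def netherlands_registry() -> RegionInputs:
    """Dutch cohort reconstruction: 128 cases over 48 months.

    Margins reproduced: 80 boys / 48 girls; 84 under 7 / 44 at least 7;
    112 under 12 / 16 at least 12; yearly totals 40/29/28/31; 73 before /
    55 during the pandemic; 7 cases while schools were closed; 28 under any
    lockdown (5 / 19 / 4 across the three lockdowns); 4 cases aged >= 12
    while masks were mandatory in public buildings.
    """
    s: list[tuple[date, str]] = []

    # 2018 (40): twelve cases aged >=12 and twenty-eight aged 7-11
    counts_2018 = [4, 3, 4, 3, 3, 4, 3, 3, 4, 3, 3, 3]
    bands_2018 = ["12p"] * 12 + ["7_12"] * 28
    pos = 0
    for m, n in enumerate(counts_2018, start=1):
        _block(s, 2018, m, bands_2018[pos : pos + n])
        pos += n

    # 2019 (29) and Jan-Feb 2020 (4): all under 7
    for m, n in enumerate([3, 2, 3, 2, 2, 3, 2, 2, 3, 2, 2, 3], start=1):
        _block(s, 2019, m, ["u7"] * n)
    _block(s, 2020, 1, ["u7"] * 2)
    _block(s, 2020, 2, ["u7"] * 2)

    # pandemic period (55)
    _block(s, 2020, 4, ["u7"] * 3, days=[15, 18, 21])     # 1st lockdown, schools closed
    _block(s, 2020, 5, ["u7"] * 2, days=[3, 6])           # 1st lockdown, schools closed
    for m, n in [(7, 4), (8, 4), (9, 4), (10, 3), (11, 3)]:
        _block(s, 2020, m, ["u7"] * n)                    # summer/autumn 2020, no measures
    _block(s, 2020, 12, ["u7"], days=[20])                # 2nd lockdown, schools closed
    _block(s, 2021, 1, ["u7"], days=[20])                 # 2nd lockdown, schools closed
    _block(s, 2021, 3, ["12p"] + ["u7"] * 8)              # 2nd lockdown, schools reopened
    _block(s, 2021, 4, ["12p"] + ["u7"] * 7)              # 2nd lockdown tail
    _block(s, 2021, 5, ["u7"] * 2)
    _block(s, 2021, 6, ["u7"] * 2)
    _block(s, 2021, 9, ["u7"] * 2)
    _block(s, 2021, 10, ["u7"] * 2)
    _block(s, 2021, 11, ["12p"], days=[20])               # mask mandate back in force
    _block(s, 2021, 12, ["12p", "u7", "u7", "u7"], days=[19, 21, 23, 25])  # 3rd lockdown

    cases = _finalize(s, "NL", n_female=48, n_hospitals=89)

    population = tuple(
        PopulationStratum("NL", label, n, _CENSUS)
        for label, n in [
            ("all", 2_936_425),
            ("boys", 1_504_400),
            ("girls", 1_432_025),
            ("under7", 1_044_899),
            ("7plus", 1_891_526),
            ("under12", 1_971_304),
            ("12plus", 965_121),
        ]
    )
    # 80 of 89 wards responded; the effective rate is 0.90, accounting for
    # referral of cases from non-responding hospitals
    survey = ResponseSurvey(units_surveyed=89, units_responded=80, response_rate=0.90)

    calendar = (
        MeasureInterval("schools_closed", date(2020, 3, 16), date(2020, 6, 9), "NL"),
        MeasureInterval("schools_closed", date(2020, 12, 15), date(2021, 3, 1), "NL"),
        MeasureInterval("lockdown", date(2020, 3, 12), date(2020, 6, 2), "NL"),
        MeasureInterval("lockdown", date(2020, 12, 15), date(2021, 4, 29), "NL"),
        MeasureInterval("lockdown", date(2021, 12, 19), date(2022, 1, 10), "NL"),
        MeasureInterval("lockdown_1", date(2020, 3, 12), date(2020, 6, 2), "NL"),
        MeasureInterval("lockdown_2", date(2020, 12, 15), date(2021, 4, 29), "NL"),
        MeasureInterval("lockdown_3", date(2021, 12, 19), date(2022, 1, 10), "NL"),
        MeasureInterval("masks", date(2020, 12, 1), date(2021, 6, 27), "NL", age_floor=12.0),
        MeasureInterval("masks", date(2021, 11, 8), date(2022, 1, 1), "NL", age_floor=12.0),
    )
    validate_calendar(calendar)

    return RegionInputs(
        region="NL",
        window=ObservationWindow(date(2018, 1, 1), date(2022, 1, 1)),
        cases=cases,
        population=population,
        survey=survey,
        calendar=calendar,
        month_overrides={
            "schools_closed": 6.0,
            "lockdown": 12.0,
            "lockdown_1": 3.0,
            "lockdown_2": 7.0,
            "lockdown_3": 2.0,
            "masks": 11.0,
        },
        comparisons=(
            (("covid_period", "before"), ("covid_period", "during")),
            (("sex", "boys"), ("sex", "girls")),
            (("age7", "under7"), ("age7", "7plus")),
            (("age12", "under12"), ("age12", "12plus")),
            (("measure:lockdown", "unexposed"), ("measure:lockdown", "exposed")),
            (("measure:schools_closed", "unexposed"), ("measure:schools_closed", "exposed")),
            (("measure:masks", "unexposed"), ("measure:masks", "exposed")),
        ),
    )


# ---------------------------------------------------------------------------
# Paris area, 2017-2021
# ---------------------------------------------------------------------------


def paris_registry() -> RegionInputs:
    """Paris-area cohort reconstruction: 324 cases over 60 months.

    Margins reproduced: 215 boys / 109 girls; 246 under 7 / 78 at least 7;
    299 under 12 / 25 at least 12; 211 before / 113 during the pandemic;
    4 cases while schools were closed; 13 under lockdown (4 in the first,
    9 in the second); 7 cases aged >= 12 and 24 cases aged >= 6 while the
    respective mask mandates were in force.
    """
    s: list[tuple[date, str]] = []

    # before the pandemic: 65 (2017) + 59 (2018) + 69 (2019) + 18 (Jan-Feb 2020)
    pre_bands = ["12p"] * 18 + ["6_7"] * 30 + ["7_12"] * 39 + ["u6"] * 124
    pos = 0
    for year, counts in [
        (2017, [6, 5, 6, 5, 5, 6, 5, 5, 6, 5, 5, 6]),
        (2018, [5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 4]),
        (2019, [6, 6, 6, 6, 6, 6, 5, 6, 5, 6, 5, 6]),
        (2020, [9, 9]),
    ]:
        for m, n in enumerate(counts, start=1):
            _block(s, year, m, pre_bands[pos : pos + n])
            pos += n
    assert pos == 211

    # pandemic period (113)
    _block(s, 2020, 4, ["u6"] * 4, days=[8, 11, 14, 17])  # 1st lockdown, schools closed
    for m in (6, 7, 8, 9, 10):
        _block(s, 2020, m, ["u6"] * 6)                    # schools reopened
    _block(s, 2020, 11, ["u6"] * 5)                       # 2nd lockdown
    _block(s, 2020, 12, ["u6"] * 4, days=[3, 5, 7, 9])    # 2nd lockdown (until Dec 15)
    _block(s, 2020, 12, ["u6"] * 4, days=[17, 19, 21, 23])
    for m in (1, 2, 3):
        _block(s, 2021, m, ["u6"] * 6)
    for m, n in [(5, 6), (6, 6), (7, 3), (8, 3)]:
        _block(s, 2021, m, ["u6"] * n)
    # autumn 2021: masks mandatory from age 6 in public spaces and schools
    _block(s, 2021, 9, ["12p", "12p", "7_12", "7_12", "7_12", "7_12", "6_7", "u6"])
    _block(s, 2021, 10, ["12p", "12p", "7_12", "7_12", "7_12", "7_12", "6_7", "u6"])
    _block(s, 2021, 11, ["12p", "12p", "7_12", "7_12", "7_12", "6_7", "u6"])
    _block(s, 2021, 12, ["12p", "7_12", "7_12", "7_12", "u6", "u6", "u6"])

    cases = _finalize(s, "paris", n_female=109, n_hospitals=34)

    population = tuple(
        PopulationStratum("paris", label, n, _CENSUS)
        for label, n in [
            ("all", 2_516_400),
            ("boys", 1_280_466),
            ("girls", 1_235_934),
            ("under7", 957_252),
            ("7plus", 1_559_148),
            ("under12", 1_747_578),
            ("12plus", 771_822),
            ("6plus", 1_719_198),
        ]
    )
    survey = ResponseSurvey(units_surveyed=34, units_responded=34)  # 100% response

    calendar = (
        MeasureInterval("schools_closed", date(2020, 3, 17), date(2020, 5, 12), "paris"),
        MeasureInterval("schools_closed", date(2021, 4, 5), date(2021, 4, 27), "paris"),
        MeasureInterval("lockdown", date(2020, 3, 17), date(2020, 6, 3), "paris"),
        MeasureInterval("lockdown", date(2020, 10, 30), date(2020, 12, 16), "paris"),
        MeasureInterval("lockdown_1", date(2020, 3, 17), date(2020, 6, 3), "paris"),
        MeasureInterval("lockdown_2", date(2020, 10, 30), date(2020, 12, 16), "paris"),
        MeasureInterval(
            "masks_12plus", date(2020, 3, 17), date(2020, 5, 12), "paris", age_floor=12.0
        ),
        MeasureInterval(
            "masks_12plus", date(2020, 9, 1), date(2021, 12, 31), "paris", age_floor=12.0
        ),
        MeasureInterval(
            "masks_6plus", date(2021, 9, 1), date(2022, 1, 1), "paris", age_floor=6.0
        ),
    )
    validate_calendar(calendar)

    return RegionInputs(
        region="paris",
        window=ObservationWindow(date(2017, 1, 1), date(2022, 1, 1)),
        cases=cases,
        population=population,
        survey=survey,
        calendar=calendar,
        month_overrides={
            "schools_closed": 2.0,
            "lockdown": 3.5,
            "lockdown_1": 2.0,
            "lockdown_2": 1.5,
            "masks_12plus": 18.0,
            "masks_6plus": 14.0,
        },
        comparisons=(
            (("covid_period", "before"), ("covid_period", "during")),
            (("sex", "boys"), ("sex", "girls")),
            (("age7", "under7"), ("age7", "7plus")),
            (("age12", "under12"), ("age12", "12plus")),
            (("measure:lockdown", "unexposed"), ("measure:lockdown", "exposed")),
            (("measure:lockdown_1", "exposed"), ("measure:lockdown_2", "exposed")),
            (("measure:schools_closed", "unexposed"), ("measure:schools_closed", "exposed")),
            (("measure:masks_12plus", "unexposed"), ("measure:masks_12plus", "exposed")),
            (("measure:masks_6plus", "unexposed"), ("measure:masks_6plus", "exposed")),
        ),
    )


def write_fixture(inputs: RegionInputs, outdir) -> dict[str, str]:
    """Write the four CSV schemas for one region; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cases": outdir / "cases.csv",
        "population": outdir / "population.csv",
        "survey": outdir / "survey.csv",
        "measures": outdir / "measures.csv",
    }
    write_cases(inputs.cases, paths["cases"])
    write_population(inputs.population, paths["population"])
    write_survey({inputs.region: inputs.survey}, paths["survey"])
    write_measures(inputs.calendar, paths["measures"])
    return {k: str(v) for k, v in paths.items()}
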