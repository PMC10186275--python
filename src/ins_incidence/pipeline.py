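"""Report assembly: the full analysis for one region.

``analyze_region`` ties the stages together: for each stratification scheme
it corrects the reported count for survey non-response, runs the Monte Carlo
interval, converts to incidence per 100,000 child-years, and finally runs the
planned two-proportion comparisons.  ``run_pipeline`` is the same analysis
driven by a :class:`RunConfig` of file paths, writing ``report.json``,
``report.tsv`` and ``run.log``.

Rounding happens only at the presentation layer (TSV / console): incidences
to 2 decimals, corrected counts to the nearest integer (half-up), p-values to
3 decimals.  The JSON report keeps full precision.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import ComparisonResult, person_years, two_proportion_test
from .correction import DEFAULT_N_SIMS, mc_true_cases
from .fixtures import RegionInputs
from .incidence import (
    COVID_BOUNDARY,
    incidence_from_estimate,
    measure_age_floor,
    measure_population,
    split_by_measure,
    stratify,
)
from .registry import (
    ObservationWindow,
    read_cases,
    read_measures,
    read_population,
    read_survey,
    whole_months,
)

__all__ = ["RunConfig", "run_pipeline", "analyze_region", "load_inputs"]

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "region", "scheme", "stratum", "reported", "true_point", "ci_low", "ci_high",
    "population", "months", "incidence", "incidence_ci_low", "incidence_ci_high",
]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RunConfig:
    """File-driven pipeline configuration."""

    cases: str
    population: str
    survey: str
    measures: str
    region: str
    window_start: date
    window_end: date
    out_dir: str | None = None
    n_sims: int = DEFAULT_N_SIMS
    seed: int = 20180101
    schemes: tuple[str, ...] = ("covid_period", "sex", "age7", "age12")
    #: measure_name -> exposed-months override (None = derive from calendar)
    month_overrides: dict[str, float | None] = field(default_factory=dict)
    window_months: float | None = None

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


def load_inputs(config: RunConfig) -> RegionInputs:
    window = ObservationWindow(
        config.window_start, config.window_end, months=config.window_months
    )
    cases = [
        c for c in read_cases(config.cases, window) if c.region == config.region
    ]
    population = tuple(
        s for s in read_population(config.population) if s.region == config.region
    )
    surveys = read_survey(config.survey)
    if config.region not in surveys:
        raise KeyError(f"no survey row for region {config.region!r}")
    calendar = tuple(
        m for m in read_measures(config.measures) if m.region == config.region
    )
    overrides = {
        name: months
        for name, months in config.month_overrides.items()
        if months is not None
    }
    measure_names = sorted({m.measure_name for m in calendar})
    for name in config.month_overrides:
        if name not in measure_names:
            raise KeyError(f"override for unknown measure {name!r}")
    plan = []
    scheme_pairs = {
        "covid_period": ("before", "during"),
        "sex": ("boys", "girls"),
        "age7": ("under7", "7plus"),
        "age12": ("under12", "12plus"),
    }
    for scheme in config.schemes:
        a, b = scheme_pairs[scheme]
        plan.append(((scheme, a), (scheme, b)))
    for name in measure_names:
        plan.append(((f"measure:{name}", "unexposed"), (f"measure:{name}", "exposed")))
    return RegionInputs(
        region=config.region,
        window=window,
        cases=tuple(cases),
        population=population,
        survey=surveys[config.region],
        calendar=calendar,
        month_overrides=overrides,
        comparisons=tuple(plan),
    )


def _row_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def analyze_region(
    inputs: RegionInputs,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 20180101,
    schemes: tuple[str, ...] = ("covid_period", "sex", "age7", "age12"),
) -> dict:
    """Run the full analysis for one region; returns the report dict.

    The report contains one row per stratum (overall, each scheme, and each
    measure's exposed/unexposed split) and one entry per planned comparison.
    Comparisons use rounded corrected counts over annualised person-time.
    Deterministic given ``seed``.
    """
    window = inputs.window
    survey = inputs.survey
    pop_all = next(
        s.children_at_risk for s in inputs.population if s.stratum_label == "all"
    )
    rows: list[dict] = []

    def add_row(scheme: str, stratum: str, reported: int, population: int, months: float):
        est = mc_true_cases(reported, survey, n_sims=n_sims, seed=_row_seed(seed, len(rows)))
        inc = incidence_from_estimate(est, population, months, stratum_label=stratum)
        rows.append(
            {
                "region": inputs.region,
                "scheme": scheme,
                "stratum": stratum,
                "reported": reported,
                "true_point": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "population": population,
                "months": months,
                "incidence": inc.incidence,
                "incidence_ci_low": inc.ci_low,
                "incidence_ci_high": inc.ci_high,
            }
        )

    add_row("overall", "all", len(inputs.cases), pop_all, window.months)

    for scheme in schemes:
        strata = stratify(inputs.cases, inputs.population, scheme)
        if scheme == "covid_period":
            before_months = float(whole_months(window.start, min(COVID_BOUNDARY, window.end)))
            months_by = {"before": before_months, "during": window.months - before_months}
        else:
            months_by = {label: window.months for label in strata}
        for label, (n, pop) in strata.items():
            add_row(scheme, label, n, pop, months_by[label])

    measure_names = sorted({m.measure_name for m in inputs.calendar})
    for name in measure_names:
        # an age-floored measure (e.g. a mask mandate from age 12) is analysed
        # within the age-restricted cases and population only
        floor = measure_age_floor(inputs.calendar, name, inputs.region)
        eligible = tuple(
            c for c in inputs.cases if floor is None or c.age_years >= floor
        )
        split = split_by_measure(
            eligible,
            inputs.calendar,
            name,
            window,
            months_override=inputs.month_overrides.get(name),
            region=inputs.region,
        )
        pop = measure_population(inputs.population, inputs.calendar, name, inputs.region)
        for stratum, n, months in (
            ("exposed", split.cases_exposed, split.months_exposed),
            ("unexposed", split.cases_unexposed, split.months_unexposed),
        ):
            if months <= 0:
                # no person-time accrued on this side of the split
                logger.warning(
                    "measure %s: %s side has zero months in the window; row skipped",
                    name, stratum,
                )
                continue
            add_row(f"measure:{name}", stratum, n, pop, months)

    by_key = {(r["scheme"], r["stratum"]): r for r in rows}
    comparisons = []
    for (key_a, key_b) in inputs.comparisons:
        if key_a not in by_key or key_b not in by_key:
            logger.warning("comparison %s vs %s skipped: missing row", key_a, key_b)
            continue
        a, b = by_key[key_a], by_key[key_b]
        result = two_proportion_test(
            cases_a=round_half_up(a["true_point"]),
            persons_a=person_years(a["population"], a["months"]),
            cases_b=round_half_up(b["true_point"]),
            persons_b=person_years(b["population"], b["months"]),
            label_a=f"{key_a[0]}/{key_a[1]}",
            label_b=f"{key_b[0]}/{key_b[1]}",
        )
        comparisons.append(result)

    logger.info(
        "analyze_region(%s): %d cases, %d rows, %d comparisons, n_sims=%d, seed=%d",
        inputs.region, len(inputs.cases), len(rows), len(comparisons), n_sims, seed,
    )
    return {
        "region": inputs.region,
        "window": {
            "start": window.start.isoformat(),
            "end": window.end.isoformat(),
            "months": window.months,
        },
        "n_cases": len(inputs.cases),
        "response_rate": survey.response_rate,
        "n_sims": n_sims,
        "seed": seed,
        "rows": rows,
        "comparisons": [
            {
                "a": c.label_a,
                "b": c.label_b,
                "cases_a": c.cases_a,
                "cases_b": c.cases_b,
                "persons_a": c.persons_a,
                "persons_b": c.persons_b,
                "z": c.z,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for c in comparisons
        ],
    }


def report_to_tsv(report: dict) -> pd.DataFrame:
    """Tidy presentation table: incidences at 2 d.p., counts as integers."""
    df = pd.DataFrame(report["rows"], columns=TSV_COLUMNS)
    for col in ("incidence", "incidence_ci_low", "incidence_ci_high"):
        df[col] = df[col].round(2)
    for col in ("true_point", "ci_low", "ci_high"):
        df[col] = df[col].map(round_half_up)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Load inputs, analyse, and (optionally) write report files.

    Writes ``report.json`` (full precision), ``report.tsv`` (presentation
    rounding) and ``run.log`` into ``config.out_dir`` when set.  Partial
    outputs are removed if a stage fails.  Re-running with the same config
    and seed reproduces byte-identical files.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    handler = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("ins_incidence").addHandler(handler)
        logging.getLogger("ins_incidence").setLevel(logging.INFO)
    try:
        inputs = load_inputs(config)
        report = analyze_region(
            inputs, n_sims=config.n_sims, seed=config.seed, schemes=config.schemes
        )
        if out_dir is not None:
            (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
            report_to_tsv(report).to_csv(out_dir / "report.tsv", sep="\t", index=False)
        return report
    except Exception:
        if out_dir is not None:
            for name in ("report.json", "report.tsv"):
                (out_dir / name).unlink(missing_ok=True)
        raise
    finally:
        if handler is not None:
            logging.getLogger("ins_incidence").removeHandler(handler)
            handler.close()
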