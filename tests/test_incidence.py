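"""Incidence computation, stratification, and exposure splits."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ins_incidence.correction import mc_true_cases
from ins_incidence.incidence import (
    compute_incidence,
    incidence_from_estimate,
    split_by_measure,
    stratify,
)
from ins_incidence.registry import (
    MeasureInterval,
    ObservationWindow,
    ResponseSurvey,
)
from ins_incidence.synthdata import SimulationConfig, simulate_registry


class TestComputeIncidence:
    @pytest.mark.parametrize(
        "true_cases,pop,months,expected",
        [
            (128 / 0.9, 2_936_425, 48, 1.21),  # Dutch cohort overall
            (324, 2_516_400, 60, 2.58),        # Paris cohort overall
            (0, 1_000_000, 12, 0.0),
        ],
    )
    def test_published_overall_incidences(self, true_cases, pop, months, expected):
        assert round(compute_incidence(true_cases, pop, months), 2) == expected

    @pytest.mark.parametrize("pop,months", [(0, 12), (-5, 12), (1000, 0), (1000, -1)])
    def test_nonpositive_denominators_rejected(self, pop, months):
        with pytest.raises(ValueError):
            compute_incidence(10, pop, months)

    def test_zero_iff_zero_cases(self):
        assert compute_incidence(0, 100, 12) == 0.0
        assert compute_incidence(0.1, 100, 12) > 0.0

    @settings(deadline=None, max_examples=50)
    @given(
        cases=st.floats(0.1, 1e4),
        pop=st.integers(1_000, 10_000_000),
        months=st.floats(1, 120),
        scale=st.floats(0.1, 10),
    )
    def test_homogeneity_in_cases_and_months(self, cases, pop, months, scale):
        """Incidence is degree 1 in cases and degree -1 in observation time."""
        base = compute_incidence(cases, pop, months)
        assert compute_incidence(cases * scale, pop, months) == pytest.approx(base * scale)
        assert compute_incidence(cases, pop, months * scale) == pytest.approx(base / scale)

    def test_interval_propagates_linearly(self):
        est = mc_true_cases(50, ResponseSurvey(89, 80, response_rate=0.9), seed=2)
        inc = incidence_from_estimate(est, 1_000_000, 24)
        scale = 12 / 24 / 1_000_000 * 100_000
        assert inc.ci_low == pytest.approx(est.ci_low * scale)
        assert inc.ci_high == pytest.approx(est.ci_high * scale)
        assert inc.incidence == pytest.approx(est.point * scale)


class TestStratify:
    def test_dutch_sex_margins(self, nl):
        out = stratify(nl.cases, nl.population, "sex")
        assert out["boys"] == (80, 1_504_400)
        assert out["girls"] == (48, 1_432_025)

    def test_paris_age7_margins(self, paris):
        out = stratify(paris.cases, paris.population, "age7")
        assert out["under7"][0] == 246
        assert out["7plus"][0] == 78

    def test_age_boundary_child_of_exactly_7_goes_to_7plus(self, nl):
        from ins_incidence.registry import CaseRecord

        case = CaseRecord(date(2019, 5, 1), 7.0, "male", "H1", "NL")
        out = stratify([case], nl.population, "age7")
        assert out["7plus"][0] == 1 and out["under7"][0] == 0

    @pytest.mark.parametrize("scheme", ["sex", "age7", "age12", "covid_period"])
    def test_partition_property(self, nl, paris, scheme):
        """Stratum counts partition the cases; sex strata partition the population."""
        for fix in (nl, paris):
            out = stratify(fix.cases, fix.population, scheme)
            assert sum(n for n, _ in out.values()) == len(fix.cases)
        all_pop = dict((s.stratum_label, s.children_at_risk) for s in nl.population)
        sex = stratify(nl.cases, nl.population, "sex")
        assert sex["boys"][1] + sex["girls"][1] == all_pop["all"]

    def test_unknown_scheme_rejected(self, nl):
        with pytest.raises(ValueError):
            stratify(nl.cases, nl.population, "postcode")


class TestSplitByMeasure:
    def test_dutch_school_closure_split(self, nl):
        split = split_by_measure(
            nl.cases, nl.calendar, "schools_closed", nl.window, months_override=6
        )
        assert split.cases_exposed == 7
        assert split.cases_unexposed == 121
        assert split.months_exposed == 6
        assert split.months_unexposed == 42

    def test_school_closure_months_derivable_without_override(self, nl):
        """The Dutch closure calendar yields the published 6 exposed months
        under the 15-day month rule even without an override."""
        split = split_by_measure(nl.cases, nl.calendar, "schools_closed", nl.window)
        assert split.months_exposed == 6.0

    def test_empty_calendar_means_never_exposed(self, nl):
        split = split_by_measure(nl.cases, [], "anything", nl.window)
        assert split.cases_exposed == 0
        assert split.months_exposed == 0.0
        assert split.cases_unexposed == len(nl.cases)

    def test_exposure_split_partitions_cases_and_months(self, nl, paris):
        for fix in (nl, paris):
            for name, override in fix.month_overrides.items():
                floor_free = [c for c in fix.cases]
                split = split_by_measure(
                    floor_free, fix.calendar, name, fix.window,
                    months_override=override, region=fix.region,
                )
                assert split.cases_exposed + split.cases_unexposed == len(floor_free)
                assert split.months_exposed + split.months_unexposed == fix.window.months

    def test_all_cases_inside_closure_leave_none_unexposed(self):
        """A registry simulated entirely inside a closure interval has no
        unexposed cases."""
        window = ObservationWindow(date(2020, 4, 1), date(2020, 6, 1))
        closure = MeasureInterval(
            "schools_closed", date(2020, 3, 1), date(2020, 7, 1), "synthetic"
        )
        config = SimulationConfig(
            window=window, base_rate=30.0, calendar=(closure,), seed=5
        )
        complete, _, _, _ = simulate_registry(config)
        assert len(complete) > 0
        split = split_by_measure(complete, [closure], "schools_closed", window)
        assert split.cases_unexposed == 0

    def test_override_outside_window_rejected(self, nl):
        with pytest.raises(ValueError):
            split_by_measure(
                nl.cases, nl.calendar, "schools_closed", nl.window, months_override=60
            )
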