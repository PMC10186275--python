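"""Registry data model, CSV I/O, and measure-calendar algebra."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ins_incidence.registry import (
    CaseRecord,
    MeasureInterval,
    ObservationWindow,
    ResponseSurvey,
    measure_in_effect,
    read_cases,
    validate_calendar,
    write_cases,
)

WINDOW = ObservationWindow(date(2018, 1, 1), date(2022, 1, 1))


def _write(tmp_path, text):
    path = tmp_path / "cases.csv"
    path.write_text(text)
    return path


class TestReadCases:
    HEADER = "presentation_date,age_years,sex,hospital_id,region\n"

    def test_age_filter_drops_infants(self, tmp_path):
        path = _write(
            tmp_path,
            self.HEADER
            + "2020-05-01,0.5,male,H1,NL\n"
            + "2020-05-02,3.0,female,H1,NL\n"
            + "2020-05-03,12.0,male,H2,NL\n",
        )
        assert len(read_cases(path, WINDOW)) == 2

    def test_eligibility_is_half_open_in_age(self, tmp_path):
        path = _write(
            tmp_path,
            self.HEADER
            + "2020-05-01,1.0,male,H1,NL\n"    # 1 year: included
            + "2020-05-02,16.9,male,H1,NL\n"   # under 17: included
            + "2020-05-03,17.0,male,H1,NL\n",  # 17: excluded
        )
        assert len(read_cases(path, WINDOW)) == 2

    def test_exact_duplicates_removed(self, tmp_path):
        row = "2020-05-01,3.0,male,H1,NL\n"
        path = _write(tmp_path, self.HEADER + row + row)
        assert len(read_cases(path, WINDOW)) == 1

    def test_window_filter(self, tmp_path):
        path = _write(
            tmp_path,
            self.HEADER + "2017-05-01,3.0,male,H1,NL\n" + "2020-05-01,3.0,male,H1,NL\n",
        )
        assert len(read_cases(path, WINDOW)) == 1

    def test_empty_file_gives_empty_collection(self, tmp_path):
        assert read_cases(_write(tmp_path, self.HEADER), WINDOW) == []

    @pytest.mark.parametrize(
        "bad_row", ["2020-13-45,3.0,male,H1,NL\n", "2020-05-01,3.0,robot,H1,NL\n"]
    )
    def test_malformed_row_names_the_row(self, tmp_path, bad_row):
        path = _write(tmp_path, self.HEADER + "2020-05-01,3.0,male,H1,NL\n" + bad_row)
        with pytest.raises(ValueError, match="row 3"):
            read_cases(path, WINDOW)


case_strategy = st.builds(
    CaseRecord,
    presentation_date=st.dates(date(2018, 1, 1), date(2021, 12, 31)),
    age_years=st.floats(1.0, 16.9).map(lambda x: round(x, 2)),
    sex=st.sampled_from(["male", "female"]),
    hospital_id=st.from_regex(r"H[0-9]{1,3}", fullmatch=True),
    region=st.just("NL"),
)


@settings(deadline=None, max_examples=25)
@given(st.lists(case_strategy, max_size=30, unique=True))
def test_roundtrip_write_then_read_is_identity(tmp_path_factory, cases):
    """Writing a valid registry and reading it back preserves every record."""
    path = tmp_path_factory.mktemp("rt") / "cases.csv"
    write_cases(cases, path)
    assert sorted(read_cases(path, WINDOW)) == sorted(cases)


class TestMeasureInEffect:
    CAL = [
        MeasureInterval("schools_closed", date(2020, 3, 16), date(2020, 6, 9), "NL"),
        MeasureInterval("masks", date(2020, 12, 1), date(2021, 6, 27), "NL", age_floor=12.0),
    ]

    def test_school_closure_covers_april_2020(self):
        assert measure_in_effect(self.CAL, "schools_closed", date(2020, 4, 1), 5.0)

    def test_interval_end_is_exclusive(self):
        assert measure_in_effect(self.CAL, "schools_closed", date(2020, 6, 8), 5.0)
        assert not measure_in_effect(self.CAL, "schools_closed", date(2020, 6, 9), 5.0)

    def test_mask_mandate_applies_only_from_age_floor(self):
        assert not measure_in_effect(self.CAL, "masks", date(2021, 1, 15), 5.0)
        assert measure_in_effect(self.CAL, "masks", date(2021, 1, 15), 13.0)

    def test_unknown_measure_lists_known_names(self):
        with pytest.raises(KeyError, match="masks.*schools_closed"):
            measure_in_effect(self.CAL, "curfew", date(2020, 4, 1), 5.0)

    def test_pure_function_of_inputs(self):
        args = (self.CAL, "schools_closed", date(2020, 4, 1), 5.0)
        assert measure_in_effect(*args) == measure_in_effect(*args)

    def test_overlapping_same_measure_rejected(self):
        cal = [
            MeasureInterval("schools_closed", date(2020, 3, 16), date(2020, 6, 9), "NL"),
            MeasureInterval("schools_closed", date(2020, 6, 1), date(2020, 7, 1), "NL"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            validate_calendar(cal)


class TestDomainTypes:
    def test_survey_rate_derived_from_counts(self):
        assert ResponseSurvey(34, 34).response_rate == 1.0
        assert ResponseSurvey(10, 9).response_rate == pytest.approx(0.9)

    def test_survey_explicit_rate_wins(self):
        # effective rate can differ from the raw fraction (referral of cases
        # from non-responding hospitals)
        assert ResponseSurvey(89, 80, response_rate=0.90).response_rate == 0.90

    def test_survey_rejects_excess_responses(self):
        with pytest.raises(ValueError):
            ResponseSurvey(10, 11)

    def test_interval_rejects_reversed_dates(self):
        with pytest.raises(ValueError):
            MeasureInterval("x", date(2020, 2, 1), date(2020, 1, 1), "NL")

    def test_window_months_derived_at_month_resolution(self):
        assert ObservationWindow(date(2018, 1, 1), date(2022, 1, 1)).months == 48
        assert ObservationWindow(date(2017, 1, 1), date(2022, 1, 1)).months == 60

    def test_case_record_rejects_invalid_sex(self):
        with pytest.raises(ValueError):
            CaseRecord(date(2020, 1, 1), 5.0, "unknown", "H1", "NL")


class TestCohortFixtures:
    def test_dutch_cohort_margins(self, nl):
        assert len(nl.cases) == 128
        assert sum(c.sex == "male" for c in nl.cases) == 80

    def test_paris_cohort_margins(self, paris):
        # 215 boys per the stratified incidence table (the cohort-description
        # table prints 216, inconsistent with its own girls count)
        assert len(paris.cases) == 324
        assert sum(c.sex == "male" for c in paris.cases) == 215

    def test_fixture_csv_roundtrip(self, nl, tmp_path):
        write_cases(nl.cases, tmp_path / "cases.csv")
        back = read_cases(tmp_path / "cases.csv", nl.window)
        assert sorted(back) == sorted(nl.cases)
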