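"""Cohort types, validation and CSV round-tripping."""

import pytest
from hypothesis import given, strategies as st

import graftsize as gs
from graftsize.cohort import complete_records

from conftest import make_measurements, make_record


def test_measurement_rejects_minor_above_major():
    with pytest.raises(ValueError, match="minor"):
        gs.TendonMeasurement.from_mm("ST", "R1", "t0", major_mm=3.0, minor_mm=3.2)


def test_measurement_rejects_off_grid_value():
    with pytest.raises(ValueError, match="quantized"):
        gs.TendonMeasurement.from_mm("ST", "R1", "t0", major_mm=4.05, minor_mm=3.0)


def test_mean_diameter_is_exact_at_two_decimals():
    m = gs.TendonMeasurement.from_mm("ST", "R1", "t0", 4.3, 3.2)
    assert m.mean_mm == 3.75


def test_duplicate_patient_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        gs.Cohort(records=(make_record("P1"), make_record("P1")))


class TestValidation:
    def test_valid_cohort_has_no_violations(self, two_patient_cohort):
        assert gs.validate_cohort(two_patient_cohort) == []

    def test_age_below_eighteen_flagged(self):
        cohort = gs.Cohort(records=(make_record(age=17),))
        violations = gs.validate_cohort(cohort)
        assert len(violations) == 1 and "age 17" in violations[0]

    def test_incomplete_measurements_flagged(self):
        r = make_record()
        short = gs.PatientRecord(
            patient_id=r.patient_id,
            age_years=r.age_years,
            sex=r.sex,
            side=r.side,
            actual_graft_mm=r.actual_graft_mm,
            measurements=r.measurements[:7],
        )
        violations = gs.validate_cohort(gs.Cohort(records=(short,)))
        assert len(violations) == 1 and "incomplete" in violations[0]

    def test_missing_actual_graft_flagged_not_fatal(self):
        cohort = gs.Cohort(records=(make_record(actual=None),))
        violations = gs.validate_cohort(cohort)
        assert len(violations) == 1 and "missing actual" in violations[0]

    def test_actual_out_of_range_flagged(self):
        cohort = gs.Cohort(records=(make_record(actual=14),))
        assert any("outside" in v for v in gs.validate_cohort(cohort))

    def test_violations_invariant_under_record_permutation(self):
        a = make_record("P1", age=17)
        b = make_record("P2", actual=4)
        fwd = gs.validate_cohort(gs.Cohort(records=(a, b)))
        rev = gs.validate_cohort(gs.Cohort(records=(b, a)))
        assert fwd == rev and len(fwd) == 2


class TestCsvRoundTrip:
    def test_two_row_file(self, two_patient_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        gs.write_cohort_csv(two_patient_cohort, path)
        back = gs.read_cohort_csv(path)
        assert back.records == two_patient_cohort.records

    def test_empty_cohort_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        gs.write_cohort_csv(gs.Cohort(records=()), path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("patient_id,")
        assert len(gs.read_cohort_csv(path)) == 0

    def test_missing_actual_round_trips_as_none(self, tmp_path):
        cohort = gs.Cohort(records=(make_record(actual=None),))
        path = tmp_path / "c.csv"
        gs.write_cohort_csv(cohort, path)
        assert gs.read_cohort_csv(path).records[0].actual_graft_mm is None

    def test_simulated_cohort_row_count(self, tmp_path):
        cohort = gs.simulate_cohort(gs.calibrated_default_config(seed=3))
        path = tmp_path / "sim.csv"
        gs.write_cohort_csv(cohort, path)
        rows = path.read_text().strip().splitlines()
        assert len(rows) == 1 + 92 * 8
        assert gs.read_cohort_csv(path).records == cohort.records

    @given(
        rows=st.lists(
            st.tuples(
                st.integers(20, 80),  # minor, tenths
                st.integers(0, 20),  # major - minor, tenths
                st.integers(5, 12),
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_round_trip_is_lossless_on_the_grid(self, rows, tmp_path_factory):
        records = tuple(
            make_record(
                patient_id=f"P{i}",
                actual=actual,
                st=((minor + extra) / 10, minor / 10),
                gt=((minor + extra) / 10, minor / 10),
            )
            for i, (minor, extra, actual) in enumerate(rows)
        )
        cohort = gs.Cohort(records=records)
        path = tmp_path_factory.mktemp("rt") / "c.csv"
        gs.write_cohort_csv(cohort, path)
        assert gs.read_cohort_csv(path).records == cohort.records


class TestCsvErrors:
    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,age_years\nP1,30\n")
        with pytest.raises(gs.SchemaError, match="missing required columns"):
            gs.read_cohort_csv(path)

    def test_invariant_violation_names_row(self, two_patient_cohort, tmp_path):
        path = tmp_path / "c.csv"
        gs.write_cohort_csv(two_patient_cohort, path)
        lines = path.read_text().splitlines()
        # corrupt data row 3: swap major/minor so minor > major
        parts = lines[3].split(",")
        parts[-2], parts[-1] = parts[-1], parts[-2]
        lines[3] = ",".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(gs.RowError, match="row 3"):
            gs.read_cohort_csv(path)

    def test_non_numeric_diameter_names_row(self, two_patient_cohort, tmp_path):
        path = tmp_path / "c.csv"
        gs.write_cohort_csv(two_patient_cohort, path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].rsplit(",", 1)[0] + ",abc"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(gs.RowError, match="row 2"):
            gs.read_cohort_csv(path)


def test_complete_records_reports_exclusions():
    full = make_record("P1")
    partial = gs.PatientRecord(
        patient_id="P2",
        age_years=30,
        sex=gs.Sex.F,
        side=gs.Side.RIGHT,
        actual_graft_mm=8,
        measurements=make_measurements()[:6],
    )
    kept, excluded = complete_records(gs.Cohort(records=(full, partial)))
    assert [r.patient_id for r in kept] == ["P1"]
    assert excluded == ["P2"]
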