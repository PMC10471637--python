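"""Cohort domain types, validation, and CSV input/output.

A cohort is a collection of patients scheduled for ACL reconstruction with a
doubled semitendinosus + gracilis (ST + GT) autograft.  For each patient we
hold demographics, the actual graft diameter recorded intraoperatively
(integer millimetres — the smallest tunnel the graft passes through), and the
tendon cross-section measurements taken on the pre-operative MRI: major (D)
and minor (d) diameters per tendon, per reader, per reading session.

Diameters are reported by the measuring workstation at 0.1-mm resolution.
To keep that grid exact, diameters are stored internally as integer tenths
of a millimetre and exposed as mm floats; all downstream arithmetic that
must be exact (tendon means, the predicted graft diameter) is done on the
integer representation.

The on-disk format is a long-format CSV, one measurement per row::

    patient_id,age_years,sex,side,actual_graft_mm,reader,session,tendon,major_mm,minor_mm

with sex in {M, F}, side in {left, right}, session in {t0, t1month} and
tendon in {ST, GT}.  Encoding is UTF-8, separator ",", decimal mark ".".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("graftsize")

#: Minimum patient age (years); younger patients are an exclusion criterion.
MIN_AGE_YEARS = 18
#: Plausible range for the intraoperative graft diameter, mm.
ACTUAL_GRAFT_RANGE_MM = (5, 12)
#: A complete record: 2 readers x 2 sessions x 2 tendons.
MEASUREMENTS_PER_COMPLETE_RECORD = 8

CSV_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "side",
    "actual_graft_mm",
    "reader",
    "session",
    "tendon",
    "major_mm",
    "minor_mm",
]


class Tendon(str, Enum):
    ST = "ST"
    GT = "GT"


class Session(str, Enum):
    T0 = "t0"
    T1MONTH = "t1month"


class Sex(str, Enum):
    M = "M"
    F = "F"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class CohortError(Exception):
    """Base class for cohort data errors."""


class SchemaError(CohortError):
    """The CSV file does not conform to the cohort schema."""


class RowError(CohortError):
    """A CSV row could not be parsed or violates a measurement invariant."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


def mm_to_tenths(value_mm: float, what: str = "diameter") -> int:
    """Convert a mm value on the 0.1-mm grid to integer tenths.

    Raises ValueError if the value does not sit on the grid (more than one
    decimal place), since the measuring workstation reports one decimal.
    """
    tenths = round(float(value_mm) * 10)
    if abs(float(value_mm) * 10 - tenths) > 1e-6:
        raise ValueError(f"{what} {value_mm} is not quantized to 0.1 mm")
    return int(tenths)


@dataclass(frozen=True)
class TendonMeasurement:
    """One reader's major/minor diameter pair for one tendon at one session."""

    tendon: Tendon
    reader: str
    session: Session
    major_tenths: int
    minor_tenths: int

    def __post_init__(self) -> None:
        if not (0 < self.minor_tenths <= self.major_tenths):
            raise ValueError(
                f"invalid diameters: minor {self.minor_tenths / 10} mm must be "
                f"positive and not exceed major {self.major_tenths / 10} mm"
            )

    @classmethod
    def from_mm(
        cls,
        tendon: Tendon | str,
        reader: str,
        session: Session | str,
        major_mm: float,
        minor_mm: float,
    ) -> "TendonMeasurement":
        return cls(
            tendon=Tendon(tendon),
            reader=str(reader),
            session=Session(session),
            major_tenths=mm_to_tenths(major_mm, "major_mm"),
            minor_tenths=mm_to_tenths(minor_mm, "minor_mm"),
        )

    @property
    def major_mm(self) -> float:
        return self.major_tenths / 10

    @property
    def minor_mm(self) -> float:
        return self.minor_tenths / 10

    @property
    def mean_tenths_x2(self) -> int:
        """major + minor in tenths: twice the mean diameter, exact."""
        return self.major_tenths + self.minor_tenths

    @property
    def mean_mm(self) -> float:
        """Mean diameter (D + d)/2 in mm; exact at two decimals."""
        return self.mean_tenths_x2 / 20


@dataclass(frozen=True)
class PatientRecord:
    """Demographics, actual graft diameter and all tendon measurements."""

    patient_id: str
    age_years: int
    sex: Sex
    side: Side
    actual_graft_mm: int | None
    measurements: tuple[TendonMeasurement, ...] = ()

    def find(
        self, tendon: Tendon, reader: str, session: Session
    ) -> TendonMeasurement | None:
        for m in self.measurements:
            if m.tendon is tendon and m.reader == reader and m.session is session:
                return m
        return None

    @property
    def readers(self) -> tuple[str, ...]:
        return tuple(sorted({m.reader for m in self.measurements}))

    @property
    def is_complete(self) -> bool:
        keys = {(m.tendon, m.reader, m.session) for m in self.measurements}
        return (
            len(self.measurements) == MEASUREMENTS_PER_COMPLETE_RECORD
            and len(keys) == MEASUREMENTS_PER_COMPLETE_RECORD
        )


@dataclass(frozen=True)
class Cohort:
    records: tuple[PatientRecord, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def record(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    @property
    def readers(self) -> tuple[str, ...]:
        return tuple(sorted({m.reader for r in self.records for m in r.measurements}))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_record(record: PatientRecord) -> list[str]:
    """Return human-readable violation descriptions for one record."""
    v: list[str] = []
    pid = record.patient_id
    if record.age_years < MIN_AGE_YEARS:
        v.append(f"{pid}: age {record.age_years} below minimum {MIN_AGE_YEARS}")
    lo, hi = ACTUAL_GRAFT_RANGE_MM
    if record.actual_graft_mm is None:
        v.append(f"{pid}: missing actual graft diameter (prediction-only record)")
    elif not (lo <= record.actual_graft_mm <= hi):
        v.append(
            f"{pid}: actual graft {record.actual_graft_mm} mm outside [{lo}, {hi}] mm"
        )
    n = len(record.measurements)
    if n != MEASUREMENTS_PER_COMPLETE_RECORD:
        v.append(
            f"{pid}: incomplete measurements ({n} of "
            f"{MEASUREMENTS_PER_COMPLETE_RECORD})"
        )
    else:
        keys = {(m.tendon, m.reader, m.session) for m in record.measurements}
        if len(keys) != MEASUREMENTS_PER_COMPLETE_RECORD:
            v.append(f"{pid}: duplicate (tendon, reader, session) measurements")
    return v


def validate_cohort(cohort: Cohort) -> list[str]:
    """Collect all invariant violations in the cohort.

    Violations are data, not exceptions: an empty list means every record is
    complete and satisfies the inclusion constraints.  The result is sorted,
    so it is invariant under permutation of the records.
    """
    violations: list[str] = []
    for record in cohort.records:
        violations.extend(validate_record(record))
    return sorted(violations)


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def _parse_row(row: pd.Series, row_index: int) -> tuple[dict, TendonMeasurement]:
    try:
        age = int(row["age_years"])
        sex = Sex(str(row["sex"]))
        side = Side(str(row["side"]))
        raw_actual = row["actual_graft_mm"]
        if pd.isna(raw_actual) or str(raw_actual).strip() == "":
            actual: int | None = None
        else:
            actual = int(float(raw_actual))
        measurement = TendonMeasurement.from_mm(
            tendon=str(row["tendon"]),
            reader=str(row["reader"]),
            session=str(row["session"]),
            major_mm=float(row["major_mm"]),
            minor_mm=float(row["minor_mm"]),
        )
    except (ValueError, KeyError) as exc:
        raise RowError(row_index, str(exc)) from exc
    patient_fields = {
        "patient_id": str(row["patient_id"]),
        "age_years": age,
        "sex": sex,
        "side": side,
        "actual_graft_mm": actual,
    }
    return patient_fields, measurement


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read a long-format cohort CSV.

    Rows are grouped by ``patient_id`` (order of first appearance is kept).
    Any row violating a measurement invariant or carrying inconsistent
    patient-level fields raises :class:`RowError` naming the offending row
    (1-based, excluding the header).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file without header") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    patients: dict[str, dict] = {}
    measurements: dict[str, list[TendonMeasurement]] = {}
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        fields, measurement = _parse_row(row, i)
        pid = fields["patient_id"]
        if pid not in patients:
            patients[pid] = fields
            measurements[pid] = []
        elif patients[pid] != fields:
            raise RowError(i, f"inconsistent patient-level fields for {pid!r}")
        measurements[pid].append(measurement)

    records = tuple(
        PatientRecord(measurements=tuple(measurements[pid]), **fields)
        for pid, fields in patients.items()
    )
    return Cohort(records=records, metadata={"source": str(path)})


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort in the long CSV format; exact round trip on re-read."""
    rows = []
    for r in cohort.records:
        for m in r.measurements:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "age_years": r.age_years,
                    "sex": r.sex.value,
                    "side": r.side.value,
                    "actual_graft_mm": "" if r.actual_graft_mm is None else r.actual_graft_mm,
                    "reader": m.reader,
                    "session": m.session.value,
                    "tendon": m.tendon.value,
                    "major_mm": f"{m.major_tenths / 10:.1f}",
                    "minor_mm": f"{m.minor_tenths / 10:.1f}",
                }
            )
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)


def complete_records(cohort: Cohort) -> tuple[list[PatientRecord], list[str]]:
    """Split records into complete ones and excluded patient ids.

    Exclusions are logged so no record is dropped silently.
    """
    kept: list[PatientRecord] = []
    excluded: list[str] = []
    for r in cohort.records:
        if r.is_complete:
            kept.append(r)
        else:
            excluded.append(r.patient_id)
            logger.info(
                "excluding %s: incomplete measurements (%d of %d)",
                r.patient_id,
                len(r.measurements),
                MEASUREMENTS_PER_COMPLETE_RECORD,
            )
    return kept, excluded
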