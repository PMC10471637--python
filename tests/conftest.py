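import hypothesis
import pytest

from graftsize import (
    Cohort,
    PatientRecord,
    Session,
    Sex,
    Side,
    Tendon,
    TendonMeasurement,
)

hypothesis.settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[hypothesis.HealthCheck.too_slow],
)
hypothesis.settings.load_profile("fixed")

READERS = ("R1", "R2")
SESSIONS = (Session.T0, Session.T1MONTH)


def make_measurements(st=(4.6, 4.0), gt=(3.4, 3.0), offsets=None):
    """Eight measurements (2 readers x 2 sessions x 2 tendons).

    ``offsets`` maps (reader, session) -> mm added to every diameter for
    that reading, to fabricate reader/session effects.
    """
    offsets = offsets or {}
    out = []
    for reader in READERS:
        for session in SESSIONS:
            delta = offsets.get((reader, session), 0.0)
            for tendon, (major, minor) in ((Tendon.ST, st), (Tendon.GT, gt)):
                out.append(
                    TendonMeasurement.from_mm(
                        tendon=tendon,
                        reader=reader,
                        session=session,
                        major_mm=round(major + delta, 1),
                        minor_mm=round(minor + delta, 1),
                    )
                )
    return tuple(out)


def make_record(
    patient_id="P001",
    age=30,
    sex=Sex.M,
    side=Side.LEFT,
    actual=8,
    st=(4.6, 4.0),
    gt=(3.4, 3.0),
    offsets=None,
):
    return PatientRecord(
        patient_id=patient_id,
        age_years=age,
        sex=sex,
        side=side,
        actual_graft_mm=actual,
        measurements=make_measurements(st=st, gt=gt, offsets=offsets),
    )


def record_with_prediction(patient_id, predicted_mm, actual_mm, offsets=None):
    """Noise-free record whose rounded prediction is exactly predicted_mm.

    Uses round tendons with raw PGD = predicted_mm - 0.1, which ceilings to
    predicted_mm.
    """
    gt_side = round(predicted_mm - 4.1, 1)
    return make_record(
        patient_id=patient_id,
        actual=actual_mm,
        st=(4.0, 4.0),
        gt=(gt_side, gt_side),
        offsets=offsets,
    )


@pytest.fixture
def two_patient_cohort():
    return Cohort(
        records=(
            make_record(patient_id="P001", actual=8),
            make_record(patient_id="P002", actual=7, st=(4.1, 3.7), gt=(3.1, 2.7)),
        ),
        metadata={"source": "fixture"},
    )


def engineered_cohort_78_8_6():
    """92 noise-free patients matching the published agreement breakdown.

    78 concordant, 8 under-predictions all by 1 mm (five 7-vs-8, three
    8-vs-9) and 6 over-predictions (five by 1 mm, one 9-vs-7 by 2 mm).
    """
    specs = []
    for size, count in ((6, 4), (7, 20), (8, 40), (9, 14)):  # 78 concordant
        specs += [(size, size)] * count
    specs += [(7, 8)] * 5 + [(8, 9)] * 3  # under
    specs += [(8, 7)] * 5 + [(9, 7)]  # over, one 2-mm case
    assert len(specs) == 92
    records = tuple(
        record_with_prediction(f"P{i + 1:03d}", pred, act)
        for i, (pred, act) in enumerate(specs)
    )
    return Cohort(records=records, metadata={"source": "engineered-78-8-6"})


@pytest.fixture
def cohort_78_8_6():
    return engineered_cohort_78_8_6()
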