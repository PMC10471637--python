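"""Predicted graft diameter (PGD) from MRI tendon measurements.

The prediction rule for a doubled semitendinosus + gracilis (ST + GT)
four-strand graft is

    PGD = (D_St + d_St) / 2 + (D_Gr + d_Gr) / 2

where D and d are the major and minor cross-sectional diameters of each
tendon on a transverse MRI slice, in mm at 0.1-mm resolution.  The raw PGD
is then rounded *up* to the next full millimetre: intraoperatively a graft
fits through a larger tunnel but not a smaller one, so the prediction must
never understate the tunnel needed.  An exact integer PGD is left unchanged
(a 7.00-mm graft fits a 7-mm tunnel).

Because the inputs carry one decimal, each tendon mean (D + d)/2 is exact at
two decimals and so is their sum; no intermediate rounding ever occurs.  All
arithmetic is done on integer hundredths of a millimetre.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

from .cohort import Cohort, PatientRecord, Session, Tendon, mm_to_tenths

logger = logging.getLogger("graftsize")

#: Default measurement set feeding the headline prediction.  The study
#: protocol does not designate whose reading produces the clinical
#: prediction; the first reader's baseline (t0) session is used unless the
#: caller chooses otherwise (see :func:`predict_cohort`).
DEFAULT_SESSION = Session.T0


@dataclass(frozen=True)
class GraftPrediction:
    """Per-tendon mean diameters and the raw / rounded predicted size.

    ``*_hundredths`` fields are the exact integer representation in
    hundredths of a mm; the ``*_mm`` properties expose conventional floats.
    """

    mean_st_hundredths: int
    mean_gt_hundredths: int
    pgd_rounded_mm: int

    @property
    def mean_st_mm(self) -> float:
        return self.mean_st_hundredths / 100

    @property
    def mean_gt_mm(self) -> float:
        return self.mean_gt_hundredths / 100

    @property
    def pgd_raw_hundredths(self) -> int:
        return self.mean_st_hundredths + self.mean_gt_hundredths

    @property
    def pgd_raw_mm(self) -> float:
        return self.pgd_raw_hundredths / 100


def mean_tendon_diameter(major_mm: float, minor_mm: float) -> float:
    """Mean diameter (D + d)/2 in mm, exact at two decimals.

    Inputs must sit on the 0.1-mm grid with 0 < minor <= major.
    """
    major_t = mm_to_tenths(major_mm, "major_mm")
    minor_t = mm_to_tenths(minor_mm, "minor_mm")
    if not (0 < minor_t <= major_t):
        raise ValueError(
            f"minor diameter {minor_mm} mm must be positive and not exceed "
            f"major diameter {major_mm} mm"
        )
    return (major_t + minor_t) * 5 / 100


def round_up_mm(x_mm: float) -> int:
    """Round a positive length up to the next full millimetre (ceiling).

    Exact integers map to themselves.  Values are snapped to the 0.01-mm
    grid first, so a float like 7.0000000001 arising from prior exact
    two-decimal arithmetic is treated as 7.00.
    """
    if x_mm <= 0:
        raise ValueError(f"length must be positive, got {x_mm}")
    hundredths = round(x_mm * 100)
    if abs(x_mm * 100 - hundredths) <= 1e-6:
        return -(-hundredths // 100)
    return math.ceil(x_mm)


def predicted_graft_diameter(
    st_major_mm: float,
    st_minor_mm: float,
    gt_major_mm: float,
    gt_minor_mm: float,
) -> GraftPrediction:
    """Apply the PGD rule to one set of four tendon diameters."""
    try:
        mean_st = mm_to_tenths(st_major_mm) + mm_to_tenths(st_minor_mm)
    except ValueError as exc:
        raise ValueError(f"ST: {exc}") from exc
    try:
        mean_gt = mm_to_tenths(gt_major_mm) + mm_to_tenths(gt_minor_mm)
    except ValueError as exc:
        raise ValueError(f"GT: {exc}") from exc
    if not (0 < mm_to_tenths(st_minor_mm) <= mm_to_tenths(st_major_mm)):
        raise ValueError(f"ST: minor {st_minor_mm} mm exceeds major {st_major_mm} mm or is non-positive")
    if not (0 < mm_to_tenths(gt_minor_mm) <= mm_to_tenths(gt_major_mm)):
        raise ValueError(f"GT: minor {gt_minor_mm} mm exceeds major {gt_major_mm} mm or is non-positive")
    mean_st_h = mean_st * 5  # (D + d)/2 in hundredths, exact
    mean_gt_h = mean_gt * 5
    raw_h = mean_st_h + mean_gt_h
    rounded = -(-raw_h // 100)  # ceiling on the integer hundredths grid
    return GraftPrediction(
        mean_st_hundredths=mean_st_h,
        mean_gt_hundredths=mean_gt_h,
        pgd_rounded_mm=int(rounded),
    )


def predict_record(
    record: PatientRecord, reader: str, session: Session
) -> GraftPrediction:
    """Prediction for one patient from one reader's session measurements."""
    st = record.find(Tendon.ST, reader, session)
    gt = record.find(Tendon.GT, reader, session)
    if st is None or gt is None:
        missing = [t.value for t, m in ((Tendon.ST, st), (Tendon.GT, gt)) if m is None]
        raise LookupError(
            f"{record.patient_id}: missing {'/'.join(missing)} measurement for "
            f"reader {reader!r} at session {session.value}"
        )
    return predicted_graft_diameter(
        st.major_mm, st.minor_mm, gt.major_mm, gt.minor_mm
    )


@dataclass(frozen=True)
class PredictionSet:
    """Predictions keyed by patient, plus explicitly reported exclusions."""

    predictions: Mapping[str, GraftPrediction]
    excluded: Mapping[str, str]  # patient_id -> reason

    def __len__(self) -> int:
        return len(self.predictions)


def predict_cohort(
    cohort: Cohort,
    reader: str | None = None,
    session: Session | str = DEFAULT_SESSION,
) -> PredictionSet:
    """Predict graft diameters for every record in the cohort.

    ``reader=None`` selects the first reader identifier in sorted order.
    Records lacking the required ST/GT measurements are reported in
    ``excluded`` (and logged), never silently dropped.
    """
    session = Session(session)
    if reader is None:
        readers = cohort.readers
        if not readers:
            raise ValueError("cohort contains no measurements")
        reader = readers[0]
    elif reader not in cohort.readers:
        raise ValueError(f"unknown reader {reader!r}; cohort has {cohort.readers}")

    predictions: dict[str, GraftPrediction] = {}
    excluded: dict[str, str] = {}
    for record in cohort.records:
        try:
            predictions[record.patient_id] = predict_record(record, reader, session)
        except LookupError as exc:
            excluded[record.patient_id] = str(exc)
            logger.info("prediction excluded: %s", exc)
    return PredictionSet(predictions=predictions, excluded=excluded)


def predict_cohort_consensus(
    cohort: Cohort, session: Session | str = DEFAULT_SESSION
) -> PredictionSet:
    """Predictions from the average of both readers' tendon means.

    Alternative reconciliation mode: each tendon's mean diameter is averaged
    across the two readers at the given session before summation and ceiling
    rounding.  Averaging two exact two-decimal means can produce a half
    hundredth; the average is kept exact internally (two-hundred-ths grid)
    so the ceiling is still exact.
    """
    session = Session(session)
    readers = cohort.readers
    if len(readers) < 2:
        raise ValueError("consensus prediction needs two readers")
    r1, r2 = readers[:2]
    predictions: dict[str, GraftPrediction] = {}
    excluded: dict[str, str] = {}
    for record in cohort.records:
        ms = [record.find(t, r, session) for t in (Tendon.ST, Tendon.GT) for r in (r1, r2)]
        if any(m is None for m in ms):
            excluded[record.patient_id] = (
                f"{record.patient_id}: missing measurements for consensus at "
                f"session {session.value}"
            )
            logger.info("prediction excluded: %s", excluded[record.patient_id])
            continue
        st1, st2, gt1, gt2 = ms
        # units of 1/200 mm: mean_tenths_x2 (tenths) * 10 / 2 per reader pair
        mean_st_200 = (st1.mean_tenths_x2 + st2.mean_tenths_x2) * 5
        mean_gt_200 = (gt1.mean_tenths_x2 + gt2.mean_tenths_x2) * 5
        raw_200 = mean_st_200 + mean_gt_200
        rounded = -(-raw_200 // 200)
        predictions[record.patient_id] = GraftPrediction(
            # consensus means may live on the half-hundredth grid; store the
            # nearest-hundredth representation only when exact, else carry
            # the exact value through doubled units by construction below.
            mean_st_hundredths=_halve_exact(mean_st_200),
            mean_gt_hundredths=_halve_exact(mean_gt_200),
            pgd_rounded_mm=int(rounded),
        )
    return PredictionSet(predictions=predictions, excluded=excluded)


def _halve_exact(units_200: int) -> int:
    """1/200-mm units to hundredths, rounding half to even when off-grid."""
    if units_200 % 2 == 0:
        return units_200 // 2
    # off the hundredth grid by half a unit; round half to even
    q, r = divmod(units_200, 4)
    return (units_200 + (1 if r == 3 else -1)) // 2
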