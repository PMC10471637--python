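"""Bland–Altman intra- and inter-reader reproducibility.

Reproducibility of the MRI tendon measurements is summarised per tendon by
Bland–Altman statistics on paired readings: the *bias* (mean of the paired
differences, a systematic offset) and the *coefficient of repeatability*
(CoR = 1.96 x SD of the differences — the value below which 95% of absolute
differences between repeated measurements are expected to fall, assuming
roughly normal differences).  Limits of agreement are bias +/- CoR.

The analysed quantity is each tendon's mean diameter (D + d)/2, matching
how the measurements feed the graft size prediction; a diagnostic mode for
major/minor diameters separately is available.

Pairings:

* intra-reader — the same reader at baseline (t0) vs one month later;
  differences oriented t0 - t1month;
* inter-reader — the two readers at the same session (t0 by default);
  differences oriented reader1 - reader2 (readers in sorted identifier
  order), so a positive bias means the first reader reads larger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .cohort import Cohort, Session, Tendon, complete_records

logger = logging.getLogger("graftsize")

#: Normal quantile used for the repeatability coefficient and limits of
#: agreement (95% of differences under normality).
LOA_FACTOR = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias_mm: float
    sd_diff_mm: float
    cor_mm: float
    loa_mm: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "bias_mm": self.bias_mm,
            "sd_diff_mm": self.sd_diff_mm,
            "cor_mm": self.cor_mm,
            "loa_mm": list(self.loa_mm),
        }


def bland_altman(
    series_a: Sequence[float], series_b: Sequence[float]
) -> BlandAltmanResult:
    """Bland–Altman statistics for position-paired measurement series.

    Differences are a - b; bias is their mean, sd the sample standard
    deviation (n-1 denominator), CoR = 1.96 x sd, limits of agreement
    bias +/- CoR.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"series must be 1-D and position-paired, got shapes {a.shape} and {b.shape}"
        )
    if a.size < 2:
        raise ValueError("Bland–Altman needs at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    cor = LOA_FACTOR * sd
    return BlandAltmanResult(
        n=int(a.size),
        bias_mm=bias,
        sd_diff_mm=sd,
        cor_mm=cor,
        loa_mm=(bias - cor, bias + cor),
    )


def bland_altman_pairs_frame(series_a, series_b):
    """Per-pair (mean, difference) columns for external BA plotting."""
    import pandas as pd

    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    return pd.DataFrame({"mean": (a + b) / 2, "difference": a - b})


Quantity = Literal["mean", "major", "minor"]


def _extract(record, tendon: Tendon, reader: str, session: Session, quantity: Quantity):
    m = record.find(tendon, reader, session)
    if m is None:
        return None
    if quantity == "mean":
        return m.mean_mm
    return m.major_mm if quantity == "major" else m.minor_mm


def reproducibility_report(
    cohort: Cohort,
    inter_session: Session | str = Session.T0,
    quantity: Quantity = "mean",
) -> dict[tuple[str, str], BlandAltmanResult]:
    """Four Bland–Altman analyses: {ST, GT} x {intra, inter}.

    Keys are (tendon value, "intra"|"inter").  Incomplete records are
    excluded with a logged count; the count is also stored under the
    ``"excluded"`` metadata key of the returned mapping via attribute
    ``excluded_n`` on the dict subclass returned.
    """
    inter_session = Session(inter_session)
    readers = cohort.readers
    if len(readers) < 2:
        raise ValueError("reproducibility needs two readers")
    r1, r2 = readers[:2]
    kept, excluded = complete_records(cohort)
    if excluded:
        logger.info("reproducibility: excluded %d incomplete records", len(excluded))

    results: dict[tuple[str, str], BlandAltmanResult] = {}
    for tendon in (Tendon.ST, Tendon.GT):
        intra_a = [_extract(r, tendon, r1, Session.T0, quantity) for r in kept]
        intra_b = [_extract(r, tendon, r1, Session.T1MONTH, quantity) for r in kept]
        inter_a = [_extract(r, tendon, r1, inter_session, quantity) for r in kept]
        inter_b = [_extract(r, tendon, r2, inter_session, quantity) for r in kept]
        results[(tendon.value, "intra")] = bland_altman(intra_a, intra_b)
        results[(tendon.value, "inter")] = bland_altman(inter_a, inter_b)
    results_with_meta = _ReproResults(results)
    results_with_meta.excluded_n = len(excluded)
    return results_with_meta


class _ReproResults(dict):
    excluded_n: int = 0
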