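"""Median/IQR summaries and the Wilcoxon signed-rank comparison.

Quantitative variables are summarised as median and interquartile range,
with quartiles computed by linear interpolation of order statistics (the
usual "type 7" convention).  The predicted and actual graft diameter
distributions are compared with the two-sided Wilcoxon signed-rank test on
the paired differences: zero differences are discarded (Wilcoxon's original
treatment; Pratt's method available) and ties are mid-ranked.  For small
samples the exact sign-flip null distribution is enumerated (valid with
tied absolute differences, since the distribution conditions on them);
larger samples use the normal approximation with tie and continuity
corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

#: Largest effective sample size for which the exact Wilcoxon null
#: distribution is enumerated (when no tied absolute differences exist).
EXACT_N_MAX = 25


@dataclass(frozen=True)
class SummaryStats:
    n: int
    median: float
    q1: float
    q3: float

    def as_dict(self) -> dict:
        return {"n": self.n, "median": self.median, "q1": self.q1, "q3": self.q3}


def median_iqr(values: Sequence[float]) -> SummaryStats:
    """Median and quartiles via linear interpolation of order statistics."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("median_iqr requires at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return SummaryStats(n=int(x.size), median=float(med), q1=float(q1), q3=float(q3))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int  # pairs remaining after zero-difference handling
    degenerate: bool  # all differences zero: no evidence against the null
    method: str

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_effective": self.n_effective,
            "degenerate": self.degenerate,
            "method": self.method,
        }


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float],
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    ``zero_method`` is ``"wilcox"`` (discard zero differences, the default)
    or ``"pratt"``.  If every difference is zero the outcome is flagged
    degenerate with p = 1: identical samples carry no evidence against the
    null, but no test statistic distribution exists either.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("samples must be 1-D and position-paired")
    if x.size < 1:
        raise ValueError("wilcoxon requires at least one pair")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    d = x - y
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return WilcoxonResult(
            statistic=0.0, p_value=1.0, n_effective=0, degenerate=True, method="degenerate"
        )
    if nonzero.size <= EXACT_N_MAX and zero_method == "wilcox":
        method = "exact"
    else:
        method = "approx"
    res = scipy.stats.wilcoxon(
        x,
        y,
        zero_method=zero_method,
        correction=(method == "approx"),
        alternative="two-sided",
        method="exact" if method == "exact" else "approx",
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_effective=int(nonzero.size),
        degenerate=False,
        method=method,
    )
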