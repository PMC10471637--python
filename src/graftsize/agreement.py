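"""Predicted-vs-actual graft size agreement statistics.

The predicted (rounded, integer mm) and actual (surgical-report, integer mm)
graft diameters for each patient form a pair of ordinal ratings.  Agreement
is summarised three ways:

* raw concordance — the fraction of exactly matching pairs — together with
  the under- and over-prediction fractions, each with an exact two-sided
  Clopper–Pearson binomial confidence interval (Wilson available as an
  option);
* linearly weighted Cohen's kappa over the integer millimetre grid, so a
  2-mm disagreement is penalised twice as much as a 1-mm one;
* a verbal interpretation band for kappa (McHugh scale), applied to kappa
  rounded to two decimals.

Percentages inside results carry full precision; rounding to integer
percent (half away from zero) happens only at display time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint


class AgreementClass(str, Enum):
    CONCORDANT = "concordant"
    UNDER = "under"  # predicted < actual
    OVER = "over"  # predicted > actual


def classify_prediction(predicted_mm: int, actual_mm: int) -> AgreementClass:
    """Classify one prediction against the intraoperative size."""
    if predicted_mm <= 0 or actual_mm <= 0:
        raise ValueError("graft diameters must be positive integers")
    if predicted_mm == actual_mm:
        return AgreementClass.CONCORDANT
    return AgreementClass.UNDER if predicted_mm < actual_mm else AgreementClass.OVER


def exact_binomial_ci(
    successes: int,
    n: int,
    level: float = 0.95,
    method: str = "clopper-pearson",
) -> tuple[float, float]:
    """Two-sided binomial confidence interval for a proportion.

    ``method`` is ``"clopper-pearson"`` (exact, the default) or ``"wilson"``.
    Returns (lower, upper) as proportions in [0, 1]; the lower bound is 0
    when ``successes == 0`` and the upper bound 1 when ``successes == n``.
    """
    if n < 1 or not (0 <= successes <= n):
        raise ValueError(f"counts out of range: {successes}/{n}")
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if method == "clopper-pearson":
        ci = binomtest(successes, n).proportion_ci(confidence_level=level, method="exact")
        return float(ci.low), float(ci.high)
    if method == "wilson":
        lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


class DegenerateAgreementError(ValueError):
    """Raised when kappa is undefined (expected disagreement is zero).

    This happens when both raters put all mass in a single category: chance
    agreement is already perfect and no chance-corrected coefficient exists.
    """


def weighted_kappa_linear(
    pairs: Sequence[tuple[int, int]],
    categories: Sequence[int] | None = None,
) -> float:
    """Linearly weighted Cohen's kappa for integer ordinal pairs.

    kappa_w = 1 - sum(w_ij O_ij) / sum(w_ij E_ij) with disagreement weights
    w_ij = |i - j| / (k - 1), O the observed joint frequency table and E the
    table expected from the product of the marginals.  By default the
    category grid is the consecutive integer range spanning the union of
    both ratings, so unobserved interior sizes still count toward distance.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("kappa requires at least two pairs")
    values = [v for p in pairs for v in p]
    if categories is None:
        categories = list(range(min(values), max(values) + 1))
    else:
        categories = list(categories)
        if any(v not in categories for v in values):
            raise ValueError("observed values outside the category grid")
    k = len(categories)
    if k == 1:
        raise DegenerateAgreementError(
            "all ratings in one category: kappa undefined"
        )
    index = {c: i for i, c in enumerate(categories)}
    observed = np.zeros((k, k))
    for a, b in pairs:
        observed[index[a], index[b]] += 1
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    idx = np.arange(k)
    weights = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    expected_disagreement = float((weights * expected).sum())
    if expected_disagreement == 0.0:
        raise DegenerateAgreementError(
            "expected disagreement is zero: kappa undefined"
        )
    return 1.0 - float((weights * observed).sum()) / expected_disagreement


#: Verbal interpretation bands (McHugh) on kappa rounded to two decimals.
KAPPA_BANDS = [
    (0.20, "None"),
    (0.39, "Minimal"),
    (0.59, "Weak"),
    (0.79, "Moderate"),
    (0.90, "Strong"),
    (1.00, "Almost Perfect"),
]


def kappa_band(kappa: float) -> str:
    """Verbal agreement label for a kappa value.

    Banding is applied to kappa rounded to two decimals, so e.g. 0.797
    becomes 0.80 and falls in the "Strong" (0.80-0.90) band.
    """
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    rounded = round(kappa, 2)
    for upper, label in KAPPA_BANDS:
        if rounded <= upper:
            return label
    return "Almost Perfect"


def round_percent(pct: float) -> int:
    """Round a percentage half away from zero to integer percent."""
    import math

    return int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))


@dataclass(frozen=True)
class AgreementResult:
    """Counts, percentages with exact CIs, and weighted kappa."""

    n: int
    n_concordant: int
    n_under: int
    n_over: int
    concordance_pct: float
    concordance_ci: tuple[float, float]  # percentages
    under_pct: float
    under_ci: tuple[float, float]
    over_pct: float
    over_ci: tuple[float, float]
    kappa: float | None
    kappa_band: str

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "n_concordant": self.n_concordant,
            "n_under": self.n_under,
            "n_over": self.n_over,
            "concordance_pct": self.concordance_pct,
            "concordance_ci_pct": list(self.concordance_ci),
            "under_pct": self.under_pct,
            "under_ci_pct": list(self.under_ci),
            "over_pct": self.over_pct,
            "over_ci_pct": list(self.over_ci),
            "kappa": self.kappa,
            "kappa_band": self.kappa_band,
        }


def agreement_summary(
    pairs: Sequence[tuple[int, int]],
    level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> AgreementResult:
    """Full agreement analysis of (predicted, actual) integer-mm pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("agreement_summary requires at least one pair")
    counts = Counter(classify_prediction(p, a) for p, a in pairs)
    n = len(pairs)
    n_conc = counts[AgreementClass.CONCORDANT]
    n_under = counts[AgreementClass.UNDER]
    n_over = counts[AgreementClass.OVER]

    def pct_ci(x: int) -> tuple[float, tuple[float, float]]:
        lo, hi = exact_binomial_ci(x, n, level=level, method=ci_method)
        return 100 * x / n, (100 * lo, 100 * hi)

    conc_pct, conc_ci = pct_ci(n_conc)
    under_pct, under_ci = pct_ci(n_under)
    over_pct, over_ci = pct_ci(n_over)

    try:
        kappa: float | None = weighted_kappa_linear(pairs) if n >= 2 else None
        band = kappa_band(kappa) if kappa is not None else "undefined (single pair)"
    except DegenerateAgreementError as exc:
        kappa = None
        band = f"undefined ({exc})"

    return AgreementResult(
        n=n,
        n_concordant=n_conc,
        n_under=n_under,
        n_over=n_over,
        concordance_pct=conc_pct,
        concordance_ci=conc_ci,
        under_pct=under_pct,
        under_ci=under_ci,
        over_pct=over_pct,
        over_ci=over_ci,
        kappa=kappa,
        kappa_band=band,
    )
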