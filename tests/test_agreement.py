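"""Agreement statistics: classification, exact CIs, weighted kappa."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import graftsize as gs
from graftsize import AgreementClass
from graftsize.agreement import round_percent


def brute_force_linear_kappa(pairs, categories):
    """Independent naive double-loop weighted kappa (test oracle)."""
    k = len(categories)
    idx = {c: i for i, c in enumerate(categories)}
    n = len(pairs)
    observed = [[0.0] * k for _ in range(k)]
    for a, b in pairs:
        observed[idx[a]][idx[b]] += 1
    row = [sum(observed[i][j] for j in range(k)) for i in range(k)]
    col = [sum(observed[i][j] for i in range(k)) for j in range(k)]
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = abs(i - j) / (k - 1)
            num += w * observed[i][j]
            den += w * row[i] * col[j] / n
    return 1.0 - num / den


@pytest.mark.parametrize(
    "pred, actual, expected",
    [
        (8, 8, AgreementClass.CONCORDANT),
        (7, 8, AgreementClass.UNDER),
        (9, 7, AgreementClass.OVER),
    ],
)
def test_classify_prediction(pred, actual, expected):
    assert gs.classify_prediction(pred, actual) is expected


class TestExactBinomialCi:
    def test_boundaries(self):
        lo0, _ = gs.exact_binomial_ci(0, 10)
        _, hi1 = gs.exact_binomial_ci(10, 10)
        assert lo0 == 0.0 and hi1 == 1.0

    def test_out_of_range_counts_rejected(self):
        with pytest.raises(ValueError):
            gs.exact_binomial_ci(5, 4)

    def test_wilson_option_also_matches_printed_concordance_interval(self):
        lo, hi = gs.exact_binomial_ci(78, 92, method="wilson")
        assert (round_percent(100 * lo), round_percent(100 * hi)) == (76, 91)

    @given(x=st.integers(0, 30), n=st.integers(1, 30))
    def test_99_interval_contains_95_interval(self, x, n):
        if x > n:
            return
        lo95, hi95 = gs.exact_binomial_ci(x, n, level=0.95)
        lo99, hi99 = gs.exact_binomial_ci(x, n, level=0.99)
        assert lo99 <= lo95 and hi99 >= hi95
        assert lo95 <= x / n <= hi95


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        pairs = [(7, 7)] * 5 + [(8, 8)] * 5
        assert gs.weighted_kappa_linear(pairs) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        pairs = [(7, 7)] * 5 + [(7, 8)] * 5 + [(8, 7)] * 5 + [(8, 8)] * 5
        assert gs.weighted_kappa_linear(pairs) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_2x2_is_one(self):
        pairs = [(6, 6)] * 10 + [(7, 7)] * 10
        assert gs.weighted_kappa_linear(pairs) == pytest.approx(1.0)

    def test_degenerate_single_category_flagged(self):
        with pytest.raises(gs.DegenerateAgreementError):
            gs.weighted_kappa_linear([(8, 8)] * 10)

    def test_values_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gs.weighted_kappa_linear([(6, 9), (7, 7)], categories=[6, 7, 8])

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(20240601)
        for _ in range(1000):
            lo = int(rng.integers(5, 9))
            span = int(rng.integers(1, 5))
            cats = list(range(lo, lo + span + 1))
            n = int(rng.integers(2, 21))
            pairs = [tuple(rng.choice(cats, size=2)) for _ in range(n)]
            values = {v for p in pairs for v in p}
            if len(values) < 2:
                continue
            ours = gs.weighted_kappa_linear(pairs)
            cats_used = list(range(min(values), max(values) + 1))
            oracle = brute_force_linear_kappa(pairs, cats_used)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_cross_check_against_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        cats = [6, 7, 8, 9, 10]
        pairs = [tuple(rng.choice(cats, size=2)) for _ in range(50)]
        ours = gs.weighted_kappa_linear(pairs, categories=cats)
        theirs = sklearn_metrics.cohen_kappa_score(
            [a for a, _ in pairs], [b for _, b in pairs],
            labels=cats, weights="linear",
        )
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_replacing_concordant_with_discordant_lowers_kappa(self):
        base = [(7, 7)] * 10 + [(8, 8)] * 10
        worse = base[:-1] + [(8, 7)]
        assert gs.weighted_kappa_linear(worse) < gs.weighted_kappa_linear(base)

    def test_invariant_under_spacing_preserving_relabel(self):
        pairs = [(6, 6), (6, 7), (7, 8), (8, 8), (8, 6), (7, 7)]
        shifted = [(a + 10, b + 10) for a, b in pairs]
        assert gs.weighted_kappa_linear(pairs) == pytest.approx(
            gs.weighted_kappa_linear(shifted)
        )


class TestKappaBand:
    @pytest.mark.parametrize(
        "kappa, label",
        [
            (0.797, "Strong"),  # rounds to 0.80 before banding
            (1.0, "Almost Perfect"),
            (0.50, "Weak"),
            (0.79, "Moderate"),
            (0.10, "None"),
            (-0.3, "None"),
            (0.91, "Almost Perfect"),
        ],
    )
    def test_bands(self, kappa, label):
        assert gs.kappa_band(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gs.kappa_band(1.2)


class TestAgreementSummary:
    def test_engineered_78_8_6_split(self):
        pairs = (
            [(7, 7)] * 40 + [(8, 8)] * 38  # 78 concordant
            + [(7, 8)] * 5 + [(8, 9)] * 3  # 8 under
            + [(8, 7)] * 5 + [(9, 7)]      # 6 over
        )
        res = gs.agreement_summary(pairs)
        assert (res.n, res.n_concordant, res.n_under, res.n_over) == (92, 78, 8, 6)
        assert round_percent(res.concordance_pct) == 85
        assert tuple(map(round_percent, res.concordance_ci)) == (76, 91)
        assert round_percent(res.under_pct) == 9
        assert tuple(map(round_percent, res.under_ci)) == (4, 16)
        assert tuple(map(round_percent, res.over_ci)) == (2, 14)
        assert res.kappa is not None and res.kappa <= 1

    def test_single_pair_flags_degenerate_kappa(self):
        res = gs.agreement_summary([(8, 8)])
        assert res.concordance_pct == 100.0
        assert res.kappa is None and "undefined" in res.kappa_band

    def test_counts_partition_n(self):
        rng = np.random.default_rng(3)
        pairs = [tuple(rng.integers(6, 11, size=2)) for _ in range(200)]
        res = gs.agreement_summary(pairs)
        assert res.n_concordant + res.n_under + res.n_over == res.n == 200

    def test_large_sample_concordance_near_probability(self):
        rng = np.random.default_rng(12)
        n = 1000
        p_equal = 0.85
        pairs = []
        for _ in range(n):
            a = int(rng.integers(6, 10))
            b = a if rng.random() < p_equal else a + rng.choice([-1, 1])
            pairs.append((int(b), a))
        res = gs.agreement_summary(pairs)
        se = 100 * np.sqrt(p_equal * (1 - p_equal) / n)
        assert abs(res.concordance_pct - 85.0) <= 3 * se

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gs.agreement_summary([])
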