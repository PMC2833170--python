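import numpy as np
import pytest

from crthedge import (
    Identifiability,
    TrendError,
    TrendTable,
    aggregate_trend,
    cohen_kappa,
    diff_proportions_ci,
    trend_test,
)
from conftest import TREND_COUNTS


@pytest.fixture(scope="module")
def gold_trend() -> TrendTable:
    return TrendTable.from_counts(TREND_COUNTS)


class TestDiffProportionsCI:
    def test_pooled_period_increase(self):
        # first half (2000-2003): 16/58 clear; second half (2004-2007): 62/104
        ci = diff_proportions_ci(16, 58, 62, 104)
        assert round(ci.difference, 1) == 32.0
        assert round(ci.lower, 1) == 17.2
        assert round(ci.upper, 1) == 46.9

    def test_matches_statsmodels_wald(self):
        sm = pytest.importorskip("statsmodels.stats.proportion")
        ci = diff_proportions_ci(16, 58, 62, 104)
        lo, hi = sm.confint_proportions_2indep(
            62, 104, 16, 58, method="wald", compare="diff"
        )
        assert ci.lower == pytest.approx(100 * lo, abs=1e-6)
        assert ci.upper == pytest.approx(100 * hi, abs=1e-6)

    def test_equal_proportions_symmetric(self):
        ci = diff_proportions_ci(30, 100, 30, 100)
        assert ci.difference == 0.0
        assert ci.lower == pytest.approx(-ci.upper)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(10, 200)), int(rng.integers(10, 200))
            x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            ci = diff_proportions_ci(x1, n1, x2, n2)
            assert ci.lower <= ci.difference <= ci.upper

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (50, 200, 800):
            x1, x2 = int(0.3 * n), int(0.6 * n)
            ci = diff_proportions_ci(x1, n, x2, n)
            widths.append(ci.upper - ci.lower)
        assert widths[0] > widths[1] > widths[2]

    def test_monte_carlo_coverage_near_nominal(self):
        rng = np.random.default_rng(77)
        p1, p2, n, sims = 0.3, 0.6, 100, 10000
        x1 = rng.binomial(n, p1, size=sims)
        x2 = rng.binomial(n, p2, size=sims)
        q1, q2 = x1 / n, x2 / n
        se = np.sqrt(q1 * (1 - q1) / n + q2 * (1 - q2) / n)
        lo = (q2 - q1) - 1.959963984540054 * se
        hi = (q2 - q1) + 1.959963984540054 * se
        covered = np.mean((lo <= p2 - p1) & (p2 - p1 <= hi))
        # spot-check the vectorized oracle against the implementation
        ci = diff_proportions_ci(int(x1[0]), n, int(x2[0]), n)
        assert ci.lower == pytest.approx(100 * lo[0], abs=1e-9)
        assert 0.93 <= covered <= 0.97

    def test_zero_sample_rejected(self):
        with pytest.raises(TrendError):
            diff_proportions_ci(0, 0, 1, 10)


class TestTrendTest:
    def test_proportions_method_on_gold_table(self, gold_trend):
        res = trend_test(gold_trend, method="proportions")
        assert round(res.statistic, 1) == 3.6
        assert res.p_value == pytest.approx(0.000327, abs=5e-5)

    def test_cochran_armitage_matches_frozen_r_value(self, gold_trend):
        # prop.trend.test on the same counts: chi2 = 17.279, p = 3.228e-05
        res = trend_test(gold_trend, method="cochran-armitage")
        assert res.statistic**2 == pytest.approx(17.279, abs=0.005)
        assert res.p_value == pytest.approx(3.228e-5, rel=0.01)

    def test_excluding_2006(self, gold_trend):
        reduced = gold_trend.exclude_years([2006])
        res = trend_test(reduced, method="proportions")
        assert res.statistic > 0
        assert res.p_value == pytest.approx(0.0015, abs=4e-4)

    def test_flat_proportions_give_null_result(self):
        table = TrendTable.from_counts([(y, 5, 10) for y in range(2000, 2006)])
        for method in ("proportions", "cochran-armitage"):
            res = trend_test(table, method=method)
            assert res.statistic == pytest.approx(0.0, abs=1e-12)
            assert res.p_value == pytest.approx(1.0)

    def test_invariant_to_year_shift(self, gold_trend):
        shifted = TrendTable.from_counts(
            [(r.year + 7, r.identified, r.total) for r in gold_trend.rows]
        )
        for method in ("proportions", "cochran-armitage"):
            a = trend_test(gold_trend, method=method)
            b = trend_test(shifted, method=method)
            assert a.statistic == pytest.approx(b.statistic, abs=1e-9)

    def test_declining_trend_is_negative(self):
        table = TrendTable.from_counts(
            [(2000, 18, 20), (2001, 12, 20), (2002, 6, 20), (2003, 2, 20)]
        )
        assert trend_test(table, "cochran-armitage").statistic < 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(TrendError):
            trend_test(TrendTable.from_counts([(2000, 1, 10)]))

    def test_unknown_method_rejected(self, gold_trend):
        with pytest.raises(TrendError):
            trend_test(gold_trend, method="bogus")


class TestTrendTable:
    def test_identified_cannot_exceed_total(self):
        with pytest.raises(TrendError):
            TrendTable.from_counts([(2000, 11, 10)])

    def test_years_strictly_increasing(self):
        with pytest.raises(TrendError):
            TrendTable.from_counts([(2001, 1, 10), (2001, 2, 10)])

    def test_pool(self, gold_trend):
        assert gold_trend.pool(range(2000, 2004)) == (16, 58)
        assert gold_trend.pool(range(2004, 2008)) == (62, 104)


class TestCohenKappa:
    def test_perfect_agreement(self):
        res = cohen_kappa([[50, 0], [0, 50]])
        assert res.kappa == pytest.approx(1.0)

    def test_chance_level_agreement(self):
        res = cohen_kappa([[25, 25], [25, 25]])
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_and_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(10):
            m = rng.integers(1, 40, size=(2, 2))
            n = m.sum()
            po = (m[0, 0] + m[1, 1]) / n
            pe = (
                (m[0].sum() / n) * (m[:, 0].sum() / n)
                + (m[1].sum() / n) * (m[:, 1].sum() / n)
            )
            res = cohen_kappa(m)
            assert res.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
            y1 = [0] * (m[0, 0] + m[0, 1]) + [1] * (m[1, 0] + m[1, 1])
            y2 = [0] * m[0, 0] + [1] * m[0, 1] + [0] * m[1, 0] + [1] * m[1, 1]
            assert res.kappa == pytest.approx(
                sk.cohen_kappa_score(y1, y2), abs=1e-12
            )

    def test_ci_brackets_estimate(self):
        res = cohen_kappa([[40, 10], [5, 45]])
        assert res.lower < res.kappa < res.upper
        assert res.upper <= 1.0

    def test_degenerate_margins_undefined(self):
        res = cohen_kappa([[10, 0], [0, 0]])
        assert res.kappa is None

    def test_empty_table_rejected(self):
        with pytest.raises(TrendError):
            cohen_kappa([[0, 0], [0, 0]])


class TestAggregateTrend:
    def test_gold_labels_reproduce_trend_table(self, gold_labels, gold_trend):
        table = aggregate_trend(gold_labels, Identifiability.CLEAR)
        assert table.rows == gold_trend.rows
        assert table.total_identified == 78
        assert table.total == 162
        assert round(100 * table.overall_proportion, 1) == 48.1

    def test_conservation(self, gold_labels):
        table = aggregate_trend(gold_labels, Identifiability.CLEAR)
        assert sum(r.identified for r in table.rows) == table.total_identified

    def test_single_year(self):
        from crthedge import GoldLabels, LabelRecord

        labels = GoldLabels()
        labels.add("00000001", LabelRecord(True, Identifiability.CLEAR, 2005))
        labels.add("00000002", LabelRecord(True, Identifiability.NONE, 2005))
        table = aggregate_trend(labels)
        assert len(table.rows) == 1
        assert table.rows[0].identified == 1 and table.rows[0].total == 2

    def test_no_crts_rejected(self):
        from crthedge import GoldLabels, LabelRecord

        labels = GoldLabels()
        labels.add("00000001", LabelRecord(False, Identifiability.NA, 2005))
        with pytest.raises(TrendError):
            aggregate_trend(labels)
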