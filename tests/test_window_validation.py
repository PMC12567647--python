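"""Fertile windows, day-level classification, diagnostic metrics and
exact binomial intervals."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from bbtval.window_validation import (
    ConfusionTable,
    DayLabel,
    FertileWindow,
    WindowKind,
    WindowMode,
    accumulate,
    classify_days,
    concordance,
    exact_binomial_interval,
    percent_str,
    performance_metrics,
    peri_ovulatory_period,
    predicted_fertile_window,
)


def window(lo, hi, kind=WindowKind.PREDICTED):
    return FertileWindow(lo, hi, kind, WindowMode.SURGE10)


def cp_bisect(successes, trials, level=0.95, iters=100):
    """Independent Clopper-Pearson: invert the binomial tails by bisection."""
    alpha = (1 - level) / 2

    def bisect(f, target):
        lo, hi = 0.0, 1.0
        for _ in range(iters):
            mid = (lo + hi) / 2
            if f(mid) > target:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    # P(X >= x | p) grows with p; the lower bound solves it equal to alpha
    low = 0.0 if successes == 0 else bisect(
        lambda p: binom.sf(successes - 1, trials, p), alpha
    )
    # P(X <= x | p) falls with p; the upper bound solves it equal to alpha
    high = 1.0 if successes == trials else bisect(
        lambda p: -binom.cdf(successes, trials, p), -alpha
    )
    return low, high


class TestWindows:
    @pytest.mark.parametrize(
        "a_edo, mode, length, expected",
        [
            (16, WindowMode.SURGE10, 28, (9, 18)),   # +-2 band plus 5 preceding days
            (16, WindowMode.WILCOX6, 28, (11, 16)),  # ovulation day + 5 preceding
            (4, WindowMode.SURGE10, 28, (1, 6)),     # clipped at the start
            (27, WindowMode.SURGE10, 28, (20, 28)),  # clipped at the end
        ],
    )
    def test_predicted_window(self, a_edo, mode, length, expected):
        w = predicted_fertile_window(a_edo, mode, length)
        assert (w.start_day, w.end_day) == expected

    @pytest.mark.parametrize(
        "a_edo, length, expected",
        [(15, 28, (13, 17)), (2, 28, (1, 4)), (27, 28, (25, 28))],
    )
    def test_peri_ovulatory_period(self, a_edo, length, expected):
        assert peri_ovulatory_period(a_edo, length) == expected

    @settings(max_examples=200, derandomize=True)
    @given(a_edo=st.integers(min_value=10, max_value=24), length=st.integers(min_value=28, max_value=35))
    def test_unclipped_widths(self, a_edo, length):
        assert len(predicted_fertile_window(a_edo, WindowMode.SURGE10, length)) == 10
        assert len(predicted_fertile_window(a_edo, WindowMode.WILCOX6, length)) == 6
        lo, hi = peri_ovulatory_period(a_edo, length)
        assert hi - lo + 1 == 5


class TestClassification:
    def test_offset_windows(self):
        labels = classify_days(28, window(9, 18), window(8, 17, WindowKind.REFERENCE))
        t = ConfusionTable.from_labels(labels)
        assert (t.tp, t.fp, t.fn, t.tn) == (9, 1, 1, 17)

    def test_identical_windows_have_no_errors(self):
        labels = classify_days(28, window(9, 18), window(9, 18, WindowKind.REFERENCE))
        t = ConfusionTable.from_labels(labels)
        assert t.fp == t.fn == 0 and t.tp == 10

    def test_disjoint_windows(self):
        labels = classify_days(28, window(3, 12), window(15, 24, WindowKind.REFERENCE))
        t = ConfusionTable.from_labels(labels)
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 10, 10, 8)

    @settings(max_examples=300, derandomize=True)
    @given(data=st.data())
    def test_matches_set_enumeration(self, data):
        length = data.draw(st.integers(min_value=10, max_value=35))
        p_lo = data.draw(st.integers(min_value=1, max_value=length))
        p_hi = data.draw(st.integers(min_value=p_lo, max_value=length))
        r_lo = data.draw(st.integers(min_value=1, max_value=length))
        r_hi = data.draw(st.integers(min_value=r_lo, max_value=length))
        labels = classify_days(
            length, window(p_lo, p_hi), window(r_lo, r_hi, WindowKind.REFERENCE)
        )
        pred, ref = set(range(p_lo, p_hi + 1)), set(range(r_lo, r_hi + 1))
        expect = ConfusionTable(
            tp=len(pred & ref),
            fp=len(pred - ref),
            fn=len(ref - pred),
            tn=length - len(pred | ref),
        )
        assert ConfusionTable.from_labels(labels) == expect
        assert len(labels) == length  # every day gets exactly one label

    def test_accumulate_is_additive(self):
        labels = classify_days(28, window(9, 18), window(8, 17, WindowKind.REFERENCE))
        t = accumulate([labels, labels])
        assert (t.tp, t.fp, t.fn, t.tn) == (18, 2, 2, 34)
        assert t.total == 56
        assert accumulate([]) == ConfusionTable()


class TestExactInterval:
    @pytest.mark.parametrize("trials", [1, 2, 5, 17, 40])
    def test_matches_tail_inversion(self, trials):
        for successes in range(trials + 1):
            got = exact_binomial_interval(successes, trials)
            want = cp_bisect(successes, trials)
            assert got == pytest.approx(want, abs=1e-9)

    def test_boundary_cases_are_exact(self):
        assert exact_binomial_interval(0, 20)[0] == 0.0
        assert exact_binomial_interval(20, 20)[1] == 1.0

    def test_contains_point_and_monotone_in_successes(self):
        n = 50
        prev_low = prev_high = -1.0
        for x in range(n + 1):
            low, high = exact_binomial_interval(x, n)
            assert low <= x / n <= high
            assert low >= prev_low and high >= prev_high
            prev_low, prev_high = low, high

    def test_widens_as_trials_decrease(self):
        wide = exact_binomial_interval(8, 10)
        narrow = exact_binomial_interval(80, 100)
        assert wide[1] - wide[0] > narrow[1] - narrow[0]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_interval(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_interval(0, 0)


class TestMetrics:
    def test_published_confusion_counts_reproduce_reported_table(self):
        """1138/4180/38/38 gives the reported metric and interval strings."""
        m = performance_metrics(ConfusionTable(tp=1138, tn=4180, fp=38, fn=38))
        assert m["sensitivity"].formatted() == "96.8% (95.6; 97.7)"
        assert m["specificity"].formatted() == "99.1% (98.8; 99.4)"
        assert m["accuracy"].formatted() == "98.6% (98.2; 98.9)"
        assert m["ppv"].formatted() == "96.8% (95.6; 97.7)"
        assert m["npv"].formatted() == "99.1% (98.8; 99.4)"

    def test_matches_rational_arithmetic(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            t = ConfusionTable(tp=tp, tn=tn, fp=fp, fn=fn)
            if t.total == 0:
                continue
            m = performance_metrics(t)
            checks = {
                "sensitivity": (tp, tp + fn),
                "specificity": (tn, tn + fp),
                "accuracy": (tp + tn, t.total),
                "ppv": (tp, tp + fp),
                "npv": (tn, tn + fn),
            }
            for name, (num, den) in checks.items():
                if den == 0:
                    assert not m[name].defined
                else:
                    assert m[name].point == pytest.approx(float(Fraction(num, den)))

    def test_zero_denominators_are_undefined_not_numbers(self):
        m = performance_metrics(ConfusionTable(tp=7, tn=0, fp=0, fn=0))
        assert m["sensitivity"].point == 1.0
        assert m["ppv"].point == 1.0
        assert not m["specificity"].defined
        assert not m["npv"].defined
        assert m["specificity"].formatted() == "undefined"

    @settings(max_examples=100, derandomize=True)
    @given(
        tp=st.integers(min_value=1, max_value=2000),
        tn=st.integers(min_value=1, max_value=5000),
        e=st.integers(min_value=0, max_value=100),
    )
    def test_equal_fp_fn_makes_sensitivity_equal_ppv(self, tp, tn, e):
        """With fp == fn the sensitivity and PPV denominators coincide."""
        m = performance_metrics(ConfusionTable(tp=tp, tn=tn, fp=e, fn=e))
        assert m["sensitivity"].point == m["ppv"].point
        assert m["specificity"].point == m["npv"].point

    def test_percent_rounding_is_half_up(self):
        assert percent_str(0.0625) == "6.3"   # 6.25 rounds up, not to even
        assert percent_str(0.96875) == "96.9"


class TestConcordance:
    def test_closed_form_mean_and_sd(self):
        s = concordance([(15, 15), (15, 14), (15, 13)])  # diffs 0, 1, 2
        assert s.mean_diff == pytest.approx(1.0)
        assert s.sd_diff == pytest.approx(1.0)
        assert s.histogram == {0: 1, 1: 1, 2: 1}

    @pytest.mark.parametrize(
        "diff, category",
        [(-2, "early"), (-1, "within"), (0, "within"), (3, "within"), (4, "delayed")],
    )
    def test_category_boundaries(self, diff, category):
        s = concordance([(14 + diff, 14)])
        got = {"within": s.n_within, "delayed": s.n_delayed, "early": s.n_early}
        assert got[category] == 1
        assert sum(got.values()) == 1

    def test_counts_partition_the_cycles(self):
        pairs = [(15, 14), (19, 14), (11, 14), (14, 14), (18, 14)]
        s = concordance(pairs)
        assert s.n_within + s.n_delayed + s.n_early == s.n == len(pairs)
        assert sum(s.histogram.values()) == s.n

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            concordance([])
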