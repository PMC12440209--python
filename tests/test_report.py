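"""Classification metrics, glycemic reports and the paired Wilcoxon test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycloop.core_io import MealEvent, MealWindow
from glycloop.errors import MetricError
from glycloop.report import (
    confusion_metrics, mcc_score, mcc_threshold, postprandial_report,
    roc_auc, tir_report, wilcoxon_paired, youden_threshold,
)

from conftest import T0, constant_trace, make_trace


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        cm = confusion_metrics(y, y)
        assert cm.accuracy == 100.0
        assert cm.mcc == 1.0

    def test_all_positive_zero_denominator_convention(self):
        y = np.array([0, 1, 0, 1])
        cm = confusion_metrics(y, np.ones(4, dtype=int))
        assert cm.mcc == 0.0

    def test_against_direct_formula(self):
        tp, tn, fp, fn = 45, 40, 10, 5
        y = np.concatenate([np.ones(tp + fn), np.zeros(tn + fp)]).astype(int)
        yhat = np.concatenate([np.ones(tp), np.zeros(fn),
                               np.ones(fp), np.zeros(tn)]).astype(int)
        cm = confusion_metrics(y, yhat)
        expected = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert cm.mcc == pytest.approx(expected)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)

    def test_symmetry_under_joint_swap(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        yhat = rng.integers(0, 2, 50)
        assert confusion_metrics(y, yhat).mcc == pytest.approx(
            confusion_metrics(1 - y, 1 - yhat).mcc)

    def test_length_mismatch(self):
        with pytest.raises(MetricError):
            confusion_metrics(np.array([1, 0]), np.array([1]))


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        y = np.array([0, 1, 0, 1])
        _, auc = roc_auc(np.full(4, 0.5), y)
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        scores = np.round(rng.uniform(size=20), 1)  # force some ties
        _, auc = roc_auc(scores, y)
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        scores = rng.normal(size=30)
        _, a1 = roc_auc(scores, y)
        _, a2 = roc_auc(np.exp(3 * scores) + 7, y)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestThresholds:
    def test_youden_midpoint_of_separating_gap(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        assert youden_threshold(scores, y) == pytest.approx(0.5)

    @pytest.mark.parametrize("picker", [youden_threshold, mcc_threshold])
    def test_rescan_confirms_optimality(self, picker):
        rng = np.random.default_rng(8)
        scores = rng.uniform(size=40)
        y = (scores + rng.normal(0, 0.3, 40) > 0.5).astype(int)
        thr = picker(scores, y)

        def objective(t):
            yhat = (scores >= t).astype(int)
            cm = confusion_metrics(y, yhat)
            if picker is youden_threshold:
                return cm.sensitivity / 100 + cm.specificity / 100 - 1
            return cm.mcc

        best = max(objective(t) for t in np.linspace(-0.1, 1.1, 400))
        assert objective(thr) == pytest.approx(best, abs=1e-9)


class TestTirReport:
    def test_constant_100_all_in_range(self):
        rep = tir_report(constant_trace(100.0, 100))
        assert rep.pct_70_180 == 100.0
        assert rep.pct_below_54 == rep.pct_above_180 == 0.0
        assert rep.cv_pct == 0.0

    def test_counted_fraction(self):
        vals = np.array([40, 50, 100, 100, 100, 100, 100, 100, 100, 100.0])
        rep = tir_report(make_trace(vals))
        assert rep.pct_below_54 == pytest.approx(20.0)

    def test_boundary_conventions(self):
        rep = tir_report(make_trace(np.array([54.0, 70.0, 180.0, 250.0])))
        assert rep.pct_54_70 == pytest.approx(50.0)   # 54 and 70 inclusive
        assert rep.pct_70_180 == pytest.approx(25.0)  # 180 inside, 70 outside
        assert rep.pct_180_250 == pytest.approx(25.0)
        assert rep.pct_above_250 == 0.0

    def test_partition_identity_random_traces(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            vals = rng.uniform(25, 500, size=rng.integers(5, 300))
            rep = tir_report(make_trace(vals))
            total = (rep.pct_below_54 + rep.pct_54_70 + rep.pct_70_180
                     + rep.pct_180_250 + rep.pct_above_250)
            assert total == pytest.approx(100.0, abs=0.01)
            assert rep.pct_above_180 == pytest.approx(
                rep.pct_180_250 + rep.pct_above_250, abs=1e-9)

    def test_all_missing_rejected(self):
        tr = make_trace(np.full(5, np.nan), missing=np.ones(5, bool))
        with pytest.raises(MetricError):
            tir_report(tr)


def _window(post_vals):
    meal_time = T0 + pd.Timedelta(hours=12)
    pre = constant_trace(120.0, 72, start=meal_time - pd.Timedelta(minutes=355))
    post = make_trace(post_vals, start=meal_time + pd.Timedelta(minutes=5))
    return MealWindow(meal=MealEvent(time=meal_time, cho_announced=50.0),
                      pre=pre, post=post, bolus_units=5.0)


class TestPostprandialReport:
    def test_triangular_peak_position(self):
        vals = np.concatenate([np.linspace(120, 220, 21),
                               np.linspace(220, 120, 27)])
        rep = postprandial_report([_window(vals)])
        assert rep.time_to_peak_min == pytest.approx(105.0)  # slot 21

    def test_constant_window(self):
        rep = postprandial_report([_window(np.full(48, 120.0))])
        assert rep.excursion == pytest.approx(0.0)
        assert rep.min_bg == rep.max_bg == 120.0

    def test_first_of_equal_maxima(self):
        vals = np.full(48, 120.0)
        vals[[10, 30]] = 200.0
        rep = postprandial_report([_window(vals)])
        assert rep.time_to_peak_min == pytest.approx(55.0)  # slot 10

    def test_excursion_is_mean_minus_initial(self):
        vals = np.full(48, 140.0)
        rep = postprandial_report([_window(vals)])
        assert rep.initial_bg == 120.0
        assert rep.excursion == pytest.approx(20.0)


class TestWilcoxon:
    def test_identical_pairs(self):
        x = np.arange(10.0)
        w, p = wilcoxon_paired(x, x)
        assert p == 1.0

    def test_all_positive_differences_smallest_p(self):
        before = np.zeros(10)
        after = np.arange(1.0, 11.0)
        _, p = wilcoxon_paired(before, after)
        assert p == pytest.approx(2 / 2**10)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            d = np.round(rng.normal(0, 2, size=9), 1)
            d = d[d != 0]
            n = len(d)
            if n < 5:
                continue
            ranks = stats.rankdata(np.abs(d))
            w_pos = ranks[d > 0].sum()
            dist = [sum(r for r, s in zip(ranks, signs) if s)
                    for signs in itertools.product([0, 1], repeat=n)]
            dist = np.array(dist)
            mu = n * (n + 1) / 4
            if w_pos <= mu:
                p_brute = 2 * np.mean(dist <= w_pos + 1e-9)
            else:
                p_brute = 2 * np.mean(dist >= w_pos - 1e-9)
            p_brute = min(p_brute, 1.0)
            _, p = wilcoxon_paired(np.zeros(n), d)
            assert p == pytest.approx(p_brute, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.5, 1.0, size=12)
        _, p = wilcoxon_paired(np.zeros(12), d)
        p_scipy = stats.wilcoxon(d, method="exact").pvalue
        assert p == pytest.approx(p_scipy, abs=1e-10)

    def test_exact_close_to_normal_at_n20(self):
        rng = np.random.default_rng(9)
        before = rng.normal(100, 10, 20)
        after = before + rng.normal(1.0, 2.0, 20)
        _, p_exact = wilcoxon_paired(before, after)
        p_norm = stats.wilcoxon(after - before, method="approx",
                                correction=True).pvalue
        assert p_exact == pytest.approx(p_norm, abs=0.01)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(MetricError):
            wilcoxon_paired(np.arange(3.0), np.arange(3.0) + 1)
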