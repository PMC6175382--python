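import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from screenprio.errors import FormatError, UndefinedMetricError
from screenprio.evaluation import (
    ScreeningTrace,
    aur,
    exact_null_pmf,
    exact_null_support,
    exact_pvalue,
    r_needed,
    recall_curve,
    running_recall,
    smooth_decision_times,
    wss95,
)


def _trace(indicators, decisions=None):
    """Build a complete trace from a 0/1 relevance sequence."""
    ids = [f"d{i}" for i in range(len(indicators))]
    truth = {i: bool(v) for i, v in zip(ids, indicators)}
    decisions = decisions or ["include" if v else "exclude" for v in indicators]
    rows = [(i, d, None) for i, d in zip(ids, decisions)]
    return ScreeningTrace.from_rows(rows, truth)


def _enumerate_i_r95(N, R):
    """Exhaustive-enumeration oracle for the null distribution of i_R95."""
    r = r_needed(R)
    counts = {}
    total = 0
    for positions in itertools.combinations(range(1, N + 1), R):
        i = sorted(positions)[r - 1]
        counts[i] = counts.get(i, 0) + 1
        total += 1
    return {i: c / total for i, c in counts.items()}


class TestRecallCurve:
    def test_perfect_ordering(self):
        curve = recall_curve(_trace([1, 1] + [0] * 8))
        assert curve.N == 10 and curve.R == 2
        np.testing.assert_allclose(curve.recall, [0.5, 1] + [1] * 8)

    def test_no_relevant_in_prefix_gives_zero_recall(self):
        curve = recall_curve(_trace([0, 0, 0, 1]))
        np.testing.assert_allclose(curve.recall[:3], 0)

    def test_hand_computed_cumulative_sums(self):
        curve = recall_curve(_trace([0, 1, 0, 1, 1, 0]))
        np.testing.assert_array_equal(curve.tp, [0, 1, 1, 2, 3, 3])
        np.testing.assert_array_equal(curve.fp, [1, 1, 2, 2, 2, 3])
        np.testing.assert_array_equal(curve.fn, [3, 2, 2, 1, 0, 0])
        np.testing.assert_allclose(curve.recall, np.array([0, 1, 1, 2, 3, 3]) / 3)

    def test_recall_non_decreasing_and_ends_at_one(self, rng):
        indicators = rng.permutation([1] * 7 + [0] * 43)
        curve = recall_curve(_trace(indicators))
        assert np.all(np.diff(curve.recall) >= 0)
        assert curve.recall[-1] == 1.0

    def test_incomplete_trace_rejected(self):
        ids = ["a", "b"]
        truth = {"a": True, "b": False, "c": False}
        trace = ScreeningTrace.from_rows([(i, "include", None) for i in ids], truth)
        with pytest.raises(UndefinedMetricError):
            recall_curve(trace)

    def test_missing_ground_truth_rejected(self):
        trace = ScreeningTrace.from_rows([("a", "include", None)], {"b": True})
        with pytest.raises(FormatError):
            recall_curve(trace)

    def test_zero_relevant_rejected(self):
        with pytest.raises(UndefinedMetricError):
            recall_curve(_trace([0, 0, 0]))


class TestWss95:
    def test_perfect_ordering_n100_r10(self):
        curve = recall_curve(_trace([1] * 10 + [0] * 90))
        res = wss95(curve)
        assert res.r_needed == 10
        assert res.i_r95 == 10
        assert res.wss95 == pytest.approx(0.85)

    def test_worst_ordering_needs_the_whole_collection(self):
        # all 10 relevant last: 95% recall needs all of them -> i_R95 = N
        curve = recall_curve(_trace([0] * 90 + [1] * 10))
        res = wss95(curve)
        assert res.i_r95 == 100
        assert res.wss95 == pytest.approx(0.95 - 1.0)

    def test_perfect_ordering_closed_form(self):
        for N, R in [(40, 3), (60, 20), (87, 13)]:
            curve = recall_curve(_trace([1] * R + [0] * (N - R)))
            assert wss95(curve).wss95 == pytest.approx(0.95 - r_needed(R) / N)

    def test_null_mean_matches_order_statistic_expectation(self, rng):
        # E[i_R95] under random ordering is the r-th order statistic mean
        # r(N+1)/(R+1); the null mean of WSS@95% is therefore slightly
        # positive, not zero.
        N, R = 200, 20
        exact_mean = 0.95 - r_needed(R) * (N + 1) / ((R + 1) * N)
        vals = []
        base = np.array([1] * R + [0] * (N - R))
        for _ in range(3000):
            vals.append(wss95(recall_curve(_trace(rng.permutation(base)))).wss95)
        assert np.mean(vals) == pytest.approx(exact_mean, abs=0.01)


class TestExactNull:
    def test_pmf_matches_enumeration_n4_r2(self):
        oracle = _enumerate_i_r95(4, 2)
        assert oracle[2] == pytest.approx(1 / 6)
        for i in range(2, 5):
            assert exact_null_pmf(4, 2, i) == pytest.approx(oracle[i])

    def test_pmf_normalises(self):
        lo, hi = exact_null_support(4, 2)
        assert (lo, hi) == (2, 4)
        assert exact_null_pmf(4, 2, np.arange(lo, hi + 1)).sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("N,R", [(6, 1), (7, 3), (8, 4), (9, 6), (10, 10)])
    def test_pmf_matches_enumeration_small(self, N, R):
        oracle = _enumerate_i_r95(N, R)
        for i, p in oracle.items():
            assert exact_null_pmf(N, R, i) == pytest.approx(p)
        lo, hi = exact_null_support(N, R)
        assert set(oracle) == set(range(lo, hi + 1))

    def test_outside_support_returns_zero(self):
        assert exact_null_pmf(10, 2, 1) == 0.0
        assert exact_null_pmf(10, 2, 11) == 0.0

    @given(st.integers(2, 120).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(1, n))))
    def test_pmf_sums_to_one(self, nr):
        N, R = nr
        lo, hi = exact_null_support(N, R)
        total = exact_null_pmf(N, R, np.arange(lo, hi + 1)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_pvalue_at_maximal_position_is_one(self):
        for N, R in [(10, 2), (50, 7)]:
            _, hi = exact_null_support(N, R)
            assert exact_pvalue(N, R, hi) == pytest.approx(1.0)

    def test_pvalue_matches_enumeration(self):
        assert exact_pvalue(4, 2, 2) == pytest.approx(1 / 6)
        for N, R in [(6, 2), (8, 3)]:
            oracle = _enumerate_i_r95(N, R)
            lo, hi = exact_null_support(N, R)
            for i in range(lo, hi + 1):
                expected = sum(p for j, p in oracle.items() if j <= i)
                assert exact_pvalue(N, R, i) == pytest.approx(expected)

    def test_large_collection_no_overflow(self):
        # magnitudes matching the largest real screening collections
        p = exact_pvalue(5000, 925, 4000)
        assert 0 < p <= 1


class TestAur:
    def test_perfect_ordering_is_exactly_one(self):
        for N, R in [(10, 2), (100, 10), (57, 9)]:
            curve = recall_curve(_trace([1] * R + [0] * (N - R)))
            assert aur(curve).aur == pytest.approx(1.0, abs=1e-12)

    def test_worst_ordering_hand_computed(self):
        # N=10, R=2 reversed: recall = 0..0,0.5,1 -> sum 1.5, normaliser 9.5
        curve = recall_curve(_trace([0] * 8 + [1, 1]))
        assert aur(curve).aur == pytest.approx(1.5 / 9.5)

    def test_random_ordering_mean_matches_analytic_expectation(self, rng):
        # E[recall(i)] = i/N so E[sum] = (N+1)/2; with N=200, R=20 the
        # expected AUR is 100.5/190.5 = 0.5276
        N, R = 200, 20
        expected = ((N + 1) / 2) / (N - (R - 1) / 2)
        base = np.array([1] * R + [0] * (N - R))
        vals = [aur(recall_curve(_trace(rng.permutation(base)))).aur
                for _ in range(2000)]
        assert np.mean(vals) == pytest.approx(expected, abs=0.01)

    def test_depends_only_on_indicator_sequence(self):
        # recorded decisions do not enter AUR, only ground-truth relevance
        indicators = [1, 0, 1, 0, 0]
        oracle_decisions = ["include", "exclude", "include", "exclude", "exclude"]
        noisy_decisions = ["exclude"] * 5
        a = aur(recall_curve(_trace(indicators, oracle_decisions)))
        b = aur(recall_curve(_trace(indicators, noisy_decisions)))
        assert a.aur == b.aur


class TestRunningRecall:
    def test_full_agreement_is_constant_one(self):
        indicators = [1, 0] * 20
        trace = _trace(indicators)
        baseline = {i for i, v in trace.ground_truth.items() if v}
        series = running_recall(trace, baseline, window=5)
        assert (series == 1.0).all()

    def test_alternating_agreement_is_half(self):
        indicators = [1] * 20
        decisions = ["include", "exclude"] * 10
        trace = _trace(indicators, decisions)
        baseline = set(trace.ids)
        series = running_recall(trace, baseline, window=10)
        assert series.iloc[-1] == pytest.approx(0.5)

    def test_late_complacency_gives_decreasing_tail(self):
        # agreement decays late: last 10 baseline-relevant all excluded
        decisions = ["include"] * 30 + ["exclude"] * 10
        trace = _trace([1] * 40, decisions)
        series = running_recall(trace, set(trace.ids), window=10)
        tail = series.iloc[-10:]
        assert (np.diff(tail) <= 0).all()
        assert tail.iloc[-1] < tail.iloc[0]

    def test_fewer_than_window_warns_and_returns_global(self):
        trace = _trace([1, 0, 1])
        baseline = {i for i, v in trace.ground_truth.items() if v}
        with pytest.warns(UserWarning):
            series = running_recall(trace, baseline, window=50)
        assert len(series) == 1


class TestSmoothDecisionTimes:
    def test_constant_intervals_unchanged(self):
        ts = np.arange(0, 300, 30)
        out = smooth_decision_times(ts, window=5)
        assert (out == 30).all()

    def test_single_outlier_removed_by_median(self):
        ts = list(np.arange(0, 300, 30.0))
        ts[5] += 20  # one long/short interval pair around position 5
        out = smooth_decision_times(ts, window=5)
        assert out.median() == pytest.approx(30)

    def test_matches_direct_truncated_median(self):
        rng = np.random.default_rng(0)
        intervals = np.where(np.arange(120) % 2 == 0, 10.0, 50.0)
        ts = np.concatenate([[0.0], np.cumsum(intervals)])
        window = 51
        out = smooth_decision_times(ts, window=window)
        half = window // 2
        direct = [
            float(np.median(intervals[max(0, j - half): j + half + 1]))
            for j in range(len(intervals))
        ]
        np.testing.assert_allclose(out.to_numpy(), direct)

    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(FormatError):
            smooth_decision_times([0, 10, 5], window=3)

    def test_even_window_rejected(self):
        from screenprio.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            smooth_decision_times([0, 1, 2], window=4)
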