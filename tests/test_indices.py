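import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germkin import (
    ExperimentSet,
    TimeCourse,
    UndefinedIndexError,
    auc,
    germinability,
    index_report,
    mean_germination_rate,
    mean_germination_time,
    time_to_fraction,
    uniformity_u8416,
)
from germkin.curves import HillParams, eval_hill


class TestFrozenFixture:
    """Hand-computed reference values on counts (0,10,30,45,45) at 24..120 h, n=50."""

    def test_germinability(self, fixture_course):
        assert germinability(fixture_course) == pytest.approx(90.0, abs=1e-12)

    def test_mean_germination_time(self, fixture_course):
        # (10*48 + 20*72 + 15*96) / 45
        assert mean_germination_time(fixture_course) == pytest.approx(3360 / 45, abs=1e-12)

    def test_mean_rate_is_reciprocal(self, fixture_course):
        v = mean_germination_rate(fixture_course)
        assert v * mean_germination_time(fixture_course) == pytest.approx(1.0, abs=1e-12)
        assert v == pytest.approx(45 / 3360, abs=1e-9)

    def test_median_time_interpolation(self, fixture_course):
        # L = 22.5 between (48, 10) and (72, 30)
        assert time_to_fraction(fixture_course, 0.5) == pytest.approx(63.0, abs=1e-9)

    def test_uniformity_quantiles(self, fixture_course):
        assert time_to_fraction(fixture_course, 0.16) == pytest.approx(41.28, abs=1e-9)
        assert time_to_fraction(fixture_course, 0.84) == pytest.approx(84.48, abs=1e-9)
        assert uniformity_u8416(fixture_course) == pytest.approx(43.2, abs=1e-9)

    def test_auc_trapezoid(self, fixture_course):
        raw, norm = auc(fixture_course, cutoff=120)
        assert raw == pytest.approx(5160.0, abs=1e-9)
        assert norm == pytest.approx(43.0, abs=1e-9)


class TestEdgeCases:
    def test_no_germination_is_zero_g_and_undefined_tbar(self):
        tc = TimeCourse("none", [24, 48, 72], [0, 0, 0], "counts", 50)
        assert germinability(tc) == 0.0
        with pytest.raises(UndefinedIndexError):
            mean_germination_time(tc)

    def test_single_interval_jump(self):
        # all events in one interval: t̄ is its right endpoint, and the
        # quantile spread is 68% of the interval under linear interpolation
        tc = TimeCourse("jump", [24, 48, 72], [0, 40, 40], "counts", 50)
        assert mean_germination_time(tc) == 48.0
        assert uniformity_u8416(tc) == pytest.approx(0.68 * 24, abs=1e-9)

    def test_synchronous_germination_zero_uniformity(self):
        # everything germinated by the first scoring: both quantiles sit at
        # the earliest time attaining the level, so the spread is zero
        tc = TimeCourse("sync", [24, 48, 72], [40, 40, 40], "counts", 50)
        assert uniformity_u8416(tc) == 0.0

    def test_level_at_observed_plateau_returns_earliest_time(self):
        tc = TimeCourse("plateau", [10, 20, 30, 40], [0, 20, 20, 40], "counts", 50)
        # q=0.5 of final 40 -> level 20, observed at t=20 first
        assert time_to_fraction(tc, 0.5) == 20.0

    def test_unreachable_sample_level_reports_attained_maximum(self, fixture_course):
        with pytest.raises(UndefinedIndexError) as exc:
            time_to_fraction(fixture_course, 0.95, baseline="of_sample")
        assert exc.value.attained == 45

    def test_of_sample_baseline_uses_seeds_sown(self, fixture_course):
        # 10% of 50 seeds = 5 counts, between (24,0) and (48,10) -> 36 h
        assert time_to_fraction(fixture_course, 0.1, "of_sample") == pytest.approx(36.0)

    def test_auc_flat_extension_and_cutoff_interpolation(self):
        tc = TimeCourse("short", [24, 48], [0, 50], "counts", 50)
        raw, _ = auc(tc, cutoff=120)
        # (0,0)->(24,0)->(48,100): 1200; flat 100 for 72 h: 7200
        assert raw == pytest.approx(1200 + 7200, abs=1e-9)
        tc2 = TimeCourse("long", [0, 200], [0, 100], "percent")
        raw2, norm2 = auc(tc2, cutoff=100)
        assert raw2 == pytest.approx(0.5 * 100 * 50, abs=1e-9)  # triangle to y=50 at t=100
        assert norm2 == pytest.approx(25.0, abs=1e-9)

    def test_constant_100_percent_saturates_normalized_auc(self):
        tc = TimeCourse("full", [0, 120], [100, 100], "percent")
        raw, norm = auc(tc, cutoff=120)
        assert raw == pytest.approx(12000.0) and norm == pytest.approx(100.0)


class TestProperties:
    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_quantile_monotonicity(self, data):
        n = data.draw(st.integers(3, 8))
        times = np.cumsum(data.draw(st.lists(st.floats(1, 24), min_size=n, max_size=n)))
        increments = data.draw(st.lists(st.integers(0, 10), min_size=n, max_size=n))
        values = np.cumsum(increments)
        if values[-1] == 0:
            values[-1] = 1
        tc = TimeCourse("h", times, values, "counts", n_seeds=int(values[-1]) + 5)
        qs = sorted(data.draw(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6)))
        ts = [time_to_fraction(tc, q) for q in qs]
        assert all(a <= b + 1e-9 for a, b in zip(ts, ts[1:]))

    def test_auc_invariant_to_collinear_points(self):
        tc = TimeCourse("base", [0, 60, 120], [0, 50, 100], "percent")
        dense = TimeCourse("dense", [0, 30, 60, 90, 120], [0, 25, 50, 75, 100], "percent")
        assert auc(tc)[0] == pytest.approx(auc(dense)[0], abs=1e-9)

    def test_interpolated_t50_converges_on_dense_sigmoid_grid(self):
        truth = HillParams(0, 90, 4, 63)
        for n_pts in (20, 80):
            t = np.linspace(1, 200, n_pts)
            tc = TimeCourse("s", t, eval_hill(truth, t), "percent")
            spacing = t[1] - t[0]
            # of_final on a finite window slightly shifts the target level, so
            # compare against the curve's own 50%-of-final crossing
            assert abs(time_to_fraction(tc, 0.5) - 63.0) < max(spacing, 3.0)
        t = np.linspace(1, 400, 4000)
        tc = TimeCourse("s", t, eval_hill(truth, t), "percent")
        assert abs(time_to_fraction(tc, 0.5) - 63.0) < t[1] - t[0]


class TestPooling:
    def test_identical_repetitions_pool_to_same_values(self, fixture_experiment):
        rep = index_report(fixture_experiment, "mean_of_repetitions")
        pooled = index_report(fixture_experiment, "pooled_counts")
        for key in ("G", "t_mean", "t50", "u_8416", "auc"):
            assert getattr(rep, key) == pytest.approx(getattr(pooled, key), abs=1e-9)
            assert getattr(rep, key) == pytest.approx(rep.per_repetition[0][key], abs=1e-9)

    def test_mean_of_repetitions_averages_each_index(self):
        a = TimeCourse("A", [20, 40], [0, 10], "counts", 50)
        b = TimeCourse("B", [30, 60], [0, 10], "counts", 50)
        rep = index_report(ExperimentSet("e", [a, b]), "mean_of_repetitions")
        assert rep.t_mean == pytest.approx((40 + 60) / 2)

    def test_pooled_counts_merges_before_computing(self):
        a = TimeCourse("A", [24, 48], [0, 10], "counts", 50)
        b = TimeCourse("B", [24, 48], [0, 30], "counts", 50)
        rep = index_report(ExperimentSet("e", [a, b]), "pooled_counts")
        assert rep.G == pytest.approx(100 * 40 / 100)
        assert rep.t_mean == pytest.approx(48.0)

    def test_mixed_value_kinds_rejected(self):
        a = TimeCourse("A", [24, 48], [0, 10], "counts", 50)
        b = TimeCourse("B", [24, 48], [0, 20], "percent")
        with pytest.raises(Exception):
            index_report(ExperimentSet("e", [a, b]), "mean_of_repetitions")
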