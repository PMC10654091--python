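"""Exposure variables, exact 2x2 test, zero-inflated Poisson inference
and grouped multiplicity control."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vaxbiome.exposure import (
    build_exposure_variables,
    cumulative_oral_days,
    current_use,
    fisher_exact_2x2,
    summarize_courses,
    use_in_window,
    used_at_birth,
    zip_component_tests,
    zip_fit,
    zip_loglik,
    zip_omnibus_lrt,
)
from vaxbiome.multiplicity import bh_adjust, double_fdr


def exposure_log(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["subject_id", "route", "start_day",
                                       "duration_days"])


class TestExposureVariables:
    def test_no_courses_means_zero_exposure(self):
        log = exposure_log([("other", "oral", 10, 5)])
        out = build_exposure_variables(log, subjects=["s1"])
        assert out.loc["s1", "cumulative_oral_days"] == 0
        assert not out.loc["s1", "used_at_birth"]

    def test_single_course_duration(self):
        log = exposure_log([("s1", "oral", 100, 10)])
        assert cumulative_oral_days(log)["s1"] == 10

    def test_overlapping_courses_count_union_of_days(self):
        # days 5..14 and 10..19: union is {5..19} = 15 days, not 20.
        log = exposure_log([("s1", "oral", 5, 10), ("s1", "oral", 10, 10)])
        days = set(range(5, 15)) | set(range(10, 20))  # enumeration oracle
        assert cumulative_oral_days(log)["s1"] == len(days) == 15

    def test_cutoff_clips_days(self):
        log = exposure_log([("s1", "oral", 360, 30)])
        assert cumulative_oral_days(log, cutoff_day=365)["s1"] == 5

    def test_course_order_invariance(self, rng):
        courses = [("s1", "oral", int(rng.integers(0, 300)), int(rng.integers(1, 15)))
                   for _ in range(12)]
        a = cumulative_oral_days(exposure_log(courses))["s1"]
        b = cumulative_oral_days(exposure_log(courses[::-1]))["s1"]
        assert a == b <= 365

    def test_topical_courses_excluded_everywhere(self):
        log = exposure_log([("s1", "topical", 2, 10), ("s1", "topical", 100, 10)])
        out = build_exposure_variables(log, subjects=["s1"])
        assert out.loc["s1", "cumulative_oral_days"] == 0
        assert not out.loc["s1", "used_at_birth"]

    def test_birth_window_uses_systemic_routes(self):
        log = exposure_log([("s1", "IV", 3, 5), ("s2", "oral", 30, 5)])
        flags = used_at_birth(log, birth_window_days=7)
        assert flags["s1"] and not flags["s2"]

    def test_recent_and_current_use_windows(self):
        log = exposure_log([("s1", "oral", 50, 5)])  # covers days 50..54
        assert use_in_window(log, day=61, window_days=7)["s1"]
        assert not use_in_window(log, day=62, window_days=7)["s1"]
        assert current_use(log, day=54)["s1"]
        assert not current_use(log, day=55)["s1"]

    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError, match="valid routes"):
            cumulative_oral_days(exposure_log([("s1", "intrathecal", 0, 1)]))

    def test_course_summary_percentages(self):
        log = exposure_log(
            [("s", "oral", 1, 1)] * 3 + [("s", "topical", 1, 1)]
        )
        summary = summarize_courses(log).set_index("route")
        assert summary.loc["oral", "pct"] == pytest.approx(75.0)
        assert summary["n_courses"].sum() == 4


class TestFisherExact:
    def test_identical_groups_p_one(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]) == pytest.approx(1.0)

    def test_perfect_separation_full_enumeration(self):
        # all C(10,5)=252 tables with these margins; only the observed
        # table and its mirror are as extreme -> p = 2/252.
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestZipFit:
    def test_no_zeros_boundary_gives_poisson_mle(self):
        counts = np.array([3, 5, 2, 7, 4])
        model = zip_fit(counts)
        assert model.pi == 0.0
        assert model.lam == pytest.approx(counts.mean())

    def test_all_zero_flagged_degenerate(self):
        model = zip_fit(np.zeros(10, dtype=int))
        assert model.degenerate and model.pi == 1.0

    def test_mle_beats_grid(self, rng):
        counts = np.where(rng.random(400) < 0.35, 0, rng.poisson(6.0, 400))
        model = zip_fit(counts)
        grid = max(
            zip_loglik(counts, pi, lam)
            for pi in np.linspace(0.0, 0.95, 50)
            for lam in np.linspace(0.1, 15.0, 50)
        )
        assert model.loglik >= grid - 1e-9

    def test_parameter_recovery_single_draw(self, rng):
        counts = np.where(rng.random(5000) < 0.4, 0, rng.poisson(12.0, 5000))
        model = zip_fit(counts)
        assert model.pi == pytest.approx(0.4, abs=0.03)
        assert model.lam == pytest.approx(12.0, abs=0.3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            zip_fit(np.array([1, -2, 3]))


class TestZipLrt:
    def test_identical_groups_give_zero_statistic(self, rng):
        x = np.where(rng.random(100) < 0.5, 0, rng.poisson(8.0, 100))
        stat, p, degenerate = zip_omnibus_lrt(x, x)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)
        assert not degenerate

    def test_group_relabeling_invariance(self, rng):
        a = np.where(rng.random(40) < 0.5, 0, rng.poisson(10.0, 40))
        b = np.where(rng.random(40) < 0.4, 0, rng.poisson(20.0, 40))
        assert zip_omnibus_lrt(a, b)[0] == pytest.approx(zip_omnibus_lrt(b, a)[0])

    def test_all_zero_group_flagged(self):
        stat, p, degenerate = zip_omnibus_lrt(np.zeros(5, dtype=int),
                                              np.array([0, 3, 4]))
        assert degenerate


class TestZipComponents:
    def test_equal_zero_fractions_not_significant(self):
        # 34/72-style vs 6/12-style zero fractions (47% vs 50%).
        a = np.array([0] * 34 + [10] * 38)
        b = np.array([0] * 6 + [28] * 6)
        zero_p, _ = zip_component_tests(a, b)
        assert zero_p > 0.5

    def test_identical_positive_counts_p_one(self):
        a = np.array([0, 10, 10, 10])
        b = np.array([0, 10, 10, 10])
        _, count_p = zip_component_tests(a, b)
        assert count_p == pytest.approx(1.0)

    def test_count_component_matches_permutation_enumeration(self):
        # disjoint positive supports {1..10} vs {21..30}: exact rank-sum
        # tail by full enumeration equals 2/C(20,10).
        a = np.arange(1, 11)
        b = np.arange(21, 31)
        exact = stats.permutation_test(
            (a, b), lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent", n_resamples=np.inf,
        ).pvalue
        _, count_p = zip_component_tests(np.r_[0, a], np.r_[0, b])
        assert count_p == pytest.approx(exact, abs=2e-4)

    def test_group_without_positives_reports_missing(self):
        zero_p, count_p = zip_component_tests(np.zeros(4, dtype=int),
                                              np.array([0, 5, 6]))
        assert math.isnan(count_p) and 0 < zero_p <= 1


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    @pytest.mark.parametrize("raw, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.04, 0.2], [0.015, 0.06, 0.2]),
    ])
    def test_worked_step_up_examples(self, raw, expected):
        assert bh_adjust(raw) == pytest.approx(expected)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestDoubleFdr:
    def test_single_group_equals_plain_bh(self, rng):
        p = rng.uniform(0.001, 1.0, size=9)
        out = double_fdr({"g": [(f"h{i}", v) for i, v in enumerate(p)]})
        assert out.adjusted_p.to_numpy() == pytest.approx(bh_adjust(p))

    def test_two_group_worked_example(self):
        out = double_fdr({"G1": [("a", 0.01), ("b", 0.04)],
                          "G2": [("c", 0.50)]}).set_index("hypothesis")
        assert out.loc["a", "adjusted_p"] == pytest.approx(0.02)
        assert out.loc["b", "adjusted_p"] == pytest.approx(0.04)
        assert out.loc["c", "adjusted_p"] == pytest.approx(0.50)

    def test_all_ones_stay_one(self):
        out = double_fdr({"g1": [("a", 1.0)], "g2": [("b", 1.0), ("c", 1.0)]})
        assert (out.adjusted_p == 1.0).all()

    @given(st.lists(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=5),
                    min_size=1, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_dominates_raw_and_within_group(self, group_ps):
        groups = {f"g{i}": [(f"h{i}_{j}", p) for j, p in enumerate(ps)]
                  for i, ps in enumerate(group_ps)}
        out = double_fdr(groups)
        assert (out.adjusted_p >= out.raw_p - 1e-12).all()
        assert (out.adjusted_p >= out.within_group_p - 1e-12).all()
        assert (out.adjusted_p <= 1.0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            double_fdr({"g1": [("a", 0.5)], "g2": []})
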