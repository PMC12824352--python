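"""Effect courses: smoothing, clustering, and permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import torcourse as tc
from conftest import make_dataset
from torcourse.effect_course import _clusters_from_t, _sign_flip_cluster_test

INFO_A = {"cue_informativity": "informative"}
INFO_B = {"cue_informativity": "non_informative"}


def course_dataset(series_by_pid_cond, value=600.0):
    """Dataset where each participant has explicit RT series per condition."""
    recs = []
    for pid, by_cond in series_by_pid_cond.items():
        for cond, values in by_cond.items():
            for v in values:
                recs.append({"participant_id": pid, "cue_informativity": cond, "rt_ms": float(v)})
    return make_dataset(recs).trials


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        x = np.full(20, 600.0)
        np.testing.assert_array_equal(tc.moving_average(x, 11), x)

    def test_window_one_identity(self):
        x = np.arange(15.0)
        np.testing.assert_array_equal(tc.moving_average(x, 1), x)

    def test_linear_series_window_three(self):
        x = np.arange(1.0, 16.0)
        sm = tc.moving_average(x, 3)
        np.testing.assert_allclose(sm[1:-1], x[1:-1])  # interior: mean of k-1,k,k+1 = k
        assert sm[0] == pytest.approx(1.5)  # truncated edge: (1+2)/2
        assert sm[-1] == pytest.approx(14.5)  # (14+15)/2

    def test_length_preserved(self):
        for n in (1, 5, 11, 30):
            assert tc.moving_average(np.random.default_rng(0).normal(size=n), 11).size == n

    def test_interior_mean_conservation(self):
        x = np.random.default_rng(1).normal(600, 50, 33)
        sm = tc.moving_average(x, 11)
        # interior smoothed values are plain window means
        for k in range(5, 28):
            assert sm[k] == pytest.approx(x[k - 5 : k + 6].mean())


class TestOrderAndSmooth:
    def test_orders_by_occurrence(self):
        data = course_dataset({"P00": {"informative": [10, 20, 30, 40, 50]}})
        cfg = tc.EffectCourseConfig(window=1)
        courses = tc.order_and_smooth(data, INFO_A, cfg)
        np.testing.assert_array_equal(courses["P00"], [10, 20, 30, 40, 50])

    def test_participant_without_trials_omitted(self):
        data = course_dataset(
            {"P00": {"informative": [1, 2]}, "P01": {"non_informative": [1, 2]}}
        )
        courses = tc.order_and_smooth(data, INFO_A, tc.EffectCourseConfig(window=1))
        assert set(courses) == {"P00"}


class TestTrialwiseTests:
    def test_equal_conditions_all_zero_t(self):
        data = course_dataset(
            {f"P{i}": {"informative": [600, 610, 620], "non_informative": [600, 610, 620]}
             for i in range(4)}
        )
        cfg = tc.EffectCourseConfig(window=1)
        ec = tc.trialwise_tests(
            tc.order_and_smooth(data, INFO_A, cfg), tc.order_and_smooth(data, INFO_B, cfg), cfg
        )
        np.testing.assert_array_equal(ec.t, np.zeros(3))

    def test_analyzed_length_is_min_across_participants(self):
        data = course_dataset(
            {"P00": {"informative": [1] * 10, "non_informative": [2] * 10},
             "P01": {"informative": [1] * 7, "non_informative": [2] * 9},
             "P02": {"informative": [1] * 8, "non_informative": [2] * 8}}
        )
        cfg = tc.EffectCourseConfig(window=1)
        ec = tc.trialwise_tests(
            tc.order_and_smooth(data, INFO_A, cfg), tc.order_and_smooth(data, INFO_B, cfg), cfg
        )
        assert ec.analyzed_length == 7

    def test_simulated_benefit_gives_negative_course(self):
        design = tc.build_design(tc.DesignConfig(n_participants=15, seed=51))
        params = tc.SimulationParams(seed=52, modulation_amplitude_ms=0.0, omission_rate=0.0)
        ds = tc.simulate_dataset(design, params)
        data = ds.trials[~ds.trials.is_filler]
        cfg = tc.EffectCourseConfig()
        ec = tc.trialwise_tests(
            tc.order_and_smooth(data, {**INFO_A, "interruption": "absent"}, cfg),
            tc.order_and_smooth(data, {**INFO_B, "interruption": "absent"}, cfg),
            cfg,
        )
        assert (ec.mean_diff < 0).all()

    def test_no_smoothing_equals_raw_ordered_differences(self):
        rng = np.random.default_rng(3)
        series = {
            f"P{i}": {
                "informative": rng.normal(580, 20, 12),
                "non_informative": rng.normal(620, 20, 12),
            }
            for i in range(5)
        }
        data = course_dataset(series)
        cfg = tc.EffectCourseConfig(window=1, sample_alpha=0.999999)
        ec = tc.trialwise_tests(
            tc.order_and_smooth(data, INFO_A, cfg), tc.order_and_smooth(data, INFO_B, cfg), cfg
        )
        raw = np.mean(
            [series[p]["informative"] - series[p]["non_informative"] for p in series], axis=0
        )
        np.testing.assert_allclose(ec.mean_diff, raw)


class TestClusters:
    def make_course(self, t):
        t = np.asarray(t, dtype=float)
        n = 10
        p = 2 * stats.t.sf(np.abs(t), n - 1)
        return tc.EffectCourse(
            condition_a=INFO_A, condition_b=INFO_B, mean_diff=t, se=np.ones_like(t), t=t,
            p=p, d_z=t / np.sqrt(n), n=n, analyzed_length=t.size,
            participants=list(range(n)), diffs=np.zeros((n, t.size)),
        )

    def test_no_significant_indices_no_clusters(self):
        course = self.make_course(np.full(10, 0.5))
        assert tc.form_clusters(course, tc.EffectCourseConfig()) == []

    def test_uniform_significant_run_mass(self):
        course = self.make_course(np.full(10, -2.0))
        clusters = tc.form_clusters(course, tc.EffectCourseConfig())
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start_index, c.end_index, c.sign) == (1, 10, -1)
        assert c.mass_T == pytest.approx(-20.0)

    def test_sign_change_splits_clusters(self):
        t = np.zeros(12)
        t[[2, 3, 4]] = -3.0
        t[[8, 9]] = 3.0
        clusters = tc.form_clusters(self.make_course(t), tc.EffectCourseConfig())
        assert [(c.start_index, c.end_index, c.sign) for c in clusters] == [(3, 5, -1), (9, 10, 1)]

    def test_mass_additivity(self):
        rng = np.random.default_rng(8)
        t = rng.normal(0, 2, 40)
        course = self.make_course(t)
        for c in tc.form_clusters(course, tc.EffectCourseConfig()):
            assert abs(c.mass_T - t[c.start_index - 1 : c.end_index].sum()) < 1e-9


class TestPermutation:
    def test_same_seed_identical_result(self):
        rng = np.random.default_rng(17)
        D = rng.normal(5, 12, (8, 20))
        cfg = tc.EffectCourseConfig(window=1, n_permutations=300, seed=5)
        a = _sign_flip_cluster_test(D, INFO_A, INFO_B, list(range(8)), cfg)
        b = _sign_flip_cluster_test(D, INFO_A, INFO_B, list(range(8)), cfg)
        assert [c.p_perm for c in a.clusters] == [c.p_perm for c in b.clusters]

    def test_p_floor_reached_for_strong_effect(self):
        rng = np.random.default_rng(2)
        D = rng.normal(-40, 5, (12, 30))
        cfg = tc.EffectCourseConfig(window=1, n_permutations=500, seed=1)
        res = _sign_flip_cluster_test(D, INFO_A, INFO_B, list(range(12)), cfg)
        assert min(c.p_perm for c in res.clusters) == pytest.approx(1 / 501)

    def test_matches_exhaustive_enumeration(self):
        """MC permutation p agrees with the exact sign-flip null on 5 participants."""
        rng = np.random.default_rng(7)
        D = rng.normal(8, 10, (5, 12))
        cfg = tc.EffectCourseConfig(window=1, sample_alpha=0.1, n_permutations=20000, seed=3)
        res = _sign_flip_cluster_test(D, INFO_A, INFO_B, list("abcde"), cfg)

        n = D.shape[0]
        exact_stats = []
        for signs in itertools.product([-1, 1], repeat=n):
            X = np.array(signs)[:, None] * D
            t = X.mean(0) / (X.std(0, ddof=1) / np.sqrt(n))
            p = 2 * stats.t.sf(np.abs(t), n - 1)
            cl = _clusters_from_t(t, p, cfg.sample_alpha)
            exact_stats.append(max((abs(c.mass_T) for c in cl), default=0.0))
        exact_stats = np.array(exact_stats)
        for c in res.clusters:
            exact_p = (exact_stats >= abs(c.mass_T)).mean()
            assert c.p_perm == pytest.approx(exact_p, abs=0.02)

    def test_full_pipeline_deterministic(self, small_clean):
        cfg = tc.EffectCourseConfig(n_permutations=200, seed=9)
        cond_a = {**INFO_A, "interruption": "absent"}
        cond_b = {**INFO_B, "interruption": "absent"}
        a = tc.permutation_test(small_clean.takeover_rt, cond_a, cond_b, cfg)
        b = tc.permutation_test(small_clean.takeover_rt, cond_a, cond_b, cfg)
        assert a.cluster_frame().equals(b.cluster_frame())

    def test_pooled_alternative_runs(self, small_clean):
        cfg = tc.EffectCourseConfig(n_permutations=200, seed=9, max_cluster_rule=False)
        res = tc.permutation_test(
            small_clean.takeover_rt,
            {**INFO_A, "interruption": "absent"},
            {**INFO_B, "interruption": "absent"},
            cfg,
        )
        assert all(0 < c.p_perm <= 1 for c in res.clusters)


class TestDifferenceCourse:
    def test_identical_effect_courses_no_clusters(self):
        rng = np.random.default_rng(4)
        series = {}
        for i in range(6):
            eff = rng.normal(-40, 5, 10)
            base_a = rng.normal(600, 10, 10)
            base_b = rng.normal(610, 10, 10)
            series[f"P{i}"] = {
                ("informative", "absent"): base_a + eff,
                ("non_informative", "absent"): base_a,
                ("informative", "present"): base_b + eff,
                ("non_informative", "present"): base_b,
            }
        recs = []
        for pid, by_cond in series.items():
            for (info, intr), values in by_cond.items():
                for v in values:
                    recs.append(
                        {"participant_id": pid, "cue_informativity": info,
                         "interruption": intr, "rt_ms": float(v),
                         "rt_ldt_ms": 700.0 if intr == "present" else np.nan,
                         "correct_ldt": True if intr == "present" else pd.NA}
                    )
        data = make_dataset(recs).trials
        cfg = tc.EffectCourseConfig(window=1, n_permutations=100, seed=2)
        res = tc.difference_course(
            data,
            ({**INFO_A, "interruption": "absent"}, {**INFO_B, "interruption": "absent"}),
            ({**INFO_A, "interruption": "present"}, {**INFO_B, "interruption": "present"}),
            cfg,
        )
        # interaction scores cancel to the base-series difference noise only;
        # smoothed effect courses subtract to ~0 where effects are identical
        np.testing.assert_allclose(res.course.mean_diff, 0.0, atol=1e-9)
        assert res.clusters == []

    def test_no_common_participants_rejected(self):
        data = course_dataset({"P00": {"informative": [1, 2]}})
        with pytest.raises(ValueError):
            tc.difference_course(
                data,
                ({**INFO_A, "interruption": "absent"}, {**INFO_B, "interruption": "absent"}),
                ({**INFO_A, "interruption": "present"}, {**INFO_B, "interruption": "present"}),
                tc.EffectCourseConfig(window=1),
            )
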