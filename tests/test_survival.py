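"""Survival battery: KM, log-rank, threshold sweep, Cox, TVN, auxiliary tests."""

import itertools
import math

import numpy as np
import pytest

from metmorph import MorphFeatures, LesionTimepoint
from metmorph.cohort import CohortRecord, CohortSimConfig, simulate_cohort
from metmorph.survival import (
    ProgressionCriterion,
    TVNCoefficients,
    cox_stepwise,
    cox_univariate,
    km_estimate,
    ks_normality,
    logrank,
    median_difference,
    progression_time,
    select_non_isolated,
    spearman,
    threshold_sweep,
    tvn_score,
    wilcoxon_signed_rank,
)

from conftest import exponential_records


def records(times, events, x=None):
    return [
        CohortRecord(f"r{i}", {} if x is None else {"x": x[i]}, t, bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


def lesion_series(volumes, times):
    def feats(v):
        return MorphFeatures(
            total_volume=v, necrotic_volume=0.0, ce_volume=v,
            surface_area=1.0, surface_regularity=1.0, rim_width=0.1, has_necrosis=False,
        )

    return [LesionTimepoint("L", t, feats(v)) for v, t in zip(volumes, times)]


class TestProgressionTime:
    def test_default_criterion_worked_example(self):
        series = lesion_series([1.0, 0.5, 0.8, 1.3], [-0.5, 3, 6, 9])
        assert progression_time(series) == (6, True)  # 0.8 >= 1.2 * 0.5 and +0.3 cm^3

    def test_monotone_shrinkage_is_censored(self):
        series = lesion_series([1.0, 0.8, 0.6, 0.5], [-0.5, 3, 6, 9])
        assert progression_time(series) == (9, False)

    def test_single_followup_equal_to_pre_is_censored(self):
        series = lesion_series([1.0, 1.0], [-0.5, 3])
        assert progression_time(series) == (3, False)

    def test_absolute_floor_blocks_tiny_regrowth(self):
        # 50% relative regrowth but only 0.05 cm^3 absolute: below the floor
        series = lesion_series([0.2, 0.1, 0.15], [-0.5, 3, 6])
        assert progression_time(series) == (6, False)

    def test_configurable_criterion(self):
        series = lesion_series([0.2, 0.1, 0.15], [-0.5, 3, 6])
        loose = ProgressionCriterion(relative_increase=0.2, absolute_floor=0.0)
        assert progression_time(series, loose) == (6, True)

    def test_missing_followups_rejected(self):
        with pytest.raises(ValueError):
            progression_time(lesion_series([1.0], [-0.5]))


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate(records([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_hand_product_limit_with_censoring(self):
        km = km_estimate(records([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 2 / 3, 0.0])
        assert km.median == 3.0

    def test_all_censored_survival_stays_one(self):
        km = km_estimate(records([1, 2], [0, 0]))
        assert (km.survival == 1.0).all()
        assert km.median is None

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(records([-1, 2], [1, 1]))


def hand_logrank(times_a, events_a, times_b, events_b):
    """Independent O-E/V log-rank computed directly from the pooled grid."""
    times = np.concatenate([times_a, times_b]).astype(float)
    events = np.concatenate([events_a, events_b]).astype(bool)
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n, n_a = at_risk.sum(), (at_risk & (group == 0)).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & (group == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_six_subject_fixture_matches_hand_computation(self):
        ga = records([1, 3, 5], [1, 1, 1])
        gb = records([2, 4, 6], [1, 1, 1])
        stat, p = logrank(ga, gb)
        expected = hand_logrank([1, 3, 5], [1, 1, 1], [2, 4, 6], [1, 1, 1])
        assert stat == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.48487626, rel=1e-6)  # frozen from the oracle

    def test_censored_fixture_matches_hand_computation(self):
        stat, _ = logrank(records([2, 4, 5, 9], [1, 0, 1, 1]), records([1, 3, 6], [1, 1, 0]))
        expected = hand_logrank([2, 4, 5, 9], [1, 0, 1, 1], [1, 3, 6], [1, 1, 0])
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_identical_groups_give_zero_statistic(self):
        g = records([1, 2, 3, 4], [1, 1, 0, 1])
        stat, p = logrank(g, list(g))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_in_group_order_and_time_rescaling(self):
        ga = records([1, 3, 5, 7], [1, 1, 0, 1])
        gb = records([2, 4, 6], [1, 0, 1])
        assert logrank(ga, gb)[0] == pytest.approx(logrank(gb, ga)[0])
        ga2 = records([10, 30, 50, 70], [1, 1, 0, 1])
        gb2 = records([20, 40, 60], [1, 0, 1])
        assert logrank(ga, gb)[0] == pytest.approx(logrank(ga2, gb2)[0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank(records([1, 2], [0, 0]), records([3], [0]))

    def test_power_at_hazard_ratio_three(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            ga = exponential_records(rng, 200, 0.05)
            gb = exponential_records(rng, 200, 0.15)
            _, p = logrank(ga, gb)
            hits += p < 0.001
        assert hits >= 29


class TestNonIsolatedSelection:
    def test_isolated_spike_is_rejected(self):
        assert select_non_isolated([0.5, 0.01, 0.6, 0.7], 0.05) is None

    def test_adjacent_pair_selects_lowest_p(self):
        assert select_non_isolated([0.5, 0.03, 0.01, 0.6], 0.05) == 2

    def test_nothing_significant(self):
        assert select_non_isolated([0.2, 0.3, 0.4], 0.05) is None

    def test_isolated_global_minimum_rejected_for_non_isolated_runner_up(self):
        assert select_non_isolated([0.04, 0.02, 0.6, 0.001, 0.6], 0.05) == 1


class TestThresholdSweep:
    @staticmethod
    def step_cohort(rng, n, cut=5.0, hr=3.0):
        x = rng.uniform(0, 10, n)
        hazards = 0.05 * np.where(x > cut, hr, 1.0)
        return exponential_records(rng, n, hazards, censor_rate=0.02, covariates={"x": x})

    def test_step_hazard_changepoint_recovered(self):
        hits = 0
        for seed in range(10):
            recs = self.step_cohort(np.random.default_rng(50 + seed), 400)
            result = threshold_sweep(recs, "x", grid=41)
            if result.significant and 4.5 <= result.selected_threshold <= 5.5:
                hits += 1
        assert hits >= 8

    def test_recovery_sharpens_with_sample_size(self):
        errs = []
        for n in (200, 400, 800):
            sel = []
            for seed in range(8):
                recs = self.step_cohort(np.random.default_rng(7000 + seed), n)
                result = threshold_sweep(recs, "x", grid=41)
                if result.significant:
                    sel.append(abs(result.selected_threshold - 5.0))
            errs.append(np.mean(sel))
        assert errs[2] < errs[0]

    def test_null_covariate_reports_profile_without_asserting_selection(self):
        rng = np.random.default_rng(99)
        recs = exponential_records(rng, 100, 0.1, covariates={"x": rng.uniform(0, 1, 100)})
        result = threshold_sweep(recs, "x")
        assert len(result.candidates) == len(result.p_values) > 0
        assert (result.group_sizes.sum(axis=1) == 100).all()

    def test_min_group_fraction_excludes_extreme_splits(self):
        rng = np.random.default_rng(5)
        recs = self.step_cohort(rng, 100)
        result = threshold_sweep(recs, "x", min_group_fraction=0.2)
        assert (result.group_sizes >= 20).all()

    def test_constant_covariate_rejected(self):
        recs = records([1, 2, 3], [1, 1, 1], x=[1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            threshold_sweep(recs, "x")


class TestMedianDifference:
    def test_identical_curves(self):
        km = km_estimate(records([1, 2, 3, 4], [1, 1, 1, 1]))
        assert median_difference(km, km) == 0.0

    def test_exponential_arms_with_known_medians(self):
        rng = np.random.default_rng(12)
        km_a = km_estimate(exponential_records(rng, 2000, math.log(2) / 5.0))
        km_b = km_estimate(exponential_records(rng, 2000, math.log(2) / 12.0))
        assert median_difference(km_a, km_b) == pytest.approx(7.0, abs=1.0)

    def test_undefined_median_flagged(self):
        km_defined = km_estimate(records([1, 2], [1, 1]))
        km_undefined = km_estimate(records([1, 2], [0, 0]))
        assert median_difference(km_defined, km_undefined) is None


class TestCox:
    def test_toy_fixture_matches_brute_force_partial_likelihood(self):
        # 4 records / 3 events; the 1-D partial likelihood has an interior max
        recs = records([1, 2, 3, 4], [1, 1, 1, 0], x=[1.0, 0.0, 1.0, 0.0])

        def log_pl(beta):
            # risk sets: t=1 {x=1,0,1,0}; t=2 {0,1,0}; t=3 {1,0}
            e = math.exp(beta)
            return (beta - math.log(2 * e + 2)) + (0 - math.log(e + 2)) + (beta - math.log(e + 1))

        grid = np.linspace(-3, 3, 20001)
        beta_scan = grid[np.argmax([log_pl(b) for b in grid])]
        fit = cox_univariate(recs, "x")
        assert fit.coef["x"] == pytest.approx(beta_scan, abs=1e-3)
        assert fit.hazard_ratio["x"] == pytest.approx(math.exp(beta_scan), rel=1e-3)
        assert fit.ci_lower["x"] < fit.hazard_ratio["x"] < fit.ci_upper["x"]

    def test_binary_covariate_recovery_short(self):
        config = CohortSimConfig(
            n_lesions=500,
            baseline_hazard=0.05,
            covariate_distributions={"g": {"dist": "bernoulli", "p": 0.5}},
            log_hazard_coefficients={"g": math.log(2)},
            censoring_rate=0.02,
            max_followup=60.0,
            seed=42,
        )
        fit = cox_univariate(simulate_cohort(config), "g")
        assert fit.hazard_ratio["g"] == pytest.approx(2.0, rel=0.25)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(records([1, 2, 3], [1, 1, 1], x=[2.0, 2.0, 2.0]), "x")


class TestStepwise:
    @staticmethod
    def two_covariate_cohort(seed, beta_signal=math.log(2)):
        config = CohortSimConfig(
            n_lesions=500,
            baseline_hazard=0.05,
            covariate_distributions={
                "signal": {"dist": "bernoulli", "p": 0.5},
                "noise": {"dist": "normal", "mean": 0, "sd": 1},
            },
            log_hazard_coefficients={"signal": beta_signal},
            censoring_rate=0.02,
            max_followup=60.0,
            seed=seed,
        )
        return simulate_cohort(config)

    def test_strong_covariate_retained(self):
        fit = cox_stepwise(self.two_covariate_cohort(3), ["signal", "noise"])
        assert "signal" in fit.covariates

    def test_all_noise_may_yield_empty_model(self):
        recs = self.two_covariate_cohort(8, beta_signal=0.0)
        fit = cox_stepwise(recs, ["signal", "noise"], removal_alpha=0.001)
        assert set(fit.covariates) | set(fit.eliminated) == {"signal", "noise"}

    def test_single_candidate_rejected(self):
        with pytest.raises(ValueError):
            cox_stepwise(self.two_covariate_cohort(1), ["signal"])


class TestTVN:
    def test_zero_ratio_no_necrosis(self):
        assert tvn_score(0.0, False) == 0.0

    def test_printed_coefficients(self):
        assert tvn_score(1.0, True) == pytest.approx(0.423)

    def test_monotone_in_both_inputs(self):
        assert tvn_score(2.0, False) > tvn_score(1.0, False)
        assert tvn_score(1.0, True) > tvn_score(1.0, False)

    def test_zero_necrosis_weight_reduces_to_ratio_ranking(self):
        coeffs = TVNCoefficients(weight_volume_ratio=0.084, weight_necrosis=0.0)
        ratios = [0.2, 1.5, 0.7, 3.0]
        scores = [tvn_score(r, bool(i % 2), coeffs) for i, r in enumerate(ratios)]
        assert np.argsort(scores).tolist() == np.argsort(ratios).tolist()

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            tvn_score(-0.1, False)


class TestWilcoxon:
    def test_exact_p_matches_sign_enumeration_at_n8(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(size=8)
        post = pre + rng.normal(0.5, 1.0, 8)
        d = post - pre
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        dist = np.array([
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=8)
        ])
        p_enum = min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))
        assert wilcoxon_signed_rank(pre, post) == pytest.approx(p_enum, rel=1e-12)

    def test_symmetric_perturbation_is_nonsignificant(self):
        pre = np.arange(1.0, 11.0)
        post = pre + np.resize([0.5, -0.5], 10)
        assert wilcoxon_signed_rank(pre, post) > 0.9

    def test_uniform_decrease_is_highly_significant(self):
        # all 20 post values below pre, as in a cohort-wide SR drop
        rng = np.random.default_rng(0)
        pre = rng.uniform(0.5, 1.0, 20)
        post = pre - rng.uniform(0.05, 0.2, 20)
        assert wilcoxon_signed_rank(pre, post) < 0.001

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestSpearman:
    def test_strictly_monotone_pair(self):
        rho, strong = spearman([1, 2, 3, 4], [10, 20, 25, 90])
        assert rho == 1.0 and strong

    def test_reversed_pair(self):
        rho, strong = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == -1.0 and not strong

    def test_tied_fixture_matches_rank_formula(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0]

        def ranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                r[order[i:j]] = (i + j - 1) / 2 + 1
                i = j
            return r

        rx, ry = ranks(x), ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestKSNormality:
    def test_calibration_on_normal_samples(self):
        rejections = 0
        for seed in range(200):
            x = np.random.default_rng(seed).normal(size=200)
            _, p, _ = ks_normality(x)
            rejections += p < 0.05
        assert 0.02 <= rejections / 200 <= 0.10

    def test_rejects_exponential_samples(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).exponential(size=200)
            _, p, _ = ks_normality(x)
            rejections += p < 0.05
        assert rejections >= 38

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])

    def test_correction_is_flagged(self):
        _, _, note = ks_normality(np.random.default_rng(1).normal(size=50))
        assert "lilliefors" in note
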