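import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cpdscreen.calibration import (
    NEOPLASTIC_CONTRAST,
    Contrast,
    DegenerateDataError,
    DiscriminantCalibrator,
    InfeasibleCutoffError,
    build_composite,
    group_difference_test,
    ks_normality,
    multi_group_screen,
    roc,
    screen_parameters,
    select_cutoff,
)
from cpdscreen.simulate import SCREENING_PARAMETERS


def pair_counting_auc(pos, neg):
    """Brute-force Mann-Whitney AUC oracle: wins + half-ties over all pairs."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestNormality:
    def test_nominal_level_on_gaussian_data(self):
        # rejection rate of the 5%-level test across 100 seeded replicates
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=500)
            if ks_normality(x) < 0.05:
                rejections += 1
        assert 1 <= rejections <= 12  # ~5 expected, binomial slack

    def test_power_against_exponential(self):
        x = np.random.default_rng(7).exponential(size=500)
        assert ks_normality(x) < 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            ks_normality([2.0] * 50)


class TestGroupDifference:
    def test_identical_samples_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert group_difference_test(a, list(a)).p_value == pytest.approx(1.0)

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 40), rng.normal(0.4, 1.3, 40)
        assert group_difference_test(a, b).p_value == pytest.approx(
            group_difference_test(b, a).p_value
        )

    def test_large_effect_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 50), rng.normal(3, 1, 50)
        res = group_difference_test(a, b)
        assert res.p_value < 1e-3
        perm = stats.permutation_test(
            (a, b), lambda x, y: np.mean(x) - np.mean(y),
            n_resamples=2000, random_state=0,
        )
        assert perm.pvalue < 1e-3

    def test_welch_default_student_by_flag(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 3, 50)
        welch = group_difference_test(a, b).p_value
        student = group_difference_test(a, b, equal_var=True).p_value
        assert welch == pytest.approx(stats.ttest_ind(a, b, equal_var=False).pvalue)
        assert student == pytest.approx(stats.ttest_ind(a, b, equal_var=True).pvalue)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            group_difference_test([1.0, 1.0], [2.0, 2.0])


class TestMultiGroupScreen:
    def test_equal_variances_take_tukey_branch(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(0, 1, 30) for k in "abc"}
        res = multi_group_screen(groups)
        assert res.homogeneous and res.test_used == "anova_tukey"

    def test_unequal_variances_take_games_howell_branch(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
                  "c": rng.normal(0, 8, 40)}
        res = multi_group_screen(groups)
        assert not res.homogeneous
        assert res.test_used == "welch_anova_games_howell"
        assert res.omnibus_p == res.welch_p

    def test_shifted_group_drives_pairwise_significance(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30),
                  "c": rng.normal(5, 1, 30)}
        res = multi_group_screen(groups)
        assert res.omnibus_p < 1e-3 and res.selected
        # oracle: pairwise Welch t-tests with Bonferroni
        for (g1, g2), p in res.pairwise_p.items():
            t_p = stats.ttest_ind(groups[g1], groups[g2], equal_var=False).pvalue * 3
            if "c" in (g1, g2):
                assert p < 0.01 and t_p < 0.01
            else:
                assert p > 0.05 and min(t_p, 1) > 0.05

    def test_null_type_one_error_calibrated(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            groups = {k: rng.normal(0, 1, 25) for k in "abc"}
            if multi_group_screen(groups).selected:
                hits += 1
        assert hits <= 22  # ~5% of 200 expected; ~4 sd slack

    def test_degenerate_group_named(self):
        with pytest.raises(DegenerateDataError, match="'b'"):
            multi_group_screen({"a": [1.0, 2.0], "b": [3.0, 3.0], "c": [1.0, 0.0]})


class TestROC:
    def test_four_pair_example(self):
        r = roc([3, 5, 1, 4], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)
        assert r.orientation == "high_is_positive"

    def test_perfect_separation(self):
        r = roc([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert r.auc == 1.0
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]

    def test_orientation_flips_when_low_scores_mark_positives(self):
        r = roc([1, 2, 10, 11], [1, 1, 0, 0])
        assert r.orientation == "low_is_positive"
        assert r.auc == 1.0

    def test_permuted_labels_give_null_auc(self):
        rng = np.random.default_rng(42)
        values = rng.normal(size=200)
        labels = rng.permutation([1] * 100 + [0] * 100)
        r = roc(values, labels)
        assert 0.5 <= r.auc <= 0.58  # null band; AUC reported >= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_sweep_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(2, 60, size=2)
        # coarse grid forces ties within and across classes
        pos = rng.integers(0, 12, n_pos).astype(float)
        neg = rng.integers(0, 12, n_neg).astype(float)
        values = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
        r = roc(values, labels)
        oracle = pair_counting_auc(pos, neg)
        assert r.auc == pytest.approx(max(oracle, 1 - oracle), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=120)
        labels = rng.integers(0, 2, 120)
        labels[0], labels[1] = 0, 1
        a = roc(values, labels).auc
        b = roc(np.exp(values), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_delong_ci_contains_auc_and_matches_hanley_scale(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(1, 1, 80), rng.normal(0, 1, 80)])
        labels = np.array([1] * 80 + [0] * 80)
        d = roc(values, labels, ci_method="delong")
        h = roc(values, labels, ci_method="hanley")
        for r in (d, h):
            assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]
        assert abs((d.auc_ci[1] - d.auc_ci[0]) - (h.auc_ci[1] - h.auc_ci[0])) < 0.05


class TestSelectCutoff:
    def test_tie_break_prefers_lower_threshold(self):
        r = select_cutoff(roc([3, 5, 1, 4], [1, 1, 0, 0]))
        assert r.chosen_cutoff == 2.0
        assert (r.sens_at_cutoff, r.spec_at_cutoff) == (1.0, 0.5)

    def test_separated_classes_midpoint(self):
        r = select_cutoff(roc([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0]))
        assert r.chosen_cutoff == 6.5
        assert r.sens_at_cutoff == r.spec_at_cutoff == 1.0

    def test_constrained_policy_infeasible(self):
        with pytest.raises(InfeasibleCutoffError):
            select_cutoff(roc([3, 5, 1, 4], [1, 1, 0, 0]), policy="constrained")

    def test_constrained_policy_feasible(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(3, 1, 100), rng.normal(0, 1, 100)])
        labels = np.array([1] * 100 + [0] * 100)
        r = select_cutoff(roc(values, labels), policy="constrained")
        assert r.sens_at_cutoff >= 0.8 and r.spec_at_cutoff >= 0.8

    def test_order_independence(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        a = select_cutoff(roc(values, labels))
        perm = rng.permutation(80)
        b = select_cutoff(roc(values[perm], labels[perm]))
        assert a.chosen_cutoff == b.chosen_cutoff


class TestScreenAndComposite:
    def test_recovers_configured_parameters_in_auc_order(self, paper_like_cohort):
        results = screen_parameters(paper_like_cohort, NEOPLASTIC_CONTRAST, auc_min=0.9)
        names = [str(r.parameter) for r in results]
        assert sorted(names) == sorted(SCREENING_PARAMETERS)
        aucs = [r.auc for r in results]
        assert aucs == sorted(aucs, reverse=True)

    def test_vacuous_auc_threshold_empty(self, paper_like_cohort):
        assert screen_parameters(paper_like_cohort, NEOPLASTIC_CONTRAST, auc_min=1.1) == []

    def test_composite_orientation_split_and_improvement(self, paper_like_cohort):
        results = screen_parameters(paper_like_cohort, NEOPLASTIC_CONTRAST, auc_min=0.9)
        rule, comp_roc = build_composite(paper_like_cohort, NEOPLASTIC_CONTRAST, results)
        assert {str(p) for p in rule.numerator} == {"SD-V-NE", "MN-UMALS-LY", "SD-AL2-MO"}
        assert {str(p) for p in rule.denominator} == {"MN-C-NE"}
        assert comp_roc.auc >= max(r.auc for r in results)

    def test_all_positive_orientations_give_pure_product(self, paper_like_cohort):
        results = screen_parameters(paper_like_cohort, NEOPLASTIC_CONTRAST, auc_min=0.9)
        highs = [r for r in results if r.orientation == "high_is_positive"]
        rule, _ = build_composite(paper_like_cohort, NEOPLASTIC_CONTRAST, highs)
        assert rule.denominator == ()

    def test_calibrator_sklearn_api(self, paper_like_cohort, paper_like_frame):
        y = (paper_like_frame["group"].str.lower()
             .map(paper_like_cohort.label_scheme) == "neoplastic")
        X = paper_like_frame.drop(columns=["group"])
        cal = DiscriminantCalibrator().fit(X, y.to_numpy())
        assert cal.get_params()["auc_min"] == 0.9
        assert cal.rule_.cutoff > 0
        pred = cal.predict(X)
        acc = (pred == np.where(y, "neoplastic", "non-neoplastic")).mean()
        assert acc > 0.95
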