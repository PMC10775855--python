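import itertools

import numpy as np
import pytest
from scipy import stats

from stereoscreen.evalstats import (AdjustMethod, ContingencyTable,
                                    adjust_pvalues, delong_compare,
                                    evaluate_screening, fisher_exact,
                                    mcnemar_exact, optimal_point,
                                    pearson_chi2, proportion_ci, roc_auc)


def pair_enumeration_auc(path_scores, norm_scores):
    """Brute-force AUC: fraction of (pathologic, normal) pairs ranked
    correctly, ties counted one half. Higher score = more normal."""
    total = 0.0
    for p, n in itertools.product(path_scores, norm_scores):
        if p < n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(path_scores) * len(norm_scores))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0, 1, 4, 5], [True, True, False, False])
        assert r.auc == 1.0

    def test_all_ties_is_chance(self):
        r = roc_auc([3, 3, 3, 3], [True, True, False, False])
        assert r.auc == 0.5

    def test_small_instance_matches_pair_enumeration(self):
        r = roc_auc([1, 2, 3, 2, 3, 4], [1, 1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(7 / 9)

    def test_random_instances_match_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m, n = rng.integers(2, 10, 2)
            path = rng.integers(0, 6, m)
            norm = rng.integers(0, 6, n)
            scores = np.concatenate([path, norm]).astype(float)
            labels = np.arange(m + n) < m
            assert roc_auc(scores, labels).auc == pytest.approx(
                pair_enumeration_auc(path, norm), abs=1e-12)

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = np.arange(60) < 25
        r = roc_auc(scores, labels)
        assert (np.diff(r.sensitivity) >= 0).all()
        assert (np.diff(r.specificity) <= 0).all()

    def test_matches_independent_reference_implementation(self):
        # frozen from an independent DeLong implementation (R pROC) on this
        # exact instance
        labels = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0], bool)
        a = np.array([1, 2, 2, 3, 0, 4, 3, 4, 4, 5, 2, 5, 3, 4], float)
        r = roc_auc(a, labels)
        assert r.auc == pytest.approx(0.84375, abs=1e-10)
        assert r.auc_se == pytest.approx(0.1076500890, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [True, True, True])

    def test_ci_coverage_near_nominal(self):
        # 95% DeLong CI coverage over repeated draws from a known model
        rng = np.random.default_rng(7)
        true_auc = stats.norm.cdf(1.0 / np.sqrt(2))  # unit shift, unit sd
        hits = 0
        for _ in range(1000):
            path = rng.normal(0, 1, 40)
            norm = rng.normal(1, 1, 40)
            scores = np.concatenate([path, norm])
            labels = np.arange(80) < 40
            ci = roc_auc(scores, labels).ci
            hits += ci[0] <= true_auc <= ci[1]
        assert 0.92 <= hits / 1000 <= 0.98


class TestDelongCompare:
    def test_identical_scores_give_p_one(self):
        scores = np.array([1, 2, 3, 4, 5, 0], float)
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        cmp_ = delong_compare(scores, scores, labels)
        assert cmp_.delta == 0.0 and cmp_.p == 1.0

    def test_matches_independent_reference_implementation(self):
        # frozen from an independent paired DeLong test (R pROC)
        labels = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0], bool)
        a = np.array([1, 2, 2, 3, 0, 4, 3, 4, 4, 5, 2, 5, 3, 4], float)
        b = np.array([0, 1, 3, 2, 2, 3, 4, 3, 5, 4, 3, 5, 2, 4], float)
        cmp_ = delong_compare(a, b, labels)
        assert cmp_.statistic == pytest.approx(-0.5338691662, abs=1e-9)
        assert cmp_.p == pytest.approx(0.5934320561, abs=1e-9)

    def test_correlation_reduces_variance_of_difference(self, default_cohort_frame):
        # two positively correlated informative scores: paired variance of
        # the AUC difference is below the sum of the marginal variances
        frame = default_cohort_frame
        y = frame["group"].isin(["amblyopia", "amblyogenic"]).to_numpy()
        a = frame["s_srds8"].to_numpy(float)
        b = (frame["s_srds8"] + frame["s_drds1"]).to_numpy(float)
        ra, rb = roc_auc(a, y), roc_auc(b, y)
        cmp_ = delong_compare(a, b, y)
        var_delta = (cmp_.delta / cmp_.statistic) ** 2
        assert var_delta < ra.auc_se ** 2 + rb.auc_se ** 2

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1, 2], [1, 2, 3], [True, False, True])


class TestOptimalPoint:
    def test_perfect_score_reaches_youden_one(self):
        r = roc_auc([0, 1, 4, 5], [True, True, False, False])
        _, sens, spec = optimal_point(r)
        assert sens == 1.0 and spec == 1.0

    def test_tie_broken_toward_sensitivity(self):
        # two thresholds with equal J: prefer the more sensitive one
        from stereoscreen.evalstats import ROCResult
        r = ROCResult(thresholds=np.array([1.0, 2.0]),
                      sensitivity=np.array([0.7, 0.9]),
                      specificity=np.array([0.9, 0.7]),
                      auc=0.8, auc_se=0.1, ci=(0.6, 1.0))
        _, sens, _ = optimal_point(r)
        assert sens == 0.9

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 21, 50).astype(float)
        labels = np.arange(50) < 20
        r = roc_auc(scores, labels)
        _, sens, spec = optimal_point(r)
        best_j = -np.inf
        for t in np.unique(scores):
            s = (scores[labels] <= t).mean()
            p = (scores[~labels] > t).mean()
            best_j = max(best_j, s + p - 1)
        assert sens + spec - 1 == pytest.approx(best_j)


class TestMcNemar:
    @pytest.mark.parametrize("b,c,expected", [
        (3, 3, 1.0),
        (1, 9, 0.021484375),
        (0, 0, 1.0),
    ])
    def test_closed_form_values(self, b, c, expected):
        assert mcnemar_exact(b, c).p == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_exact(-1, 2)

    def test_agrees_with_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b in range(0, 13):
            for c in range(0, 13 - b):
                if b + c == 0:
                    continue
                ours = mcnemar_exact(b, c).p
                theirs = sm_mcnemar([[0, b], [c, 0]], exact=True).pvalue
                assert ours == pytest.approx(theirs, abs=1e-12)


class TestFisher:
    def test_exchangeable_table(self):
        assert fisher_exact(np.array([[1, 1], [1, 1]])).p == 1.0

    def test_diagonal_table_enumeration(self):
        # only two tables (the observed and its mirror) are as extreme
        from math import comb
        assert fisher_exact(np.array([[5, 0], [0, 5]])).p == \
            pytest.approx(2 / comb(10, 5), abs=1e-12)

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            out = fisher_exact(np.array([[0, 0], [3, 4]]))
        assert out.p == 1.0

    def test_reconstructed_sensitivity_table(self):
        assert fisher_exact(np.array([[58, 30], [38, 8]])).p == \
            pytest.approx(0.0458, abs=5e-4)


class TestChi2:
    def test_proportional_rows_give_zero(self):
        chi2, df, p = pearson_chi2(np.array([[10, 20], [20, 40]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        chi2, df, _ = pearson_chi2(np.array([[10, 20], [20, 10]]))
        assert chi2 == pytest.approx(20 / 3, abs=1e-9)
        assert df == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2(np.zeros((2, 2)))


class TestProportionCI:
    def test_zero_successes_lower_bound_zero(self):
        est, lo, hi = proportion_ci(0, 20)
        assert est == 0.0 and lo == 0.0 and hi > 0

    def test_bounds_invert_binomial_tails(self):
        for k, n in [(3, 10), (38, 46), (58, 88), (1, 50)]:
            _, lo, hi = proportion_ci(k, n)
            # at the bounds the matching binomial tails equal alpha/2
            assert stats.binom.sf(k - 1, n, lo) == pytest.approx(0.025, abs=1e-6)
            assert stats.binom.cdf(k, n, hi) == pytest.approx(0.025, abs=1e-6)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in AdjustMethod:
            out = adjust_pvalues([0.03], method)
            assert out.adjusted == [pytest.approx(0.03)]

    def test_bonferroni_multiplies_by_m(self):
        out = adjust_pvalues([0.01] * 5, AdjustMethod.BONFERRONI)
        assert all(p == pytest.approx(0.05) for p in out.adjusted)

    def test_bh_monotone_after_sorting(self):
        rng = np.random.default_rng(2)
        pv = rng.random(20)
        out = adjust_pvalues(sorted(pv), AdjustMethod.BH)
        assert all(a <= b + 1e-12 for a, b in zip(out.adjusted,
                                                  out.adjusted[1:]))
        assert all(a >= r - 1e-12 for a, r in zip(out.adjusted, out.raw))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([])


class TestEvaluateScreening:
    def test_perfect_test_reports_perfect_metrics(self, default_cohort_frame):
        frame = default_cohort_frame.copy()
        frame["oracle"] = np.where(frame["group"] == "control", 20.0, 0.0)
        tables = evaluate_screening(frame, ["oracle"])
        assert (tables["auc"]["auc"] == 1.0).all()
        joint = tables["optimal_points"]
        row = joint[joint.group == "amblyopia+amblyogenic"].iloc[0]
        assert row.sensitivity == 1.0 and row.specificity == 1.0

    def test_identical_scores_give_delong_p_one(self, default_cohort_frame):
        frame = default_cohort_frame.copy()
        frame["copy1"] = frame["s_srds8"]
        frame["copy2"] = frame["s_srds8"]
        tables = evaluate_screening(frame, ["copy1", "copy2"])
        assert tables["delong_pairwise"].loc["copy1", "copy2"] == 1.0

    def test_uninformative_test_near_chance(self, default_cohort_frame):
        frame = default_cohort_frame.copy()
        rng = np.random.default_rng(4)
        frame["noise"] = rng.integers(0, 6, len(frame)).astype(float)
        y = frame["group"].isin(["amblyopia", "amblyogenic"]).to_numpy()
        r = roc_auc(frame["noise"].to_numpy(), y)
        assert abs(r.auc - 0.5) < 3 * r.auc_se
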