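import numpy as np
import pandas as pd
import pytest

from nodetex.stats import (
    combined_roc,
    compare_rocs,
    mann_whitney,
    multiple_regression,
    roc_analysis,
)

from oracles import brute_auc, brute_pair_count


class TestMannWhitney:
    def test_fully_separated_small_sample_exact(self):
        # all 20 orderings enumerable: U = 0 for the lower group, p = 2/20
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples(self):
        res = mann_whitney([5, 5, 5], [5, 5, 5])
        assert res.U == pytest.approx(4.5)  # n^2 / 2
        assert res.p == 1.0

    def test_midrank_ties_match_pair_counting(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        res = mann_whitney(a, b)
        # brute-force pair count: #(a > b) + 0.5 #(a == b)
        expect = sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b)
        assert res.U == pytest.approx(expect)
        assert res.method == "asymptotic"  # ties force the normal approximation

    def test_u_range_invariant(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 15))
            b = rng.normal(size=rng.integers(2, 15))
            res = mann_whitney(a, b)
            assert 0 <= res.U <= len(a) * len(b)

    def test_medians_and_iqr(self):
        res = mann_whitney([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.median_a == 2.5
        assert res.iqr_b == (17.5, 32.5)


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 11, 12, 13], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.youden == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_uninformative_scores(self):
        res = roc_analysis([5.0] * 8, [0, 1] * 4)
        assert res.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_probability(self, rng):
        for _ in range(30):
            n1, n0 = rng.integers(3, 12, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # rounding makes ties
            labels = np.r_[np.ones(n1), np.zeros(n0)]
            res = roc_analysis(scores, labels, positive=1)
            assert res.auc_raw == pytest.approx(brute_auc(scores, labels, 1), abs=1e-12)

    def test_orientation_flip(self):
        # score lower in positives: reported AUC >= 0.5 with flip flag
        res = roc_analysis([5, 6, 7, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.flipped and res.auc == 1.0 and res.auc_raw == 0.0

    def test_criterion_reproduces_sens_spec(self, rng):
        scores = rng.normal(size=40) + np.r_[np.zeros(25), np.full(15, 1.2)]
        labels = np.r_[np.zeros(25), np.ones(15)]
        res = roc_analysis(scores, labels, positive=1)
        pos, neg = scores[labels == 1], scores[labels == 0]
        assert (pos > res.criterion).mean() == pytest.approx(res.sensitivity)
        assert (neg <= res.criterion).mean() == pytest.approx(res.specificity)

    def test_delong_ci_matches_independent_reference(self):
        # frozen values computed with an independent DeLong implementation
        # (pROC 1.19) on this exact dataset
        neg = [1.2, 2.3, 0.7, 1.9, 2.2, 1.4, 2.8, 0.9, 1.6, 2.0, 1.2, 1.8]
        pos = [2.1, 2.9, 1.7, 3.4, 2.6, 3.1, 2.2, 2.8, 1.9, 3.6]
        res = roc_analysis(neg + pos, [0] * 12 + [1] * 10, positive=1)
        assert res.auc == pytest.approx(0.8541666667, abs=1e-9)
        assert res.auc_ci[0] == pytest.approx(0.6986234267, abs=1e-9)
        assert res.auc_ci[1] == pytest.approx(1.0, abs=1e-9)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestCompareROCs:
    def test_score_against_itself(self):
        s = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        labels = [0, 0, 0, 1, 1, 1]
        res = compare_rocs(s, s, labels)
        assert res["p"] == 1.0 and res["delta_auc"] == 0.0

    def test_monotone_transform_same_auc(self):
        s = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        labels = [0, 0, 0, 1, 1, 1]
        res = compare_rocs(s, np.exp(s), labels)
        assert res["delta_auc"] == pytest.approx(0.0)

    def test_paired_p_matches_independent_reference(self):
        # frozen paired-DeLong p computed with pROC 1.19 on this dataset
        neg = [1.2, 2.3, 0.7, 1.9, 2.2, 1.4, 2.8, 0.9, 1.6, 2.0, 1.2, 1.8]
        pos = [2.1, 2.9, 1.7, 3.4, 2.6, 3.1, 2.2, 2.8, 1.9, 3.6]
        s1 = np.array(neg + pos)
        adj = np.array([0.3, -0.2, 0.1, 0.4, -0.5, 0.2, -0.1, 0.3, 0.2, -0.3, 0.1, 0.2,
                        0.5, -0.4, 0.3, 0.1, -0.2, 0.4, 0.3, -0.1, 0.2, 0.3])
        s2 = 0.6 * s1 + adj
        labels = [0] * 12 + [1] * 10
        res = compare_rocs(s1, s2, labels)
        assert res["p"] == pytest.approx(0.2988276790, abs=1e-9)
        assert res["z"] == pytest.approx(-1.038951, abs=1e-5)

    def test_unpaired_lengths_error(self):
        with pytest.raises(ValueError, match="paired"):
            compare_rocs([1, 2, 3], [1, 2], [0, 1, 1])

    def test_null_rejection_rate_nominal(self):
        """Under H0 (equal AUCs), the paired test rejects at ~alpha."""
        rejections = 0
        reps = 400
        g = np.random.default_rng(7)
        labels = np.r_[np.zeros(25), np.ones(15)]
        for _ in range(reps):
            base = g.normal(size=40) + 0.8 * labels
            s1 = base + 0.5 * g.normal(size=40)
            s2 = base + 0.5 * g.normal(size=40)
            if compare_rocs(s1, s2, labels)["p"] < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.035)


class TestRegression:
    def test_self_prediction_r2_one(self):
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
        res = multiple_regression(pd.DataFrame({"x": y}), y)
        assert res.r2 == pytest.approx(1.0)
        assert res.coefficients.loc["x", "coef"] == pytest.approx(1.0)

    def test_orthogonal_predictors_unit_vif(self):
        x1 = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        x2 = np.array([1, 1, -1, -1, 1, 1, -1, -1], dtype=float)
        y = np.array([0, 1, 1, 0, 0, 1, 1, 0], dtype=float)
        res = multiple_regression(pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert res.coefficients.loc["x1", "vif"] == pytest.approx(1.0)
        assert res.coefficients.loc["x2", "vif"] == pytest.approx(1.0)

    def test_near_noiseless_slope_recovered(self, rng):
        x = rng.normal(size=50)
        y = 2.0 * x + 1e-8 * rng.normal(size=50)
        res = multiple_regression(pd.DataFrame({"x": x}), y)
        assert res.coefficients.loc["x", "coef"] == pytest.approx(2.0, abs=1e-6)
        assert res.coefficients.loc["x", "p"] < 1e-12

    def test_vif_at_least_one_and_permutation_invariant(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        X["d"] = X["a"] * 0.8 + rng.normal(size=30) * 0.3
        y = rng.integers(0, 2, size=30).astype(float)
        res = multiple_regression(X, y)
        vifs = res.coefficients["vif"].drop("const")
        assert (vifs >= 1.0 - 1e-9).all()
        perm = rng.permutation(30)
        res2 = multiple_regression(X.iloc[perm].reset_index(drop=True), y[perm])
        assert res2.r2 == pytest.approx(res.r2)

    def test_singular_design_names_columns(self):
        x = np.arange(8, dtype=float)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            multiple_regression(X, np.r_[np.zeros(4), np.ones(4)])

    def test_constant_predictor_rejected(self):
        X = pd.DataFrame({"a": np.ones(8), "b": np.arange(8.0)})
        with pytest.raises(ValueError, match="constant"):
            multiple_regression(X, np.r_[np.zeros(4), np.ones(4)])

    def test_adjusted_r2_not_above_r2(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 3)))
        y = rng.integers(0, 2, 25).astype(float)
        res = multiple_regression(X, y)
        assert res.r2_adj <= res.r2 + 1e-12
        assert res.multiple_r == pytest.approx(np.sqrt(res.r2))


class TestCombinedROC:
    def test_single_predictor_auc_preserved(self, rng):
        labels = np.r_[np.zeros(20), np.ones(12)]
        x = rng.normal(size=32) + labels
        reg = multiple_regression(pd.DataFrame({"x": x}), labels)
        comb = combined_roc(reg, labels, positive=1)
        direct = roc_analysis(x, labels, positive=1)
        assert comb.auc == pytest.approx(direct.auc)

    def test_adding_noise_predictor_never_hurts_in_sample(self, rng):
        labels = np.r_[np.zeros(20), np.ones(12)]
        x = rng.normal(size=32) + labels
        noise = rng.normal(size=32)
        auc1 = combined_roc(multiple_regression(pd.DataFrame({"x": x}), labels), labels, positive=1).auc
        auc2 = combined_roc(
            multiple_regression(pd.DataFrame({"x": x, "n": noise}), labels), labels, positive=1
        ).auc
        assert auc2 >= auc1 - 1e-12
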