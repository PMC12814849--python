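"""Agreement statistics: correlation, Bland-Altman, ICC, TOST, ROC, DeLong."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qpcmr import (
    bland_altman,
    classify_abnormal,
    delong_test,
    icc_agreement,
    icc_sample_size,
    pearson_regression,
    roc_auc,
    tost_equivalence,
)
from qpcmr.stats import AbnormalityThresholds, EquivalenceMargins


@pytest.fixture(scope="module")
def noisy_pairs():
    rng = np.random.default_rng(17)
    x = rng.uniform(1.0, 4.0, 20)
    y = 0.9 * x + 0.3 + rng.normal(0, 0.3, 20)
    return x, y


class TestPearsonRegression:
    def test_identity_line(self):
        x = np.linspace(1, 4, 10)
        res = pearson_regression((x, x))
        assert res["r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_negative_affine_line(self):
        x = np.linspace(0, 5, 12)
        res = pearson_regression((x, -2 * x + 3))
        assert res["r"] == pytest.approx(-1.0)
        assert res["slope"] == pytest.approx(-2.0)
        assert res["intercept"] == pytest.approx(3.0)

    def test_matches_direct_formula(self, noisy_pairs):
        x, y = noisy_pairs
        res = pearson_regression((x, y))
        # brute-force product-moment formula
        xc, yc = x - x.mean(), y - y.mean()
        r = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        slope = np.sum(xc * yc) / np.sum(xc**2)
        assert res["r"] == pytest.approx(r, abs=1e-12)
        assert res["slope"] == pytest.approx(slope, abs=1e-12)
        assert res["intercept"] == pytest.approx(y.mean() - slope * x.mean(), abs=1e-12)
        # two-sided p via the t transform
        t = r * np.sqrt((len(x) - 2) / (1 - r**2))
        assert res["p"] == pytest.approx(2 * sps.t.sf(abs(t), len(x) - 2), rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_regression((np.ones(5), np.arange(5.0)))


class TestBlandAltman:
    def test_identical_arms(self):
        x = np.linspace(1, 3, 8)
        res = bland_altman((x, x))
        assert res["bias"] == 0.0 and res["sd"] == 0.0

    def test_two_point_spread(self):
        res = bland_altman((np.array([0.0, 0.0, 0.0]), np.array([1.0, -1.0, 0.0])))
        assert res["bias"] == pytest.approx(0.0)
        assert res["sd"] == pytest.approx(1.0)
        assert res["loa_high"] == pytest.approx(1.96)

    def test_bias_plus_reference_mean_equals_test_mean(self, noisy_pairs):
        x, y = noisy_pairs
        res = bland_altman((x, y))
        assert res["bias"] + x.mean() == pytest.approx(y.mean(), abs=1e-12)


def brute_force_icc_a1(x, y):
    """ICC(A,1) from explicitly accumulated two-way ANOVA sums of squares."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = sum(
        (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_perfect_agreement(self):
        x = np.linspace(1, 4, 10)
        assert icc_agreement((x, x))["icc"] == pytest.approx(1.0)

    def test_offset_penalised_relative_to_pearson(self):
        x = np.linspace(1.0, 2.0, 12)
        y = x + 5.0  # bias large vs spread
        res = icc_agreement((x, y))
        assert res["icc"] < pearson_regression((x, y))["r"]

    def test_matches_brute_force_mean_squares(self, noisy_pairs):
        x, y = noisy_pairs
        res = icc_agreement((x, y))
        assert res["icc"] == pytest.approx(brute_force_icc_a1(x, y), abs=1e-10)

    def test_matches_pingouin_icc2(self, noisy_pairs):
        pingouin = pytest.importorskip("pingouin")
        x, y = noisy_pairs
        long = pd.DataFrame({
            "subject": np.r_[np.arange(x.size), np.arange(x.size)],
            "rater": ["a"] * x.size + ["b"] * x.size,
            "score": np.r_[x, y],
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        res = icc_agreement((x, y))
        assert res["icc"] == pytest.approx(row.ICC, abs=1e-9)
        # pingouin rounds its CI to 2 decimals
        assert res["ci_low"] == pytest.approx(row.CI95[0], abs=6e-3)
        assert res["ci_high"] == pytest.approx(row.CI95[1], abs=6e-3)

    @pytest.mark.parametrize(
        "icc,expected",
        [(0.3, "poor"), (0.50, "moderate"), (0.75, "moderate"),
         (0.80, "good"), (0.90, "good"), (0.95, "excellent")],
    )
    def test_interpretation_bands(self, icc, expected):
        from qpcmr.stats import _icc_interpretation

        assert _icc_interpretation(icc) == expected

    def test_degenerate_between_subject_variance(self):
        x = np.full(6, 2.0)
        y = np.full(6, 2.0)
        res = icc_agreement((x, y + np.array([0, 1e-9, 0, -1e-9, 0, 0])))
        assert res["icc"] <= 0.0 or res["degenerate"]


class TestTost:
    def test_tight_differences_are_equivalent(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 3, 50)
        y = x + rng.normal(0, 0.1, 50)
        res = tost_equivalence((x, y), margin=0.9)
        assert res["equivalent"] and res["p"] < 0.001

    def test_mean_difference_at_margin_gives_half(self):
        # binding one-sided t statistic is 0 => p = 0.5
        x = np.zeros(16)
        d = np.array([0.4, 0.6] * 8)  # mean 0.5, sd > 0
        res = tost_equivalence((x, d), margin=0.5)
        assert res["p"] == pytest.approx(0.5)

    def test_sign_flip_symmetry(self, noisy_pairs):
        x, y = noisy_pairs
        a = tost_equivalence((x, y), margin=0.9)
        b = tost_equivalence((y, x), margin=0.9)  # flips every difference
        assert a["p"] == pytest.approx(b["p"], abs=1e-12)

    def test_matches_closed_form_t(self):
        x = np.array([1.0, 1.2, 0.9, 1.1, 1.05, 0.95])
        y = x + np.array([0.1, -0.05, 0.2, 0.0, 0.15, -0.1])
        margin = 0.5
        res = tost_equivalence((x, y), margin=margin)
        d = y - x
        se = d.std(ddof=1) / np.sqrt(d.size)
        p_low = sps.t.sf((d.mean() + margin) / se, d.size - 1)
        p_up = sps.t.cdf((d.mean() - margin) / se, d.size - 1)
        assert res["p"] == pytest.approx(max(p_low, p_up), abs=1e-12)

    def test_zero_variance_short_circuit(self):
        x = np.ones(5)
        res = tost_equivalence((x, x + 0.2), margin=0.5)
        assert res["degenerate_variance"] and res["equivalent"]
        res2 = tost_equivalence((x, x + 0.8), margin=0.5)
        assert not res2["equivalent"]

    def test_default_margins_and_thresholds(self):
        m = EquivalenceMargins()
        assert (m.mbf_participant, m.mpr_participant) == (0.90, 0.98)
        assert (m.stress_mbf_vessel_segment, m.mpr_vessel_segment) == (1.43, 2.80)
        t = AbnormalityThresholds()
        assert (t.stress_mbf_le, t.mpr_le) == (2.3, 2.5)


class TestClassifyAbnormal:
    def test_boundary_inclusive(self):
        labels = classify_abnormal([2.3, 2.31, 1.0], threshold=2.3)
        assert list(labels) == [True, False, True]

    def test_vector_matches_elementwise_comparison(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0, 5, 100)
        np.testing.assert_array_equal(classify_abnormal(v, 2.5), v <= 2.5)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = scores > 0.5
        assert roc_auc(scores, labels)["auc"] == 1.0
        # perfusion convention: abnormal = low value
        assert roc_auc(-scores, labels, direction="less")["auc"] == 1.0

    def test_ties_match_pairwise_count(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 4.0])
        labels = np.array([False, False, True, False, True, True])
        pos, neg = scores[labels], scores[~labels]
        brute = np.mean([
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        ])
        assert roc_auc(scores, labels)["auc"] == pytest.approx(brute, abs=1e-12)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 1, 200) + rng.integers(0, 2, 200)
        labels = rng.integers(0, 2, 200).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc(scores, labels)["auc"] == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_orientation_identity_without_ties(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(0, 1, 50)
        labels = rng.integers(0, 2, 50).astype(bool)
        labels[0], labels[1] = True, False
        a = roc_auc(scores, labels)["auc"]
        b = roc_auc(-scores, labels)["auc"]
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, bool))


class TestDelong:
    def test_identical_scores_degenerate(self):
        rng = np.random.default_rng(11)
        s = rng.normal(0, 1, 40)
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        res = delong_test(s, s, labels)
        assert res["p"] == 1.0 and res["degenerate"]

    def test_monotone_transform_is_rank_invariant(self):
        rng = np.random.default_rng(12)
        s = rng.normal(0, 1, 60)
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        res = delong_test(s, np.exp(s), labels)
        assert res["auc_a"] == pytest.approx(res["auc_b"], abs=1e-12)
        assert res["p"] == 1.0

    def test_detects_clearly_better_score(self):
        rng = np.random.default_rng(13)
        n = 200
        labels = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        good = labels + rng.normal(0, 0.5, 2 * n)
        bad = rng.normal(0, 1, 2 * n)
        res = delong_test(good, bad, labels)
        assert res["auc_a"] > res["auc_b"]
        assert res["p"] < 0.001


class TestIccSampleSize:
    def test_study_planning_value(self):
        n = icc_sample_size(0.20, 0.60, alpha=0.05, power=0.80, raters=2)
        assert abs(n - 35) <= 2

    def test_monotone_in_effect_size(self):
        ns = [icc_sample_size(0.20, alt) for alt in (0.4, 0.6, 0.8, 0.95)]
        assert ns == sorted(ns, reverse=True) and len(set(ns)) == len(ns)

    def test_monotone_in_power(self):
        assert icc_sample_size(0.2, 0.6, power=0.90) > icc_sample_size(
            0.2, 0.6, power=0.80
        )

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            icc_sample_size(0.6, 0.2)
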