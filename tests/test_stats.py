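"""Statistical layer against independent oracles and closed forms."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aslkid import (
    ConfusionMatrix,
    diagnostic_indices,
    icc_two_way,
    logistic_fit,
    paired_t,
    roc_auc,
    student_t,
)

from _oracles import (
    anova_mean_squares,
    icc21_from_mean_squares,
    newton_logistic,
    pair_count_auc,
)


class TestPairedT:
    def test_hand_computed_example(self):
        # differences (1,2,3): mean 2, sd 1, t = 2/(1/sqrt(3))
        t, p = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(3.4641016, rel=1e-6)

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        t1, p1 = paired_t(x, y)
        t2, p2 = paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestStudentT:
    def test_hand_computed_example(self):
        t, p = student_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.6742346, rel=1e-6)

    def test_identical_groups_give_zero(self):
        t, p = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = np.array([1.0, 2.0, 4.0, 5.0])
        b = np.array([3.0, 6.0, 7.0, 9.0])
        t1, _ = student_t(a, b)
        t2, _ = student_t(10 * a, 10 * b)
        assert t1 == pytest.approx(t2)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            student_t([2.0, 2.0], [5.0, 5.0])


class TestICC:
    def test_duplicated_sessions_give_exactly_one(self):
        m = np.array([[1.0, 1.0], [3.0, 3.0], [5.0, 5.0], [7.0, 7.0]])
        assert icc_two_way(m).icc == 1.0

    def test_matches_anova_oracle_on_fixed_matrix(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        res = icc_two_way(m)
        msr, msc, mse = anova_mean_squares(m)
        assert res.ms_rows == pytest.approx(msr, abs=1e-12)
        assert res.ms_cols == pytest.approx(msc, abs=1e-12)
        assert res.ms_error == pytest.approx(mse, abs=1e-12)
        assert res.icc == pytest.approx(icc21_from_mean_squares(msr, msc, mse, 4, 2), abs=1e-12)

    def test_matches_anova_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = rng.normal(size=(10, 2)) * rng.uniform(0.5, 20)
            res = icc_two_way(m)
            msr, msc, mse = anova_mean_squares(m)
            expected = icc21_from_mean_squares(msr, msc, mse, 10, 2)
            assert res.icc == pytest.approx(expected, abs=1e-10)
            assert res.icc <= 1.0

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        m = rng.normal(10, 3, size=(12, 2))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "score": m.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        # "ICC(A,1)": two-way, absolute agreement, single measurement
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_two_way(m).icc == pytest.approx(icc2, abs=1e-8)

    def test_no_subject_effect_gives_icc_near_zero(self):
        rng = np.random.default_rng(13)
        m = rng.normal(size=(500, 2))
        assert abs(icc_two_way(m).icc) < 0.1

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            icc_two_way(np.full((5, 2), 3.0))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1.0, 2.0, 10.0, 11.0], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_tied_scores_give_half(self):
        r = roc_auc([5.0] * 6, [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(0.5)

    def test_youden_cutoff_picks_smallest_threshold_on_ties(self):
        # two thresholds reach J = 1: any cutoff in (2, 10]; smallest unique
        # score threshold achieving the max must be returned
        r = roc_auc([1.0, 2.0, 10.0, 11.0], [0, 0, 1, 1])
        assert r.youden_cutoff == 10.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        n=st.integers(4, 100),
        seed=st.integers(0, 10_000),
        discrete=st.booleans(),
    )
    def test_trapezoid_equals_pair_counting(self, n, seed, discrete):
        """Trapezoidal AUC is the tie-corrected concordant-pair proportion."""
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.normal(size=n)
        if discrete:
            scores = np.round(scores * 2) / 2  # force ties
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-10)


class TestDiagnosticIndices:
    def test_cohort_consistent_confusion_matrix(self):
        idx = diagnostic_indices(ConfusionMatrix(tp=9, fn=3, tn=27, fp=0))
        assert idx.sensitivity == 0.75
        assert idx.specificity == 1.0
        assert idx.npv == pytest.approx(27 / 30)

    def test_symmetric_matrix_gives_half_everywhere(self):
        idx = diagnostic_indices(ConfusionMatrix(tp=1, fp=1, tn=1, fn=1))
        assert idx.sensitivity == idx.specificity == idx.ppv == idx.npv == 0.5

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_indices(ConfusionMatrix(tp=0, fn=0, tn=3, fp=1))

    def test_wilson_intervals_bracket_the_estimate(self):
        idx = diagnostic_indices(ConfusionMatrix(tp=9, fn=3, tn=27, fp=0))
        lo, hi = idx.sensitivity_ci
        assert lo < idx.sensitivity < hi
        lo, hi = idx.specificity_ci
        assert lo <= 1.0 and hi == pytest.approx(1.0)


class TestLogisticFit:
    def test_grouped_two_by_two_closed_form(self):
        x = np.array([0.0] * 10 + [1.0] * 10).reshape(-1, 1)
        y = np.array([1] * 2 + [0] * 8 + [1] * 8 + [0] * 2)
        model = logistic_fit(x, y)
        assert model.coefficients[1] == pytest.approx(np.log(16.0), abs=1e-9)
        assert model.odds_ratios[1] == pytest.approx(16.0, rel=1e-8)

    def test_constant_predictor_on_balanced_labels_is_uninformative(self):
        model = logistic_fit(np.ones((20, 1)), np.array([0, 1] * 10))
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-8)
        assert model.odds_ratios[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_newton_raphson_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            X = rng.normal(size=(60, 3))
            beta_true = rng.normal(scale=0.5, size=4)
            eta = beta_true[0] + X @ beta_true[1:]
            y = (rng.random(60) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.min() == y.max():
                continue
            model = logistic_fit(X, y)
            oracle = newton_logistic(np.column_stack([np.ones(60), X]), y)
            np.testing.assert_allclose(model.coefficients, oracle, atol=1e-6)

    def test_affine_rescaling_rescales_beta_only(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(80, 2))
        y = (rng.random(80) < 1 / (1 + np.exp(-(X[:, 0] - 0.3 * X[:, 1])))).astype(float)
        m1 = logistic_fit(X, y)
        X2 = X.copy()
        X2[:, 0] = X2[:, 0] * 10.0
        m2 = logistic_fit(X2, y)
        assert m2.coefficients[1] == pytest.approx(m1.coefficients[1] / 10.0, abs=1e-7)
        p1 = 1 / (1 + np.exp(-(m1.coefficients[0] + X @ m1.coefficients[1:])))
        p2 = 1 / (1 + np.exp(-(m2.coefficients[0] + X2 @ m2.coefficients[1:])))
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_separation_flagged_not_raised(self):
        x = np.linspace(-2, 2, 20).reshape(-1, 1)
        y = (x.ravel() > 0).astype(float)
        model = logistic_fit(x, y)
        assert not model.converged
        assert "separation" in model.message

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="collinear"):
            logistic_fit(X, y, names=["a", "b"])


class TestNullCalibration:
    def test_paired_and_two_sample_p_uniform_under_null(self):
        """Type-I calibration: p-values uniform under the null (KS at 0.01)."""
        from scipy import stats as sps

        rng = np.random.default_rng(99)
        p_paired = np.empty(2000)
        p_student = np.empty(2000)
        for i in range(2000):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            p_paired[i] = paired_t(x, y)[1]
            p_student[i] = student_t(rng.normal(size=12), rng.normal(size=18))[1]
        assert sps.kstest(p_paired, "uniform").pvalue > 0.01
        assert sps.kstest(p_student, "uniform").pvalue > 0.01
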