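import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import auc_pair_counting

from renoct.metrics import (
    HEALTH_STATUS_RULES,
    agreement_report,
    bland_altman,
    classify_health_status,
    clopper_pearson,
    cohort_baseline_comparison,
    concordance_correlation,
    delong_paired_test,
    diagnostic_metrics_cp,
    paired_error_comparison,
    reduced_major_axis,
    roc_auc_delong,
    summarize_tasks,
)


class TestAgreement:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2, 3, 4, 5])
        rep = agreement_report(x, x)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mae == 0 and rep.mse == 0
        assert rep.ccc == pytest.approx(1.0)
        assert rep.rma_slope == pytest.approx(1.0)
        assert rep.rma_intercept == pytest.approx(0.0)
        assert rep.paired_t_p == 1.0

    def test_closed_form_example(self):
        # x=[1,2,3], y=[2,4,6]: CCC = 8/22, RMA slope 2, intercept 0
        x = np.array([1.0, 2, 3])
        y = np.array([2.0, 4, 6])
        assert concordance_correlation(x, y) == pytest.approx(8 / 22)
        slope, intercept = reduced_major_axis(x, y)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)
        rep = agreement_report(y, x)  # estimates=y vs references=x
        assert rep.ccc == pytest.approx(8 / 22)
        assert rep.rma_slope == pytest.approx(2.0)

    def test_location_shift_reduces_ccc_not_r(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.2, 50)
        base = agreement_report(y, x)
        shifted = agreement_report(y + 5.0, x)
        assert shifted.pearson_r == pytest.approx(base.pearson_r)
        assert shifted.ccc < base.ccc

    def test_ccc_bounded_by_abs_r(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30) + 0.5 * x
            r = np.corrcoef(x, y)[0, 1]
            assert concordance_correlation(x, y) <= abs(r) + 1e-12

    def test_ccc_ci_contains_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(50, 10, 100)
        y = x + rng.normal(0, 5, 100)
        rep = agreement_report(y, x)
        lo, hi = rep.ccc_ci
        assert lo < rep.ccc < hi
        assert -1 <= lo and hi <= 1

    def test_rma_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(0, 0.5, 40)
        s1, _ = reduced_major_axis(x, y)
        s2, _ = reduced_major_axis(x, 3.0 * y)
        assert s2 == pytest.approx(3.0 * s1)

    def test_degenerate_zero_variance_flagged(self):
        rep = agreement_report([1.0, 1, 1], [1.0, 2, 3])
        assert rep.degenerate
        assert np.isnan(rep.ccc) and np.isnan(rep.pearson_r)


_finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.tuples(_finite, _finite), min_size=4, max_size=30))
def test_ccc_attenuation_property(pairs):
    """CCC never exceeds |r| and stays in [-1, 1] for any paired sample."""
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if x.std() == 0 or y.std() == 0:
        return
    ccc = concordance_correlation(x, y)
    r = np.corrcoef(x, y)[0, 1]
    assert -1.0 - 1e-9 <= ccc <= 1.0 + 1e-9
    assert ccc <= abs(r) + 1e-9


class TestBlandAltman:
    def test_constant_difference(self):
        rep = bland_altman([2.0, 3, 4], [1.0, 2, 3])
        assert rep.mean_difference == pytest.approx(1.0)
        assert rep.sd_difference == 0.0
        assert rep.loa_lower == rep.loa_upper == pytest.approx(1.0)

    def test_limits_are_1_96_sd(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0, 1, 500)
        rep = bland_altman(d, np.zeros(500))
        assert rep.loa_upper == pytest.approx(rep.mean_difference + 1.96 * rep.sd_difference)

    def test_normal_differences_95_percent_within(self):
        rng = np.random.default_rng(5)
        est = rng.normal(0, 1, 10_000)
        rep = bland_altman(est, np.zeros(10_000))
        assert rep.fraction_within == pytest.approx(0.95, abs=0.01)


class TestWilcoxon:
    def test_identical_vectors_p_one(self):
        assert paired_error_comparison([1.0, 2, 3], [1.0, 2, 3]) == 1.0

    def test_exact_small_sample(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        assert paired_error_comparison(a + 1.0 * np.arange(1, 7), a) == pytest.approx(2 / 64)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert paired_error_comparison(a, b) == pytest.approx(paired_error_comparison(b, a))


class TestHealthRules:
    @pytest.mark.parametrize(
        "rule,value,expected",
        [
            ("impaired", 30.0, "impaired"),  # inclusive bound
            ("impaired", 30.001, "normal"),
            ("non_functioning", 10.0, "functioning"),  # strict bound
            ("non_functioning", 9.999, "non-functioning"),
            ("nephrectomy", 15.0, "non-nephrectomy"),
            ("lower_function", 44.9, "lower"),
            ("lower_function", 45.0, "not-lower"),
            ("non_dominant", 60.0, "non-dominant"),  # inclusive bound
            ("non_dominant", 60.1, "dominant"),
        ],
    )
    def test_published_boundaries(self, rule, value, expected):
        assert classify_health_status(value, rule) == expected

    def test_unknown_rule_rejected(self):
        with pytest.raises(KeyError):
            classify_health_status(50.0, "made_up")


class TestAUC:
    def test_perfect_and_tied(self):
        auc, _ = roc_auc_delong([3.0, 4, 1, 2], [1, 1, 0, 0])
        assert auc == 1.0
        auc, _ = roc_auc_delong([1.0, 1, 1, 1], [1, 1, 0, 0])
        assert auc == 0.5

    def test_toy_2plus2(self):
        auc, _ = roc_auc_delong([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_equals_pair_counting_up_to_n50(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(8, 50))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            auc, _ = roc_auc_delong(scores, labels)
            assert auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_delong([1.0, 2.0], [1, 1])


class TestDeLongPaired:
    def test_identical_scores_p_one(self):
        scores = [0.1, 0.9, 0.4, 0.7]
        labels = [0, 1, 0, 1]
        z, p = delong_paired_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        z, p = delong_paired_test(scores, np.exp(scores), labels)
        assert p == pytest.approx(1.0)

    def test_agrees_with_bootstrap(self):
        rng = np.random.default_rng(9)
        n = 60
        labels = np.arange(n) < 25
        a = labels * 1.0 + rng.normal(0, 0.8, n)
        b = labels * 1.0 + rng.normal(0, 1.6, n)
        _, p = delong_paired_test(a, b, labels)
        # bootstrap the AUC difference distribution
        boots = []
        idx_pos = np.where(labels)[0]
        idx_neg = np.where(~labels)[0]
        for _ in range(10_000):
            take = np.concatenate(
                [rng.choice(idx_pos, idx_pos.size), rng.choice(idx_neg, idx_neg.size)]
            )
            boots.append(
                auc_fast(a[take], labels[take]) - auc_fast(b[take], labels[take])
            )
        boots = np.array(boots)
        d0 = auc_fast(a, labels) - auc_fast(b, labels)
        # two-sided p from the centered bootstrap distribution
        p_boot = 2 * min(np.mean(boots - boots.mean() >= abs(d0)), np.mean(boots - boots.mean() <= -abs(d0)))
        assert abs(p - p_boot) < 0.02 or (p > 0.2 and p_boot > 0.2)


def auc_fast(scores, labels):
    from scipy.stats import rankdata

    r = rankdata(scores)
    npos = labels.sum()
    nneg = len(labels) - npos
    return (r[labels].sum() - npos * (npos + 1) / 2) / (npos * nneg)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (0, 4, 0.0, 60.2),
            (2, 2, 15.8, 100.0),
            (218, 256, 80.2, 89.3),
            (252, 252, 98.5, 100.0),
            (190, 234, 75.6, 86.0),
        ],
    )
    def test_published_intervals(self, k, n, lo, hi):
        got_lo, got_hi = clopper_pearson(k, n)
        assert 100 * got_lo == pytest.approx(lo, abs=0.05)
        assert 100 * got_hi == pytest.approx(hi, abs=0.05)

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(1, 300))
            k = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi

    def test_coverage_at_least_nominal(self):
        rng = np.random.default_rng(11)
        p_true, n = 0.3, 40
        hits = 0
        reps = 2000
        ks = rng.binomial(n, p_true, reps)
        for k in ks:
            lo, hi = clopper_pearson(int(k), n)
            hits += lo <= p_true <= hi
        assert hits / reps >= 0.95


class TestDiagnosticReport:
    def test_counts_and_cis(self):
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        pred = np.array([0, 0, 0, 0, 0, 0, 0, 0], bool)
        rep = diagnostic_metrics_cp(pred, truth, task="toy")
        assert rep.sensitivity == 0.0
        assert rep.sensitivity_counts == (0, 4)
        assert rep.sensitivity_ci[1] == pytest.approx(60.2, abs=0.05)
        assert rep.specificity == 100.0
        assert rep.accuracy_counts == (4, 8)

    def test_undefined_class_flagged(self):
        truth = np.zeros(5, bool)
        pred = np.zeros(5, bool)
        rep = diagnostic_metrics_cp(pred, truth)
        assert np.isnan(rep.sensitivity)
        assert any("sensitivity undefined" in n for n in rep.notes)

    def test_mean_row_arithmetic(self):
        # published mean-row arithmetic: AUCs and sensitivities of the five
        # test-set tasks
        aucs = [0.862, 0.911, 0.959, 0.980, 0.964]
        sens = [71.4, 10.5, 22.2, 88.2, 93.2]
        reports = [
            diagnostic_metrics_cp([True], [True], task=f"t{i}", auc=a) for i, a in enumerate(aucs)
        ]
        for rep, s in zip(reports, sens):
            rep.sensitivity = s
        out = summarize_tasks(reports)
        assert out["auc"] == pytest.approx(0.935, abs=5e-4)
        assert out["sensitivity"] == pytest.approx(57.1, abs=0.05)

    def test_single_task_mean_is_identity(self):
        rep = diagnostic_metrics_cp([True, False], [True, False], task="t", auc=0.9)
        out = summarize_tasks([rep])
        assert out["auc"] == 0.9
        assert out["accuracy"] == rep.accuracy


class TestBaselineComparison:
    def test_published_sex_comparison(self):
        a = pd.DataFrame(dict(sex=["M"] * 74 + ["F"] * 54))
        b = pd.DataFrame(dict(sex=["M"] * 69 + ["F"] * 48))
        out = cohort_baseline_comparison(a, b, continuous=[], categorical=["sex"])
        assert out.loc[0, "p"] == pytest.approx(0.853, abs=1.5e-3)

    def test_identical_groups_maximal_p(self):
        rng = np.random.default_rng(12)
        g = pd.DataFrame(dict(age=rng.normal(50, 10, 60)))
        out = cohort_baseline_comparison(g, g.copy(), continuous=["age"], categorical=[])
        assert out.loc[0, "p"] > 0.95

    def test_large_shift_detected(self):
        rng = np.random.default_rng(13)
        a = pd.DataFrame(dict(age=rng.normal(50, 5, 50)))
        b = pd.DataFrame(dict(age=rng.normal(100, 5, 50)))
        out = cohort_baseline_comparison(a, b, continuous=["age"], categorical=[])
        assert out.loc[0, "p"] < 0.001

    def test_constant_variable_flagged(self):
        a = pd.DataFrame(dict(x=[1.0] * 5))
        b = pd.DataFrame(dict(x=[1.0] * 5))
        out = cohort_baseline_comparison(a, b, continuous=["x"], categorical=[])
        assert out.loc[0, "flag"] == "constant"
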