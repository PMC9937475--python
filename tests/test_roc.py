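"""ROC construction, binormal Az, confidence bounds and operating points."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lrobserver as lr
from lrobserver.errors import UndefinedIntervalError, UndefinedROCError
from .conftest import AMYG_AD, AMYG_NC, HIPPO_AD, HIPPO_NC, MTL_AD, MTL_NC, make_record, mann_whitney_auc


def labels_for(n_pos, n_neg):
    return ["diseased"] * n_pos + ["normal"] * n_neg


class TestEmpiricalRoc:
    def test_small_example_against_pairwise_count(self):
        curve = lr.empirical_roc([3, 5, 1, 4], labels_for(2, 2))
        assert curve.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        curve = lr.empirical_roc([10, 9, 1, 2], labels_for(2, 2))
        assert curve.auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        curve = lr.empirical_roc([5.0] * 6, labels_for(3, 3))
        assert curve.auc == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedROCError):
            lr.empirical_roc([1, 2], ["diseased", "diseased"])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=60)
        curve = lr.empirical_roc(scores, labels_for(30, 30))
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)
        assert curve.auc == pytest.approx(np.trapezoid(curve.tpr, curve.fpr))

    @given(
        pos=st.lists(st.integers(-20, 20), min_size=1, max_size=30),
        neg=st.lists(st.integers(-20, 20), min_size=1, max_size=30),
    )
    @settings(max_examples=80, deadline=None)
    def test_equals_mann_whitney_statistic(self, pos, neg):
        # integer scores force plenty of ties; the trapezoid must equal the
        # pairwise win + half-tie count exactly
        curve = lr.empirical_roc(pos + neg, labels_for(len(pos), len(neg)))
        assert curve.auc == pytest.approx(mann_whitney_auc(pos, neg), abs=1e-12)

    # scores rounded to 3 decimals: distinct values stay distinct under the
    # transforms in float arithmetic (subnormal gaps would collapse)
    score_strategy = st.lists(
        st.floats(-5, 5, allow_nan=False).map(lambda v: round(v, 3)),
        min_size=2, max_size=20,
    )

    @given(pos=score_strategy, neg=score_strategy)
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, pos, neg):
        scores = np.array(pos + neg)
        labels = labels_for(len(pos), len(neg))
        base = lr.empirical_roc(scores, labels).auc
        for f in (lambda s: 3 * s + 2, np.tanh, lambda s: np.exp(s / 5)):
            assert lr.empirical_roc(f(scores), labels).auc == pytest.approx(base, abs=1e-12)

    def test_label_flip_with_score_negation_preserves_auc(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(1, 1, 25), rng.normal(0, 1, 35)])
        labels = np.array([True] * 25 + [False] * 35)
        a = lr.empirical_roc(scores, labels).auc
        b = lr.empirical_roc(-scores, ~labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestBinormalAz:
    def test_identical_densities_give_half(self):
        d = lr.GaussianDensity(5000, 400)
        assert lr.binormal_az(d, d) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "ad, nc, printed",
        [(MTL_AD, MTL_NC, 0.840), (HIPPO_AD, HIPPO_NC, 0.826), (AMYG_AD, AMYG_NC, 0.804)],
        ids=["mtl", "hippocampus", "amygdala"],
    )
    def test_published_parameters_reproduce_printed_az(self, ad, nc, printed):
        az = lr.binormal_az(lr.GaussianDensity(*nc), lr.GaussianDensity(*ad))
        assert az == pytest.approx(printed, abs=0.005)

    def test_monte_carlo_oracle_for_mtl(self):
        """Az equals P(diseased draw < normal draw) for atrophic separation."""
        rng = np.random.default_rng(17)
        n = 2_000_000
        xd = rng.normal(*MTL_AD, size=n)
        xn = rng.normal(*MTL_NC, size=n)
        az = lr.binormal_az(lr.GaussianDensity(*MTL_NC), lr.GaussianDensity(*MTL_AD))
        assert az == pytest.approx((xd < xn).mean(), abs=0.002)

    def test_symmetric_in_arguments(self):
        a = lr.GaussianDensity(*MTL_AD)
        b = lr.GaussianDensity(*MTL_NC)
        assert lr.binormal_az(a, b) == lr.binormal_az(b, a)

    def test_strictly_increasing_in_separation(self):
        azs = [
            lr.binormal_az(lr.GaussianDensity(10000, 800), lr.GaussianDensity(10000 - d, 900))
            for d in (0, 200, 500, 1000, 2000)
        ]
        assert all(x < y for x, y in zip(azs, azs[1:]))

    def test_large_sample_empirical_auc_converges_to_binormal(self):
        rng = np.random.default_rng(26300)
        n = 20_000
        scores = np.concatenate(
            [-rng.normal(*MTL_AD, size=n), -rng.normal(*MTL_NC, size=n)]
        )  # negated volume: larger = more atrophic = more diseased
        curve = lr.empirical_roc(scores, labels_for(n, n))
        az = lr.binormal_az(lr.GaussianDensity(*MTL_NC), lr.GaussianDensity(*MTL_AD))
        assert curve.auc == pytest.approx(az, abs=0.005)


class TestAucConfidenceInterval:
    def test_symmetric_about_half_for_null_auc(self):
        curve = lr.ROCCurve(
            fpr=np.array([0, 1.0]), tpr=np.array([0, 1.0]), auc=0.5, n_pos=500, n_neg=500
        )
        lo, hi = lr.auc_confidence_interval(curve)
        assert lo + hi == pytest.approx(1.0)

    def test_upper_bound_clipped_at_one(self):
        curve = lr.ROCCurve(
            fpr=np.array([0, 0, 1.0]), tpr=np.array([0, 1, 1.0]), auc=1.0, n_pos=10, n_neg=10
        )
        assert lr.auc_confidence_interval(curve)[1] == 1.0

    def test_matches_bootstrap_oracle_at_test_cohort_size(self):
        """Hanley-McNeil half-width vs a 10,000-resample bootstrap, 46/23 split."""
        rng = np.random.default_rng(4623)
        pos = rng.normal(1.6, 1.0, size=46)
        neg = rng.normal(0.0, 1.0, size=23)
        curve = lr.empirical_roc(
            np.concatenate([pos, neg]), labels_for(46, 23)
        )
        lo, hi = lr.auc_confidence_interval(curve)
        boots = np.empty(10_000)
        for b in range(boots.size):
            boots[b] = mann_whitney_auc(
                rng.choice(pos, 46, replace=True), rng.choice(neg, 23, replace=True)
            )
        se_boot = boots.std(ddof=1)
        se_hm = (hi - lo) / (2 * 1.959963984540054)
        assert abs(1.959963984540054 * (se_hm - se_boot)) < 0.02

    def test_degenerate_counts_rejected(self):
        curve = lr.ROCCurve(
            fpr=np.array([0, 1.0]), tpr=np.array([0, 1.0]), auc=0.5, n_pos=1, n_neg=5
        )
        with pytest.raises(UndefinedIntervalError):
            lr.auc_confidence_interval(curve)


class TestEvaluateAtZeroThreshold:
    def test_hand_enumerated_toy_cohort(self):
        model = lr.LRObserverModel(
            normal_density=lr.GaussianDensity(10, 1),
            diseased_density=lr.GaussianDensity(6, 1),
            measure=lr.HIPPOCAMPUS_TOTAL,
        )
        # boundary at 8: diseased iff total hippocampal volume < 8
        def rec(sid, group, total):
            return lr.SubjectRecord(
                sid, group,
                {
                    (lr.Region.HIPPOCAMPUS, lr.Hemisphere.LEFT): total / 2,
                    (lr.Region.HIPPOCAMPUS, lr.Hemisphere.RIGHT): total / 2,
                },
            )
        test = lr.CohortTable(
            [
                rec("d1", lr.Group.AD, 5), rec("d2", lr.Group.AD, 7), rec("d3", lr.Group.AD, 11),
                rec("n1", lr.Group.NC, 9), rec("n2", lr.Group.NC, 12),
            ]
        )
        report = lr.evaluate_at_zero_threshold(model, test)
        assert (report.tp, report.fn, report.tn, report.fp) == (2, 1, 2, 0)
        assert report.sensitivity == pytest.approx(2 / 3)
        assert report.specificity == pytest.approx(1.0)

    def test_perfectly_separated_cohorts(self, mtl_model):
        recs = [make_record(f"d{i}", lr.Group.AD, 500.0) for i in range(5)] + [
            make_record(f"n{i}", lr.Group.NC, 2500.0) for i in range(5)
        ]
        report = lr.evaluate_at_zero_threshold(mtl_model, lr.CohortTable(recs))
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_empty_table_undefined(self, mtl_model):
        with pytest.raises(UndefinedROCError):
            lr.evaluate_at_zero_threshold(mtl_model, lr.CohortTable([]))


def test_report_arithmetic_from_confusion_counts():
    report = lr.ClassificationReport(tp=41, fn=5, tn=20, fp=3)
    assert report.sensitivity == pytest.approx(41 / 46)
    assert report.specificity == pytest.approx(20 / 23)
    assert report.balanced_accuracy == pytest.approx(0.5 * (41 / 46 + 20 / 23))
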