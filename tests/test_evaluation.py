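import numpy as np
import pytest
from scipy import stats

from osteomir.cohort import CohortTable, MODEL_FEATURES
from osteomir.evaluation import (
    UndefinedROCError,
    accuracy_at_threshold,
    auc_concordance,
    dagostino_pearson,
    delong_test,
    group_compare,
    kfold_cv,
    optimal_cutoff,
    roc,
    se_at_fixed_sp,
)
from osteomir.simulate import GeneratorConfig, generate_cohort


class TestROC:
    def test_perfect_separation(self):
        res = roc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], orientation="low")
        assert res.auc == 1.0

    def test_hand_computed_auc(self):
        # positives {0.35, 0.8}, higher = positive; concordant pairs 3 of 4
        res = roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], orientation="high")
        assert res.auc == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(UndefinedROCError):
            roc([0.1, 0.2], [1, 1], orientation="low")

    def test_auc_equals_brute_force_concordance(self):
        """Trapezoidal AUC is the tie-corrected concordance probability."""
        rng = np.random.default_rng(0)
        for n in (10, 50, 200):
            for trial in range(5):
                scores = np.round(rng.normal(size=n), 1)  # induce ties
                labels = (rng.random(n) < 0.4).astype(int)
                if labels.min() == labels.max():
                    continue
                res = roc(scores, labels, orientation="high")
                assert res.auc == pytest.approx(
                    auc_concordance(scores, labels), abs=1e-12)

    def test_orientation_flip_preserves_auc(self):
        rng = np.random.default_rng(1)
        s = rng.random(40)
        lab = (rng.random(40) < 0.5).astype(int)
        lab[0], lab[1] = 0, 1
        assert roc(s, lab, "high").auc == pytest.approx(
            roc(-s, lab, "low").auc)


class TestOptimalCutoff:
    def test_perfect_classifier(self):
        res = roc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1], orientation="low")
        thr, se, sp = optimal_cutoff(res)
        assert se == 1.0 and sp == 1.0
        assert 0.2 <= thr < 0.8  # inclusive threshold convention

    def test_threshold_reported_on_original_scale(self):
        scores = np.array([0.1, 0.3, 0.5, 0.7])
        res = roc(scores, [1, 1, 0, 0], orientation="low")
        thr, _, _ = optimal_cutoff(res)
        assert 0.1 <= thr <= 0.7

    def test_tie_breaks_toward_higher_sp(self):
        # two operating points share max J; the higher-specificity one wins
        scores = [1, 2, 3, 4, 5, 6]
        labels = [1, 1, 0, 1, 0, 0]
        res = roc(scores, labels, orientation="low")
        j = res.se + res.sp - 1
        best = j.max()
        _, se, sp = optimal_cutoff(res)
        candidates = [(s, p) for s, p, jj in zip(res.se, res.sp, j)
                      if jj == pytest.approx(best)]
        assert sp == max(p for _, p in candidates)


class TestSEAtFixedSP:
    def test_perfect_classifier(self):
        res = roc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1], orientation="low")
        assert se_at_fixed_sp(res, 0.9) == 1.0

    def test_hand_enumerated_operating_points(self):
        # positives at 0.1 and 0.3 (low = positive); negatives 0.2,0.4,0.5,0.6
        scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        labels = [1, 0, 1, 0, 0, 0]
        res = roc(scores, labels, orientation="low")
        # step rule by hand: SP=1 attainable only below 0.2 -> SE=0.5;
        # any threshold catching 0.3 also catches 0.2 -> SP=0.75 < 0.9
        assert se_at_fixed_sp(res, 0.9) == pytest.approx(0.5)

    def test_non_increasing_in_sp_floor(self):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        labels = (rng.random(60) < 0.4).astype(int)
        labels[:2] = [0, 1]
        res = roc(scores, labels, orientation="low")
        values = [se_at_fixed_sp(res, sp) for sp in (0.5, 0.7, 0.9, 0.99)]
        assert values == sorted(values, reverse=True)


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy_at_threshold([0.1, 0.9], [1, 0], 0.5) == 1.0

    def test_threshold_below_all_scores(self):
        # nobody called positive -> accuracy = prevalence of non-osteoporosis
        labels = np.array([1, 0, 0, 0])
        acc = accuracy_at_threshold([0.5, 0.6, 0.7, 0.8], labels, 0.0)
        assert acc == pytest.approx(0.75)


class TestDeLong:
    def _paired(self, seed=7, n=30):
        rng = np.random.default_rng(seed)
        lab = np.array([0] * 18 + [1] * 12)
        s1 = rng.normal(0, 1, n) + 0.8 * lab
        s2 = rng.normal(0, 1, n) + 0.3 * lab
        return s1, s2, lab

    def test_identical_scores(self):
        s1, _, lab = self._paired()
        res = delong_test(s1, s1, lab)
        assert res.z == 0.0 and res.p == 1.0

    def test_monotone_transform_zero_auc_difference(self):
        s1, _, lab = self._paired()
        res = delong_test(s1, np.exp(s1), lab)
        assert res.auc1 == pytest.approx(res.auc2)
        assert res.p == pytest.approx(1.0)

    def test_antisymmetric_in_argument_order(self):
        s1, s2, lab = self._paired()
        a = delong_test(s1, s2, lab)
        b = delong_test(s2, s1, lab)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_variance_positive_for_nondegenerate_input(self):
        s1, s2, lab = self._paired()
        assert delong_test(s1, s2, lab).var_diff > 0

    def test_known_instance_against_external_reference(self):
        rng = np.random.default_rng(7)
        n = 30
        lab = (rng.random(n) < 0.4).astype(int)
        s1 = rng.normal(0, 1, n) + 0.8 * lab
        s2 = rng.normal(0, 1, n) + 0.3 * lab
        res = delong_test(s1, s2, lab)
        # frozen oracle: R pROC roc.test(..., method="delong", paired=TRUE)
        assert res.auc1 == pytest.approx(0.715, abs=1e-3)
        assert res.auc2 == pytest.approx(0.475, abs=1e-3)
        assert res.z == pytest.approx(1.84319, abs=1e-4)
        assert res.p == pytest.approx(0.06530, abs=1e-4)


class TestNormality:
    def test_standard_normal_calibration(self):
        rng = np.random.default_rng(0)
        passes = sum(dagostino_pearson(rng.normal(0, 1, 230)).passes
                     for _ in range(100))
        assert passes >= 95

    def test_lognormal_rejected(self):
        rng = np.random.default_rng(1)
        rejections = sum(not dagostino_pearson(rng.lognormal(0, 1, 230)).passes
                         for _ in range(50))
        assert rejections >= 49

    def test_mirror_symmetric_sample_zero_skewness(self):
        v = np.concatenate([np.arange(1, 20), -np.arange(1, 20), [0]])
        rep = dagostino_pearson(v.astype(float))
        assert rep.skewness == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            dagostino_pearson(np.arange(10))


class TestGroupCompare:
    def test_identical_groups_large_p(self):
        v = np.tile(np.arange(10.0), 2)
        g = np.repeat(["a", "b"], 10)
        res = group_compare(v, g)
        assert res.anova_p > 0.5

    def test_planted_shift_detected(self):
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            v = np.concatenate([rng.normal(0, 1, 60), rng.normal(1, 1, 60)])
            g = np.repeat(["a", "b"], 60)
            hits += group_compare(v, g).anova_p < 0.01
        assert hits >= 29

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)])
        g = np.repeat(["a", "b"], 15)
        res = group_compare(v, g)
        t = stats.ttest_ind(v[:15], v[15:])
        assert res.anova_f == pytest.approx(t.statistic**2)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])


@pytest.fixture(scope="module")
def small_cv():
    cohort = generate_cohort(GeneratorConfig(n=120), seed=4)
    return cohort, kfold_cv(cohort, MODEL_FEATURES, k=4, seed=4)


class TestKFoldCV:
    def test_every_participant_scored_once(self, small_cv):
        cohort, cv = small_cv
        assert np.isfinite(cv.scores).all()
        assert len(cv.scores) == len(cohort)

    def test_fold_sizes_nearly_equal(self, small_cv):
        _, cv = small_cv
        sizes = np.bincount(cv.fold_assignment)
        assert sizes.sum() == 120 and max(sizes) - min(sizes) <= 1

    def test_no_reference_leakage(self, small_cv):
        """A held-out participant never appears in the derivative-feature
        reference of the model that scores her fold."""
        cohort, cv = small_cv
        ids = cohort.ids
        for f, ref in enumerate(cv.fold_reference_ids):
            held_out = {str(i) for i in ids[cv.fold_assignment == f]}
            assert not (held_out & ref)

    def test_out_of_fold_scores_carry_signal(self, small_cv):
        _, cv = small_cv
        assert cv.rho > 0.2
        assert cv.roc.auc > 0.55

    def test_ten_folds_of_23_for_full_cohort_size(self):
        n, k = 230, 10
        sizes = np.diff(np.linspace(0, n, k + 1).astype(int))
        assert list(sizes) == [23] * 10
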