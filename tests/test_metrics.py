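"""One-vs-rest AUC averaging, segmentation suite, kappa and fold aggregation."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import histoswt as hs
from histoswt.metrics import ConfusionCounts

from conftest import pairwise_auc


def multiclass_pairwise_micro(truth, scores):
    """Pooled one-vs-rest pairwise-ranking oracle for micro-AUC."""
    k = scores.shape[1]
    onehot = np.eye(k, dtype=int)[truth]
    return pairwise_auc(onehot.ravel(), scores.ravel())


def multiclass_pairwise_macro(truth, scores):
    """Mean of per-class pairwise-ranking AUCs (macro 'mean' variant oracle)."""
    k = scores.shape[1]
    return np.mean([pairwise_auc((truth == i).astype(int), scores[:, i])
                    for i in range(k)])


class TestAucMicro:
    def test_perfect_ranking_gives_one(self):
        truth = np.array([0, 1, 2])
        scores = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        assert hs.auc_micro(truth, scores) == pytest.approx(1.0)

    def test_identical_scores_give_chance_level(self):
        truth = np.array([0, 1, 2, 0])
        scores = np.full((4, 3), 1 / 3)
        assert hs.auc_micro(truth, scores) == pytest.approx(0.5)

    def test_matches_pairwise_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            truth = rng.integers(0, 3, n)
            scores = rng.random((n, 3))
            assert hs.auc_micro(truth, scores) == pytest.approx(
                multiclass_pairwise_micro(truth, scores), abs=1e-9)

    def test_invariant_under_monotone_score_transform(self, rng):
        truth = rng.integers(0, 3, 20)
        scores = rng.random((20, 3))
        warped = np.exp(3 * scores)
        assert hs.auc_micro(truth, scores) == pytest.approx(
            hs.auc_micro(truth, warped), abs=1e-12)

    def test_permuted_truth_concentrates_at_half(self):
        rng = np.random.default_rng(99)
        truth = rng.integers(0, 3, 500)
        scores = rng.random((500, 3))
        assert abs(hs.auc_micro(rng.permutation(truth), scores) - 0.5) < 0.05


class TestAucMacro:
    def test_perfect_ranking_gives_one_both_variants(self):
        truth = np.array([0, 1, 2])
        scores = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        assert hs.auc_macro(truth, scores, variant="curve") == pytest.approx(1.0)
        assert hs.auc_macro(truth, scores, variant="mean") == pytest.approx(1.0)

    def test_mean_variant_matches_per_class_pairwise_oracle(self, rng):
        for _ in range(50):
            truth = np.array([0, 0, 1, 1, 2, 2, 0, 1])
            scores = rng.random((8, 3))
            assert hs.auc_macro(truth, scores, variant="mean") == pytest.approx(
                multiclass_pairwise_macro(truth, scores), abs=1e-9)

    def test_two_class_complementary_scores_collapse_to_binary_auc(self, rng):
        # each class's one-vs-rest problem is the mirror of the same binary
        # problem, so the macro mean collapses to the plain binary AUC; the
        # pooled micro expansion mixes the two mirrored problems and is
        # checked against its own pooled pairwise oracle instead
        truth = rng.integers(0, 2, 30)
        s = rng.random(30)
        scores = np.stack([1 - s, s], axis=1)
        binary = pairwise_auc(truth, s)
        assert hs.auc_macro(truth, scores, variant="mean") == pytest.approx(binary, abs=1e-9)
        assert hs.auc_micro(truth, scores) == pytest.approx(
            multiclass_pairwise_micro(truth, scores), abs=1e-9)

    def test_curve_variant_within_unit_interval_and_monotone_invariant(self, rng):
        truth = rng.integers(0, 3, 30)
        scores = rng.random((30, 3))
        v = hs.auc_macro(truth, scores, variant="curve")
        assert 0.0 <= v <= 1.0
        assert hs.auc_macro(truth, np.exp(scores), variant="curve") == pytest.approx(
            v, abs=1e-12)

    def test_absent_class_raises_naming_it(self):
        truth = np.array([0, 0, 1, 1])
        scores = np.random.default_rng(0).random((4, 3))
        with pytest.raises(hs.UndefinedMetricError, match="class 2"):
            hs.auc_macro(truth, scores)


class TestConfusion:
    def test_exact_prediction_has_no_errors(self, rng):
        mask = rng.integers(0, 2, (6, 6))
        cc = hs.confusion(mask, mask, k=2)
        np.testing.assert_array_equal(cc.fp, 0)
        np.testing.assert_array_equal(cc.fn, 0)

    def test_hand_counted_binary_grid(self):
        # 4x4 grid engineered to tp=4, fp=2, fn=2, tn=8 for class 1
        truth = np.zeros((4, 4), dtype=int)
        truth[0] = 1
        truth[1, :2] = 1
        pred = np.zeros((4, 4), dtype=int)
        pred[0] = 1
        pred[2, :2] = 1
        cc = hs.confusion(pred, truth, k=2)
        assert (cc.tp[1], cc.fp[1], cc.fn[1], cc.tn[1]) == (4, 2, 2, 8)

    def test_swapping_pred_and_truth_swaps_fp_fn(self, rng):
        a = rng.integers(0, 3, (5, 5))
        b = rng.integers(0, 3, (5, 5))
        cc = hs.confusion(a, b, k=3)
        cs = hs.confusion(b, a, k=3)
        np.testing.assert_array_equal(cc.fp, cs.fn)
        np.testing.assert_array_equal(cc.fn, cs.fp)

    def test_counts_conserved_per_class(self, rng):
        a = rng.integers(0, 3, (7, 7))
        b = rng.integers(0, 3, (7, 7))
        cc = hs.confusion(a, b, k=3)
        np.testing.assert_array_equal(cc.tp + cc.fp + cc.fn + cc.tn, 49)


class TestSegmentationSuite:
    def test_identical_masks_score_one_everywhere(self, rng):
        mask = rng.integers(0, 2, (8, 8))
        suite = hs.segmentation_suite(hs.confusion(mask, mask, k=2))
        for name in ("miou", "f1", "acc", "precision", "sensitivity", "specificity"):
            assert suite[name] == pytest.approx(1.0)

    def test_worked_counts_match_direct_substitution(self):
        cc = ConfusionCounts(tp=np.array([4]), fp=np.array([2]),
                             fn=np.array([2]), tn=np.array([8]))
        suite = hs.segmentation_suite(cc)
        per = suite["per_class"]
        assert per["iou"][0] == pytest.approx(0.5)
        assert per["f1"][0] == pytest.approx(2 / 3, abs=1e-4)
        assert per["acc"][0] == pytest.approx(0.75)
        assert per["precision"][0] == pytest.approx(2 / 3, abs=1e-4)
        assert per["sensitivity"][0] == pytest.approx(2 / 3, abs=1e-4)
        assert per["specificity"][0] == pytest.approx(0.8)

    def test_f1_is_algebraic_function_of_iou(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 50, 4)
            cc = ConfusionCounts(*(np.array([v]) for v in counts))
            suite = hs.segmentation_suite(cc)
            iou = suite["per_class"]["iou"][0]
            assert suite["per_class"]["f1"][0] == pytest.approx(
                2 * iou / (1 + iou), abs=1e-12)

    def test_zero_denominator_reported_undefined_not_zero(self):
        cc = ConfusionCounts(tp=np.array([0, 5]), fp=np.array([0, 0]),
                             fn=np.array([0, 0]), tn=np.array([5, 0]))
        with pytest.warns(RuntimeWarning, match="undefined"):
            suite = hs.segmentation_suite(cc)
        assert np.isnan(suite["per_class"]["iou"][0])
        assert suite["miou"] == pytest.approx(1.0)  # defined class only

    def test_miou_bounded_by_per_class_ious(self, rng):
        a = rng.integers(0, 2, (10, 10))
        b = rng.integers(0, 2, (10, 10))
        suite = hs.segmentation_suite(hs.confusion(a, b, k=2))
        ious = suite["per_class"]["iou"]
        assert np.nanmin(ious) <= suite["miou"] <= np.nanmax(ious)


class TestCohenKappa:
    def test_identical_ratings_give_one(self):
        assert hs.cohen_kappa([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 3000)
        b = rng.integers(0, 3, 3000)
        assert abs(hs.cohen_kappa(a, b)) < 0.05

    def test_two_by_two_agreement_table_hand_value(self):
        # table a=20 (0,0), b=5 (0,1), c=10 (1,0), d=15 (1,1):
        # p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        assert hs.cohen_kappa(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_matches_sklearn_on_random_ratings(self, rng):
        a = rng.integers(0, 4, 100)
        b = rng.integers(0, 4, 100)
        assert hs.cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hs.cohen_kappa([0, 1], [0, 1, 2])


class TestAggregateFolds:
    def test_single_fold_sigma_zero(self):
        report = hs.aggregate_folds([{"auc": 0.9}])
        assert report.metrics["auc"] == (0.9, 0.0)

    def test_population_sigma_closed_form(self):
        report = hs.aggregate_folds([{"m": 0.8}, {"m": 1.0}])
        mean, sigma = report.metrics["m"]
        assert mean == pytest.approx(0.9)
        assert sigma == pytest.approx(0.1)  # divide-by-n convention

    def test_inconsistent_keys_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            hs.aggregate_folds([{"a": 1.0}, {"b": 1.0}])
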