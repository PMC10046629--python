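"""Metric definitions, identities and fold statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from mwbrain.evaluation import (
    classwise_metrics,
    confusion_matrix,
    fold_statistics,
    percent,
    pixel_metrics,
    segmentation_metrics,
)

# Misclassification counts reported for the three-class task: raw images
# (34 errors) and segmented images (5 errors), 100 test images per class.
RAW_CONFUSION = np.array([[97, 3, 0], [6, 86, 8], [3, 14, 83]])
SEG_CONFUSION = np.array([[100, 0, 0], [1, 96, 3], [0, 1, 99]])


class TestPixelMetrics:
    def test_perfect_prediction(self):
        m = np.zeros((16, 16), bool)
        m[2:6, 3:9] = True
        r = pixel_metrics(m, m)
        assert (r.accuracy, r.iou, r.dice) == (1.0, 1.0, 1.0)

    def test_half_overlap_counts(self):
        """100-px masks overlapping 50 px: IoU 1/3, Dice 1/2."""
        pred = np.zeros((256, 256), bool)
        truth = np.zeros((256, 256), bool)
        pred[0, 0:100] = True
        truth[0, 50:150] = True
        r = pixel_metrics(pred, truth)
        assert r.iou == pytest.approx(1 / 3)
        assert r.dice == pytest.approx(0.5)
        assert r.accuracy == pytest.approx(1 - 100 / 256 ** 2)

    def test_empty_vs_empty_scores_one(self):
        r = pixel_metrics(np.zeros((8, 8), bool), np.zeros((8, 8), bool))
        assert r.iou == 1.0 and r.dice == 1.0 and r.accuracy == 1.0

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(deadline=None, max_examples=40)
    def test_dice_iou_identity(self, seed):
        """DSC = 2*IoU/(1+IoU) for any mask pair."""
        rng = np.random.default_rng(seed)
        pred = rng.random((12, 12)) > 0.7
        truth = rng.random((12, 12)) > 0.7
        r = pixel_metrics(pred, truth)
        assert r.dice == pytest.approx(2 * r.iou / (1 + r.iou), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_metrics(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_per_image_vs_pooled_aggregation(self):
        a_pred = np.ones((4, 4), bool)
        a_truth = np.ones((4, 4), bool)
        b_pred = np.zeros((4, 4), bool)
        b_truth = np.ones((4, 4), bool)
        per = segmentation_metrics([a_pred, b_pred], [a_truth, b_truth])
        pooled = segmentation_metrics([a_pred, b_pred], [a_truth, b_truth],
                                      pooled=True)
        assert per.dice == pytest.approx(0.5)       # mean of 1 and 0
        assert pooled.dice == pytest.approx(2 * 16 / (2 * 16 + 16))


class TestClasswiseMetrics:
    def test_raw_image_worked_example(self):
        m = classwise_metrics(RAW_CONFUSION).as_percent()
        # overall accuracy is trace/total = 266/300; with equal class sizes
        # it coincides with weighted recall by construction
        assert m["accuracy"] == pytest.approx(88.67, abs=0.01)
        assert m["precision"] == pytest.approx(88.74, abs=0.01)
        assert m["recall"] == pytest.approx(88.67, abs=0.01)
        assert m["specificity"] == pytest.approx(94.33, abs=0.01)
        # 88.61 as printed arises from intermediate rounding; full precision
        # gives 88.6049 -> 88.60 at two decimals
        assert m["f1"] == pytest.approx(88.61, abs=0.011)

    def test_segmented_image_worked_example(self):
        m = classwise_metrics(SEG_CONFUSION).as_percent()
        assert m["accuracy"] == pytest.approx(98.33, abs=0.01)
        assert m["precision"] == pytest.approx(98.35, abs=0.01)
        assert m["recall"] == pytest.approx(98.33, abs=0.01)
        assert m["specificity"] == pytest.approx(99.17, abs=0.01)
        assert m["f1"] == pytest.approx(98.33, abs=0.01)

    def test_diagonal_matrix_scores_100(self):
        m = classwise_metrics(np.diag([30, 30, 30])).as_percent()
        assert all(v == 100.0 for v in m.values())

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(deadline=None, max_examples=30)
    def test_weighted_recall_equals_accuracy_for_equal_row_sums(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((3, 3), int)
        for row in range(3):
            picks = rng.integers(0, 3, size=50)
            for p in picks:
                m[row, p] += 1
        r = classwise_metrics(m)
        assert r.recall == pytest.approx(r.accuracy, abs=1e-12)

    def test_permutation_invariance(self):
        perm = [2, 0, 1]
        base = classwise_metrics(RAW_CONFUSION)
        permuted = classwise_metrics(RAW_CONFUSION[np.ix_(perm, perm)])
        for k in ("accuracy", "precision", "recall", "specificity", "f1"):
            assert getattr(base, k) == pytest.approx(getattr(permuted, k))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            classwise_metrics(np.zeros((3, 3)))

    def test_confusion_matrix_builder(self):
        m = confusion_matrix([0, 1, 2, 1], [0, 2, 2, 1])
        assert m[1, 2] == 1 and m[1, 1] == 1 and m.sum() == 4


class TestFoldStatistics:
    def test_identical_fold_values_zero_std(self):
        r = fold_statistics([0.9] * 5)
        assert r.mean == 0.9 and r.std == 0.0

    def test_degenerate_paired_test_flagged(self):
        """Model equal to baseline fold-for-fold: p reported as 1."""
        r = fold_statistics([0.8, 0.9, 0.85], [0.8, 0.9, 0.85])
        assert r.p_value == 1.0 and r.degenerate

    def test_constant_nonzero_shift_is_limit_case(self):
        """Exactly constant paired differences: t undefined, p at its limit."""
        r = fold_statistics([0.8, 0.9, 0.85, 0.95, 0.9],
                            [0.7, 0.8, 0.75, 0.85, 0.8])
        assert r.degenerate and r.p_value == 0.0 and r.t_stat == np.inf

    def test_matches_textbook_paired_t(self):
        """t = mean(d) / (sd(d)/sqrt(n)), cross-checked against scipy."""
        model = [0.8, 0.9, 0.85, 0.95, 0.9]
        base = [0.7, 0.82, 0.74, 0.86, 0.79]
        d = np.array(model) - np.array(base)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * sstats.t.sf(abs(t_hand), df=len(d) - 1)
        r = fold_statistics(model, base)
        assert r.t_stat == pytest.approx(t_hand)
        assert r.p_value == pytest.approx(p_hand)

    def test_single_fold_has_no_test(self):
        r = fold_statistics([0.9], [0.8])
        assert r.p_value is None and r.degenerate


class TestPercentRounding:
    def test_half_up_at_two_decimals(self):
        assert percent(0.886049) == 88.6
        assert percent(0.8860494, 2) == 88.6
        assert percent(0.88605) == 88.61   # decimal half-up, not banker's
        assert percent(0.983459) == 98.35
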