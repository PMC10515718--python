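"""Confusion counts, the six accuracy scores, FPS and overlay rendering."""

import numpy as np
import pytest

from dme_deeplab import confusion_counts, metric_report, render_overlay
from dme_deeplab.metrics import ConfusionCounts


def brute_force_report(pred, true):
    """Per-pixel recomputation of all six scores, independent of the
    vectorized tabulation."""
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), true.ravel()):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 1 and p == 0:
            fn += 1
        else:
            tn += 1
    total = tp + fp + fn + tn
    safe = lambda n, d: n / d if d else 1.0
    pa = (tp + tn) / total
    mpa = 0.5 * (safe(tn, tn + fp) + safe(tp, tp + fn))
    pre = safe(tp, tp + fp)
    re = safe(tp, tp + fn)
    f1 = safe(2 * pre * re, pre + re)
    miou = 0.5 * (safe(tn, tn + fp + fn) + safe(tp, tp + fp + fn))
    return dict(PA=pa, MPA=mpa, Pre=pre, Re=re, F1=f1, MIoU=miou)


class TestConfusionCounts:
    def test_identity_prediction_has_no_errors(self, rng):
        mask = (rng.random((9, 9)) > 0.6).astype(np.uint8)
        c = confusion_counts(mask, mask)
        assert c.FP == 0 and c.FN == 0
        assert c.TP == int(mask.sum())

    def test_all_positive_prediction_on_empty_truth(self):
        c = confusion_counts(np.ones((4, 4), int), np.zeros((4, 4), int))
        assert (c.TP, c.FP, c.FN, c.TN) == (0, 16, 0, 0)

    def test_hand_counted_toy_mask(self):
        true = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]])
        pred = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        c = confusion_counts(pred, true)
        assert (c.TP, c.FN, c.FP) == (2, 2, 1)

    def test_shape_and_value_validation(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2), int), np.zeros((3, 3), int))
        with pytest.raises(ValueError):
            confusion_counts(np.full((2, 2), 2), np.zeros((2, 2), int))


class TestMetricReport:
    def test_perfect_prediction_scores_one_everywhere(self, rng):
        mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        r = metric_report(confusion_counts(mask, mask))
        assert (r.PA, r.MPA, r.Pre, r.Re, r.F1, r.MIoU) == (1, 1, 1, 1, 1, 1)

    def test_hand_substituted_counts(self):
        # TP=2, FP=1, FN=2, TN=4
        r = metric_report(ConfusionCounts(np.array([[4, 1], [2, 2]])))
        assert r.Pre == pytest.approx(2 / 3)
        assert r.Re == pytest.approx(1 / 2)
        assert r.F1 == pytest.approx(4 / 7)
        assert r.MIoU == pytest.approx((4 / 7 + 2 / 5) / 2)

    def test_degenerate_all_background_scores_one_by_convention(self):
        z = np.zeros((5, 5), int)
        r = metric_report(confusion_counts(z, z))
        assert r.Pre == 1.0 and r.Re == 1.0 and r.MIoU == 1.0

    def test_fps_from_frame_count_and_elapsed_time(self):
        r = metric_report(ConfusionCounts(np.array([[1, 0], [0, 1]])),
                          frame_num=171, elapsed_time=18.94)
        assert r.FPS == pytest.approx(171 / 18.94)
        with pytest.raises(ValueError):
            metric_report(ConfusionCounts(np.eye(2, dtype=int)),
                          frame_num=1, elapsed_time=0.0)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            pred = (rng.random((32, 32)) > rng.uniform(0.3, 0.95)).astype(np.uint8)
            true = (rng.random((32, 32)) > rng.uniform(0.3, 0.95)).astype(np.uint8)
            r = metric_report(confusion_counts(pred, true)).to_dict()
            expected = brute_force_report(pred, true)
            for k, v in expected.items():
                assert r[k] == pytest.approx(v, abs=1e-12), k

    def test_invariants_on_random_pairs(self, rng):
        for _ in range(50):
            pred = (rng.random((24, 24)) > 0.6).astype(np.uint8)
            true = (rng.random((24, 24)) > 0.6).astype(np.uint8)
            r = metric_report(confusion_counts(pred, true))
            vals = [r.PA, r.MPA, r.Pre, r.Re, r.F1, r.MIoU]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert r.MIoU <= r.PA + 1e-12
            assert min(r.Pre, r.Re) - 1e-12 <= r.F1 <= max(r.Pre, r.Re) + 1e-12

    def test_label_swap_symmetry(self, rng):
        # PA/MPA/MIoU are invariant under swapping labels in both masks;
        # Pre/Re are class-1 specific and generally change.
        pred = (rng.random((20, 20)) > 0.7).astype(np.uint8)
        true = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        r = metric_report(confusion_counts(pred, true))
        rs = metric_report(confusion_counts(1 - pred, 1 - true))
        assert rs.PA == pytest.approx(r.PA)
        assert rs.MPA == pytest.approx(r.MPA)
        assert rs.MIoU == pytest.approx(r.MIoU)
        assert rs.Pre != pytest.approx(r.Pre) or rs.Re != pytest.approx(r.Re)


class TestOverlay:
    def test_pixelwise_color_assignment(self):
        true = np.array([[1, 1, 0], [0, 0, 0]])
        pred = np.array([[1, 0, 1], [0, 0, 0]])
        img = render_overlay(pred, true)
        assert tuple(img[0, 0]) == (255, 0, 0)      # TP red
        assert tuple(img[0, 1]) == (255, 255, 255)  # FN white
        assert tuple(img[0, 2]) == (0, 0, 255)      # FP blue
        assert tuple(img[1, 0]) == (0, 0, 0)        # TN background

    def test_identity_prediction_yields_only_red_and_background(self, rng):
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        img = render_overlay(mask, mask)
        red = (img == (255, 0, 0)).all(axis=2)
        assert red.sum() == mask.sum()
        assert ((img == 0).all(axis=2) | red).all()

    def test_missed_lesions_are_white(self):
        true = np.zeros((6, 6), int)
        true[2:4, 2:4] = 1
        img = render_overlay(np.zeros_like(true), true)
        assert ((img[true == 1] == 255).all())
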