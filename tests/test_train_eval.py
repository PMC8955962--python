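"""Splitting, augmentation, training behavior, and the accuracy metrics
(greedy matching, AP, matched IOU) against independent references."""

from fractions import Fraction

import numpy as np
import pytest

from synquant.detect import BBox
from synquant.synthgen import SceneParams, generate_dataset
from synquant.train_eval import (
    EvalConfig,
    TrainConfig,
    augment,
    average_precision,
    builtin_method_table,
    compare_methods,
    mask_iou,
    match_predictions,
    mean_matched_iou,
    split_dataset,
    train_models,
)


# ---------------------------------------------------------------------------
# splitting

@pytest.mark.parametrize("n,expected", [(156, (93, 31, 32)), (10, (6, 2, 2)), (5, (3, 1, 1))])
def test_split_sizes(n, expected):
    tr, te, va = split_dataset(n, seed=0)
    assert (len(tr), len(te), len(va)) == expected


def test_split_is_disjoint_cover(rng):
    for seed in range(5):
        n = int(rng.integers(5, 200))
        tr, te, va = split_dataset(n, seed=seed)
        combined = np.concatenate([tr, te, va])
        assert sorted(combined.tolist()) == list(range(n))


def test_split_too_small_errors():
    with pytest.raises(ValueError):
        split_dataset(2)


# ---------------------------------------------------------------------------
# augmentation

def _sample(rng):
    img = rng.uniform(0, 100, (24, 24))
    m = np.zeros((24, 24), bool)
    m[6:14, 8:16] = True
    return img, [m]


def test_horizontal_flip_is_involution(rng):
    img, masks = _sample(rng)
    i1, m1 = augment(img, masks, ("flip_h",), rng)
    i2, m2 = augment(i1, m1, ("flip_h",), rng)
    assert np.array_equal(i2, img)
    assert np.array_equal(m2[0], masks[0])


def test_photometric_ops_leave_masks_untouched(rng):
    img, masks = _sample(rng)
    _, m1 = augment(img, masks, ("brightness", "contrast"), rng)
    assert np.array_equal(m1[0], masks[0])


def test_crop_keeps_masks_within_bounds_and_binary(rng):
    for _ in range(10):
        img, masks = _sample(rng)
        i1, m1 = augment(img, masks, ("expand", "crop"), rng)
        for m in m1:
            assert m.dtype == bool
            assert m.shape == i1.shape
            assert m.sum() >= 10
    with pytest.raises(ValueError):
        augment(img, masks, ("rotate13",), rng)


# ---------------------------------------------------------------------------
# training harness

def _tiny_dataset(n=6, seed=0):
    params = SceneParams(
        image_height=96,
        image_width=96,
        n_z=3,
        focal_z=1,
        n_cells=2,
        cell_radius_range=(9.0, 12.0),
        boundary_contrast=1.0,
        impurity_density=0.02,
        noise_sigma=15.0,
        seed=seed,
    )
    return generate_dataset(n, params, seed=seed)


def test_smoke_training_loss_decreases():
    ds = _tiny_dataset()
    cfg = TrainConfig(epochs=5, seed=3, n_augment=0)
    _det, _seg, curve = train_models(ds, cfg)
    assert len(curve.train) == 5 and len(curve.val) == 5
    assert all(np.isfinite(curve.train))
    assert curve.train[-1] < curve.train[0]


def test_training_is_deterministic_given_seed():
    ds = _tiny_dataset()
    cfg = TrainConfig(epochs=2, seed=9)
    _, _, c1 = train_models(ds, cfg)
    _, _, c2 = train_models(ds, cfg)
    assert c1.train == c2.train
    assert c1.val == c2.val


def test_zero_epochs_rejected():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)


# ---------------------------------------------------------------------------
# metrics

def test_mask_iou_examples(rng):
    a = np.zeros((10, 10), bool)
    a[2:6, 2:6] = True
    assert mask_iou(a, a) == 1.0
    b = np.zeros((10, 10), bool)
    b[7:9, 7:9] = True
    assert mask_iou(a, b) == 0.0
    assert mask_iou(b, np.zeros((10, 10), bool)) == 0.0
    for _ in range(20):
        m1 = rng.uniform(size=(8, 8)) > 0.5
        m2 = rng.uniform(size=(8, 8)) > 0.5
        inter = sum(1 for y in range(8) for x in range(8) if m1[y, x] and m2[y, x])
        union = sum(1 for y in range(8) for x in range(8) if m1[y, x] or m2[y, x])
        expected = inter / union if union else 0.0
        assert mask_iou(m1, m2) == pytest.approx(expected)
    with pytest.raises(ValueError):
        mask_iou(a, np.zeros((5, 5), bool))


def test_match_predictions_basic_cases():
    gts = [BBox(0, 0, 10, 10), BBox(20, 20, 30, 30)]
    perfect = [BBox(0, 0, 10, 10, 0.9), BBox(20, 20, 30, 30, 0.8)]
    matches, tp, _s, n_gt = match_predictions(perfect, gts, 0.5, "box")
    assert tp.all() and len(matches) == 2 and n_gt == 2

    matches, tp, _s, n_gt = match_predictions([], gts, 0.5, "box")
    assert len(matches) == 0 and n_gt == 2  # 2 false negatives


def test_match_prefers_high_scores_and_low_gt_index():
    gts = [BBox(0, 0, 10, 10), BBox(0, 0, 10, 10)]  # identical twins
    preds = [BBox(0, 0, 10, 10, 0.6), BBox(0, 0, 10, 10, 0.9), BBox(50, 50, 60, 60, 0.99)]
    matches, tp, _s, _n = match_predictions(preds, gts, 0.5, "box")
    # the 0.9 pred matches gt 0 (lower index), the 0.6 pred matches gt 1
    assert (1, 0) in [(i, j) for i, j, _ in matches]
    assert (0, 1) in [(i, j) for i, j, _ in matches]
    assert not tp[2]


def test_average_precision_examples():
    gts = [BBox(0, 0, 10, 10), BBox(20, 20, 30, 30)]
    perfect = [BBox(0, 0, 10, 10, 0.9), BBox(20, 20, 30, 30, 0.8)]
    assert average_precision(perfect, gts, 0.5, "box") == pytest.approx(100.0)
    assert average_precision([], gts, 0.5, "box") == 0.0
    # ranked (TP, FP, TP) over 2 gts -> all-point AP = 0.5*1 + 0.5*(2/3)
    preds = [
        BBox(0, 0, 10, 10, 0.9),
        BBox(50, 50, 60, 60, 0.8),
        BBox(20, 20, 30, 30, 0.7),
    ]
    assert average_precision(preds, gts, 0.5, "box") == pytest.approx(100 * (0.5 + 0.5 * 2 / 3))
    assert np.isnan(average_precision(preds, [], 0.5, "box"))


def test_mean_matched_iou_threshold_gating():
    gt = np.zeros((10, 10), bool)
    gt[0:5, 0:10] = True  # 50 px
    pred = np.zeros((10, 10), bool)
    pred[0:5, 0:6] = True
    pred[5:7, 0:5] = True  # overlap 30, union 70 -> IoU ~0.571? tune to 0.6
    # build a pair with IoU exactly 0.6: |a|=50, overlap 37.5 not integer; use 0.6 via 30/50
    a = np.zeros((10, 10), bool)
    a[:5, :] = True  # 50
    b = np.zeros((10, 10), bool)
    b[2:5, :] = True
    b[5:7, :] = True  # 50, overlap 30, union 70 -> 3/7
    pair_iou = mask_iou(a, b)
    got = mean_matched_iou([(b, 0.9)], [a], 0.4, "mask")
    assert got == pytest.approx(100 * pair_iou)
    assert mean_matched_iou([(b, 0.9)], [a], 0.7, "mask") == 0.0
    perfect = mean_matched_iou([(a, 1.0)], [a], 0.5, "mask")
    assert perfect == 100.0


def test_ap_monotonicity_properties():
    gts = [BBox(0, 0, 10, 10)]
    tp_pred = [BBox(0, 0, 10, 10, 0.9)]
    base = average_precision(tp_pred, gts, 0.5, "box")
    with_fp = tp_pred + [BBox(40, 40, 50, 50, 0.5)]
    assert average_precision(with_fp, gts, 0.5, "box") <= base
    # score-monotone transform leaves AP unchanged
    rescored = [BBox(0, 0, 10, 10, 0.45), BBox(40, 40, 50, 50, 0.25)]
    assert average_precision(rescored, gts, 0.5, "box") == pytest.approx(
        average_precision(with_fp, gts, 0.5, "box")
    )


# ---------------------------------------------------------------------------
# method-comparison arithmetic

def test_compare_methods_zero_for_identical():
    table = builtin_method_table()
    out = compare_methods(table, "DCAN", "DCAN", "bbox_ap")
    assert out["mean"] == 0.0
    assert all(v == 0.0 for v in out["deltas"].values())


def test_compare_methods_missing_cell_named():
    table = builtin_method_table()
    with pytest.raises(KeyError, match="NoSuchMethod"):
        compare_methods(table, "NoSuchMethod", "DCAN", "bbox_ap")
    with pytest.raises(ValueError):
        compare_methods(table, "InstSeg", "DCAN", "not_a_preset")


def test_compare_methods_published_deltas():
    table = builtin_method_table()
    single = compare_methods(table, "InstSeg", "DCAN", [("bbox", 100, "AP@0.5")])
    assert single["mean"] == 18.53
    avg = compare_methods(table, "InstSeg", "CosineEmbedding", "bbox_ap")
    assert avg["mean"] == 60.70
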