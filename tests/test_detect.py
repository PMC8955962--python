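"""Keypoint Hough-voting chain: IoU, votes, grouping, box construction,
NMS — each checked against an independent brute-force reference."""

import numpy as np
import pytest

from synquant.detect import (
    DEFAULT_SCALES,
    KEYPOINT_CLASSES,
    BBox,
    KeypointMaps,
    Vote,
    box_iou,
    boxes_from_group,
    detect_cells,
    group_keypoints,
    keypoint_maps_from_boxes,
    nms,
    vote_centers,
)
from synquant.models import ThresholdKeypointModel


# ---------------------------------------------------------------------------
# box IoU

def _raster_iou(a: BBox, b: BBox) -> float:
    """Count pixels of both half-open boxes on the integer grid."""
    x1 = int(max(a.x_max, b.x_max))
    y1 = int(max(a.y_max, b.y_max))
    ga = np.zeros((y1, x1), bool)
    gb = np.zeros((y1, x1), bool)
    ga[int(a.y_min) : int(a.y_max), int(a.x_min) : int(a.x_max)] = True
    gb[int(b.y_min) : int(b.y_max), int(b.x_min) : int(b.x_max)] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union if union else 0.0


def test_box_iou_examples():
    a = BBox(0, 0, 10, 10)
    assert box_iou(a, a) == 1.0
    assert box_iou(a, BBox(20, 20, 30, 30)) == 0.0
    b = BBox(5, 5, 15, 15)
    assert box_iou(a, b) == pytest.approx(25 / 175)
    assert box_iou(a, b) == pytest.approx(_raster_iou(a, b))


def test_box_iou_properties(rng):
    for _ in range(50):
        x0, y0 = rng.integers(0, 20, 2)
        a = BBox(x0, y0, x0 + rng.integers(1, 15), y0 + rng.integers(1, 15))
        x0, y0 = rng.integers(0, 20, 2)
        b = BBox(x0, y0, x0 + rng.integers(1, 15), y0 + rng.integers(1, 15))
        v = box_iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == box_iou(b, a)
        assert v == pytest.approx(_raster_iou(a, b))
        assert (v == 1.0) == (a.as_array() == b.as_array()).all()


def test_degenerate_box_rejected():
    with pytest.raises(ValueError):
        BBox(5, 0, 5, 10)


# ---------------------------------------------------------------------------
# voting

def _maps_with_single_peak(kp_class: str, pos, offset, shape=(32, 32)):
    heat = np.zeros((1, 5, *shape))
    offs = np.zeros((1, 5, 2, *shape))
    ki = KEYPOINT_CLASSES.index(kp_class)
    x, y = pos
    heat[0, ki, y, x] = 1.0
    offs[0, ki, 0, y, x] = offset[0]
    offs[0, ki, 1, y, x] = offset[1]
    return KeypointMaps(heatmaps=heat, offsets=offs, scales=(16.0,))


def test_all_zero_heatmaps_give_no_votes():
    maps = KeypointMaps(
        heatmaps=np.zeros((1, 5, 16, 16)), offsets=np.zeros((1, 5, 2, 16, 16)), scales=(16.0,)
    )
    assert vote_centers(maps, 0) == []


def test_single_peak_vote_arithmetic():
    maps = _maps_with_single_peak("TL", (10, 10), (5, 5))
    votes = vote_centers(maps, 0, heat_threshold=0.1)
    assert len(votes) == 1
    v = votes[0]
    assert v.keypoint_class == "TL"
    assert v.position == (10.0, 10.0)
    assert v.voted_center == (15.0, 15.0)


def test_constructed_maps_vote_within_one_cell_of_true_center():
    box = BBox(20, 24, 52, 56)  # center (36, 40)
    maps = keypoint_maps_from_boxes([box], (96, 96), scales=(16.0,))
    votes = vote_centers(maps, 0, 0.1)
    assert sorted(v.keypoint_class for v in votes) == sorted(KEYPOINT_CLASSES)
    cell = 16.0 / 4
    for v in votes:
        assert abs(v.voted_center[0] - 36) < cell
        assert abs(v.voted_center[1] - 40) < cell


# ---------------------------------------------------------------------------
# grouping

def _vote(kc, center, conf=1.0, pos=(0.0, 0.0)):
    return Vote(keypoint_class=kc, position=pos, confidence=conf, voted_center=center)


def test_grouping_examples():
    near = [_vote("TL", (15.0, 15.0)), _vote("BR", (15.0, 16.0))]
    groups = group_keypoints(near, 8.0)
    assert len(groups) == 1 and len(groups[0].members) == 2

    far = [_vote("TL", (0.0, 0.0)), _vote("BR", (100.0, 100.0))]
    assert group_keypoints(far, 8.0) == []


def test_grouping_matches_bruteforce_cell_clustering(rng):
    for _ in range(30):
        votes = [
            _vote(
                KEYPOINT_CLASSES[rng.integers(5)],
                (float(rng.uniform(0, 60)), float(rng.uniform(0, 60))),
                conf=float(rng.uniform(0.1, 1.0)),
            )
            for _ in range(rng.integers(2, 12))
        ]
        cell = float(rng.choice([4.0, 8.0]))
        groups = group_keypoints(votes, cell)
        # brute force: bucket every vote by its nearest cell center, dedupe
        # classes by confidence, discard singletons
        buckets = {}
        for v in votes:
            key = (int(round(v.voted_center[0] / cell)), int(round(v.voted_center[1] / cell)))
            cur = buckets.setdefault(key, {})
            if v.keypoint_class not in cur or v.confidence > cur[v.keypoint_class].confidence:
                cur[v.keypoint_class] = v
        expected = {k: set(m) for k, m in buckets.items() if len(m) >= 2}
        got = {g.cell: set(g.members) for g in groups}
        assert got == expected


# ---------------------------------------------------------------------------
# box construction

def test_diagonal_pairs_span_box():
    g1 = group_keypoints([_vote("TL", (5.0, 5.0), pos=(0, 0)), _vote("BR", (5.0, 5.0), pos=(10, 10))], 8.0)
    assert boxes_from_group(g1[0]).as_array().tolist() == [0, 0, 10, 10]
    g2 = group_keypoints([_vote("TR", (5.0, 5.0), pos=(10, 0)), _vote("BL", (5.0, 5.0), pos=(0, 10))], 8.0)
    assert boxes_from_group(g2[0]).as_array().tolist() == [0, 0, 10, 10]


def test_three_points_with_center_reflection():
    votes = [
        _vote("TL", (5.0, 5.0), pos=(0, 0)),
        _vote("TR", (5.0, 5.0), pos=(10, 0)),
        _vote("C", (5.0, 5.0), pos=(5, 5)),
    ]
    (group,) = group_keypoints(votes, 8.0)
    box = boxes_from_group(group)
    assert box.as_array().tolist() == [0, 0, 10, 10]
    # brute-force check: solve the corner constraint system directly
    # TL -> (x0,y0)=(0,0); TR -> x1=10,y0=0; C reflections: BR=(10,10), BL=(0,10)
    assert (box.x_min, box.y_min, box.x_max, box.y_max) == (0, 0, 10, 10)


def test_underdetermined_and_inconsistent_groups_yield_none():
    # two adjacent corners: no diagonal, fewer than three members
    votes = [_vote("TL", (5.0, 5.0), pos=(0, 0)), _vote("TR", (5.0, 5.0), pos=(10, 0))]
    (group,) = group_keypoints(votes, 8.0)
    assert boxes_from_group(group) is None
    # center + one corner is also under-determined
    votes = [_vote("C", (5.0, 5.0), pos=(5, 5)), _vote("TL", (5.0, 5.0), pos=(0, 0))]
    (group,) = group_keypoints(votes, 8.0)
    assert boxes_from_group(group) is None
    # geometrically inconsistent: corners crossed
    votes = [_vote("TL", (5.0, 5.0), pos=(12, 0)), _vote("BR", (5.0, 5.0), pos=(2, 10))]
    (group,) = group_keypoints(votes, 8.0)
    assert boxes_from_group(group) is None


# ---------------------------------------------------------------------------
# NMS

def _nms_reference(boxes, thr):
    """Exhaustive O(n^2) greedy reference."""
    order = sorted(boxes, key=lambda b: (-b.score, b.x_min, b.y_min, b.x_max, b.y_max))
    keep = []
    for b in order:
        ok = True
        for k in keep:
            if box_iou(b, k) >= thr:
                ok = False
                break
        if ok:
            keep.append(b)
    return keep


def test_nms_examples():
    b = BBox(0, 0, 10, 10, score=0.9)
    assert nms([b], 0.5) == [b]
    dup = BBox(0, 0, 10, 10, score=0.8)
    assert nms([b, dup], 0.5) == [b]


def test_nms_matches_bruteforce_and_is_idempotent(rng):
    boxes = []
    for _ in range(20):
        x0, y0 = rng.integers(0, 40, 2)
        boxes.append(
            BBox(
                float(x0),
                float(y0),
                float(x0 + rng.integers(5, 20)),
                float(y0 + rng.integers(5, 20)),
                score=float(rng.uniform(0, 1)),
            )
        )
    kept = nms(boxes, 0.5)
    assert kept == _nms_reference(boxes, 0.5)
    assert set(map(id, kept)) <= set(map(id, boxes))
    assert nms(kept, 0.5) == kept  # idempotent
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            assert box_iou(a, b) < 0.5


# ---------------------------------------------------------------------------
# full chain

def test_chain_recovers_planted_boxes_exactly():
    """On noiseless constructed maps the vote->group->box chain is exact
    (boxes with integer centers, sizes matching the scale set)."""
    truth = [BBox(10, 12, 34, 36), BBox(60, 20, 92, 52), BBox(30, 70, 86, 118)]
    maps = keypoint_maps_from_boxes(truth, (160, 160), DEFAULT_SCALES)

    class _Fixed:
        scales = DEFAULT_SCALES

        def predict_maps(self, image):
            return maps

    found = detect_cells(np.zeros((160, 160)), _Fixed())
    assert len(found) == 3
    found_sorted = sorted(found, key=lambda b: b.x_min)
    for f, t in zip(found_sorted, sorted(truth, key=lambda b: b.x_min)):
        assert f.as_array().tolist() == t.as_array().tolist()


def test_blank_image_detects_nothing(oracle_models):
    detector, _ = oracle_models
    assert detect_cells(np.zeros((64, 64)), detector) == []


def test_threshold_detector_boxes_match_truth(noiseless_scene, oracle_models):
    stack, gt = noiseless_scene
    detector, _ = oracle_models
    img = stack.plane(1, gt.focal_z).astype(float)
    boxes = detect_cells(img, detector)
    assert len(boxes) == len(gt)
    for b in boxes:
        best = max(box_iou(b, BBox(*row)) for row in gt.boxes)
        assert best >= 0.9
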