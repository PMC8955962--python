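"""Bounding-box generation by multi-scale keypoint Hough voting.

Each cell is detected through five keypoint classes — the four bounding-box
corners (TL, TR, BL, BR) and the center (C).  A model predicts, at each of
four detection scales, a heatmap per keypoint class plus a two-channel
offset map giving the displacement from each keypoint toward its instance
center.  Local heatmap maxima cast Hough votes at ``position + offset``;
votes landing in the same accumulator cell form a keypoint group; a group
containing a diagonal corner pair, or at least three keypoints, fixes a
bounding box.  Greedy non-maximum suppression removes duplicates across
scales.

The same supervision geometry (:func:`keypoint_maps_from_boxes`) is used to
build training targets and to drive the chain from ground truth in tests:
on noiselessly constructed maps the chain recovers every planted box
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "KEYPOINT_CLASSES",
    "DEFAULT_SCALES",
    "BBox",
    "KeypointMaps",
    "Vote",
    "KeypointGroup",
    "box_iou",
    "keypoint_maps_from_boxes",
    "vote_centers",
    "group_keypoints",
    "boxes_from_group",
    "nms",
    "detect_cells",
]

logger = logging.getLogger(__name__)

KEYPOINT_CLASSES = ("TL", "TR", "BL", "BR", "C")

# disk radii (px) of the four detection scales; bracket the synthetic cell
# size range so every object matches some scale
DEFAULT_SCALES = (16.0, 32.0, 64.0, 128.0)

DEFAULT_HEAT_THRESHOLD = 0.1


@dataclass(frozen=True, order=True)
class BBox:
    """Axis-aligned half-open box [x_min, x_max) x [y_min, y_max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], float)


@dataclass
class KeypointMaps:
    """Per-scale heatmaps and center-offset maps.

    heatmaps: (n_scales, 5, H, W) in [0, 1]
    offsets:  (n_scales, 5, 2, H, W), channels (dx, dy) in pixels
    """

    heatmaps: np.ndarray
    offsets: np.ndarray
    scales: tuple[float, ...] = DEFAULT_SCALES

    def __post_init__(self) -> None:
        h, o = np.asarray(self.heatmaps), np.asarray(self.offsets)
        if h.ndim != 4 or h.shape[1] != len(KEYPOINT_CLASSES):
            raise ValueError(f"heatmaps must be (S, 5, H, W), got {h.shape}")
        if o.shape != (h.shape[0], h.shape[1], 2, h.shape[2], h.shape[3]):
            raise ValueError(f"offsets must be (S, 5, 2, H, W), got {o.shape}")
        if h.size and (h.min() < -1e-6 or h.max() > 1 + 1e-6):
            raise ValueError("heatmap values must lie in [0, 1]")
        if len(self.scales) != h.shape[0]:
            raise ValueError("one scale per heatmap level required")
        self.heatmaps, self.offsets = h, o


@dataclass(frozen=True)
class Vote:
    keypoint_class: str
    position: tuple[float, float]  # (x, y)
    confidence: float
    voted_center: tuple[float, float]  # (x, y)


@dataclass
class KeypointGroup:
    members: dict[str, Vote]  # keypoint class -> best vote
    cell: tuple[int, int]  # accumulator cell index (ix, iy)
    voted_center: tuple[float, float]


def box_iou(a: BBox, b: BBox) -> float:
    """Intersection over union under the half-open area convention."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def assign_scale(box: BBox, scales: tuple[float, ...]) -> int:
    """Scale whose disk radius best matches the box half-size."""
    half = max(box.x_max - box.x_min, box.y_max - box.y_min) / 2.0
    return int(np.argmin([abs(s - half) for s in scales]))


def _keypoint_positions(box: BBox) -> dict[str, tuple[float, float]]:
    cx, cy = box.center
    return {
        "TL": (box.x_min, box.y_min),
        "TR": (box.x_max, box.y_min),
        "BL": (box.x_min, box.y_max),
        "BR": (box.x_max, box.y_max),
        "C": (cx, cy),
    }


def keypoint_maps_from_boxes(
    boxes: list[BBox],
    image_shape: tuple[int, int],
    scales: tuple[float, ...] = DEFAULT_SCALES,
) -> KeypointMaps:
    """Construct ideal keypoint maps for known boxes (supervision targets).

    Around each keypoint a disk of radius ``s/2`` carries a Gaussian peak
    (value 1 at the keypoint); offsets inside the disk point from the pixel
    to the instance center.  Where disks of the same class and scale
    overlap, the stronger heat wins.
    """
    h, w = image_shape
    n_s = len(scales)
    heat = np.zeros((n_s, 5, h, w), np.float64)
    offs = np.zeros((n_s, 5, 2, h, w), np.float64)
    for box in boxes:
        si = assign_scale(box, scales)
        r = scales[si] / 2.0
        sigma = max(r / 3.0, 1.0)
        cx, cy = box.center
        for ki, kc in enumerate(KEYPOINT_CLASSES):
            kx, ky = _keypoint_positions(box)[kc]
            kx = min(max(kx, 0.0), w - 1.0)
            ky = min(max(ky, 0.0), h - 1.0)
            y0, y1 = max(0, int(ky - r)), min(h, int(ky + r) + 2)
            x0, x1 = max(0, int(kx - r)), min(w, int(kx + r) + 2)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (xx - kx) ** 2 + (yy - ky) ** 2
            g = np.exp(-d2 / (2 * sigma**2)) * (d2 <= r**2)
            patch = heat[si, ki, y0:y1, x0:x1]
            win = g > patch
            patch[win] = g[win]
            offs[si, ki, 0, y0:y1, x0:x1][win] = (cx - xx)[win]
            offs[si, ki, 1, y0:y1, x0:x1][win] = (cy - yy)[win]
    return KeypointMaps(heatmaps=heat, offsets=offs, scales=tuple(scales))


def _local_maxima(
    plane: np.ndarray, threshold: float, smooth_sigma: float = 1.0
) -> list[tuple[int, int, float]]:
    """(y, x, raw value) of local maxima whose raw value exceeds threshold.

    Maxima are located on a lightly smoothed copy of the plane (3x3
    neighborhood maximum), which consolidates jittery predicted peaks;
    plateaus collapse to their centroid.  Confidence is read from the raw
    plane so isolated single-pixel peaks keep their full weight.
    """
    sm = ndimage.gaussian_filter(plane, smooth_sigma) if smooth_sigma > 0 else plane
    mx = ndimage.maximum_filter(sm, size=3, mode="nearest")
    cand = (sm >= mx) & (sm > 1e-9)
    if not cand.any():
        return []
    lab, n = ndimage.label(cand, structure=np.ones((3, 3)))
    out = []
    for cy, cx in ndimage.center_of_mass(cand, lab, index=range(1, n + 1)):
        y, x = int(round(cy)), int(round(cx))
        if plane[y, x] > threshold:
            out.append((y, x, float(plane[y, x])))
    return out


def vote_centers(
    maps: KeypointMaps,
    scale_index: int,
    heat_threshold: float = DEFAULT_HEAT_THRESHOLD,
) -> list[Vote]:
    """Extract heatmap local maxima and cast their center votes."""
    votes: list[Vote] = []
    for ki, kc in enumerate(KEYPOINT_CLASSES):
        plane = maps.heatmaps[scale_index, ki]
        for y, x, conf in _local_maxima(plane, heat_threshold):
            dx = float(maps.offsets[scale_index, ki, 0, y, x])
            dy = float(maps.offsets[scale_index, ki, 1, y, x])
            votes.append(
                Vote(
                    keypoint_class=kc,
                    position=(float(x), float(y)),
                    confidence=conf,
                    voted_center=(x + dx, y + dy),
                )
            )
    return votes


def group_keypoints(votes: list[Vote], accumulator_cell_size: float) -> list[KeypointGroup]:
    """Group votes whose centers fall in the same accumulator cell.

    Cells are centered on multiples of the cell size (votes snap to the
    nearest bin), so votes within half a cell of a common bin center merge.
    Within a cell, each keypoint class contributes its highest-confidence
    vote; cells holding fewer than two distinct classes are discarded.
    """
    if accumulator_cell_size <= 0:
        raise ValueError("accumulator_cell_size must be positive")
    cells: dict[tuple[int, int], dict[str, Vote]] = {}
    for v in sorted(
        votes, key=lambda v: (-v.confidence, v.position[1], v.position[0], v.keypoint_class)
    ):
        key = (
            int(np.round(v.voted_center[0] / accumulator_cell_size)),
            int(np.round(v.voted_center[1] / accumulator_cell_size)),
        )
        members = cells.setdefault(key, {})
        members.setdefault(v.keypoint_class, v)  # highest confidence arrives first
    groups = []
    for key in sorted(cells):
        members = cells[key]
        if len(members) < 2:
            continue
        cx = float(np.mean([m.voted_center[0] for m in members.values()]))
        cy = float(np.mean([m.voted_center[1] for m in members.values()]))
        groups.append(KeypointGroup(members=members, cell=key, voted_center=(cx, cy)))
    return groups


# which box coordinates each corner class pins down
_CORNER_COORDS = {
    "TL": ("x_min", "y_min"),
    "TR": ("x_max", "y_min"),
    "BL": ("x_min", "y_max"),
    "BR": ("x_max", "y_max"),
}
_DIAGONAL = {"TL": "BR", "BR": "TL", "TR": "BL", "BL": "TR"}


def boxes_from_group(group: KeypointGroup) -> BBox | None:
    """Build a box from a keypoint group, or None if under-determined.

    A diagonal corner pair (TL+BR or TR+BL) spans the box directly.
    Otherwise at least three members are required; when the center C is a
    member, each known corner is reflected through C to impute its diagonal
    partner.  Coordinates supported by several members are averaged.
    """
    members = group.members
    has_diagonal = any(kc in members and _DIAGONAL[kc] in members for kc in _CORNER_COORDS)
    if not has_diagonal and len(members) < 3:
        return None

    evidence: dict[str, list[float]] = {"x_min": [], "x_max": [], "y_min": [], "y_max": []}
    center = members.get("C")
    for kc, (xc, yc) in _CORNER_COORDS.items():
        if kc in members:
            x, y = members[kc].position
            evidence[xc].append(x)
            evidence[yc].append(y)
            if center is not None:
                # reflect through C to impute the diagonal corner
                mx, my = center.position
                dxc, dyc = _CORNER_COORDS[_DIAGONAL[kc]]
                evidence[dxc].append(2 * mx - x)
                evidence[dyc].append(2 * my - y)
    if any(not v for v in evidence.values()):
        return None
    x_min = float(np.mean(evidence["x_min"]))
    x_max = float(np.mean(evidence["x_max"]))
    y_min = float(np.mean(evidence["y_min"]))
    y_max = float(np.mean(evidence["y_max"]))
    if x_min >= x_max or y_min >= y_max:
        logger.debug("geometrically inconsistent keypoint group at cell %s", group.cell)
        return None
    score = float(np.mean([m.confidence for m in members.values()]))
    return BBox(x_min, y_min, x_max, y_max, score=min(max(score, 0.0), 1.0))


def nms(boxes: list[BBox], iou_threshold: float = 0.5) -> list[BBox]:
    """Greedy non-maximum suppression (suppress at IoU >= threshold)."""
    order = sorted(boxes, key=lambda b: (-b.score, b.x_min, b.y_min, b.x_max, b.y_max))
    kept: list[BBox] = []
    for b in order:
        if all(box_iou(b, k) < iou_threshold for k in kept):
            kept.append(b)
    return kept


def detect_cells(
    image: np.ndarray,
    model,
    heat_threshold: float = DEFAULT_HEAT_THRESHOLD,
    nms_iou: float = 0.5,
) -> list[BBox]:
    """Full detection chain: maps -> votes -> groups -> boxes -> NMS.

    ``model`` must expose ``predict_maps(image) -> KeypointMaps`` (see
    :mod:`synquant.models`).  Deterministic given the model and the image.
    """
    maps = model.predict_maps(np.asarray(image, np.float64))
    boxes: list[BBox] = []
    for si, s in enumerate(maps.scales):
        votes = vote_centers(maps, si, heat_threshold)
        # half the scale radius: wide enough to absorb the offset noise of
        # learned votes, narrow enough to separate neighboring cells
        cell = s / 2.0
        # accumulate under half-cell-shifted grids as well, so votes that
        # straddle a bin boundary still meet in some grid; NMS dedupes the
        # resulting duplicate boxes
        for sx, sy in ((0.0, 0.0), (0.5, 0.5), (0.5, 0.0), (0.0, 0.5)):
            shifted = [
                Vote(
                    keypoint_class=v.keypoint_class,
                    position=v.position,
                    confidence=v.confidence,
                    voted_center=(
                        v.voted_center[0] + sx * cell,
                        v.voted_center[1] + sy * cell,
                    ),
                )
                for v in votes
            ]
            for g in group_keypoints(shifted, accumulator_cell_size=cell):
                box = boxes_from_group(g)
                if box is not None:
                    boxes.append(box)
    return nms(boxes, nms_iou)
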