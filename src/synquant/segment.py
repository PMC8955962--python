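"""Patch-wise instance segmentation and mask geometry.

Detected boxes are expanded by a margin, cropped into patches, segmented
one cell at a time (so neighbors do not interfere), and pasted back into
the image frame.  Overlapping claims are resolved by detection score and
tiny instances dropped, leaving pairwise-disjoint instance masks.  Each
mask is decomposed into an ordered outer contour, a 1-pixel border (mask
pixels with an 8-neighbor outside the mask) and the interior remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .detect import BBox

__all__ = [
    "Patch",
    "CellInstance",
    "crop_patch",
    "segment_patch",
    "mask_to_contour",
    "split_border_interior",
    "assemble_instances",
    "DEFAULT_PATCH_MARGIN",
    "DEFAULT_MIN_AREA",
]

DEFAULT_PATCH_MARGIN = 8
DEFAULT_MIN_AREA = 20

_EIGHT = np.ones((3, 3), bool)


@dataclass(frozen=True)
class Patch:
    """A cropped window plus the placement needed to paste it back."""

    pixels: np.ndarray
    y0: int
    x0: int  # top-left corner of the patch in the image frame

    def paste_mask(self, patch_mask: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(image_shape, bool)
        h, w = patch_mask.shape
        out[self.y0 : self.y0 + h, self.x0 : self.x0 + w] = patch_mask
        return out


@dataclass
class CellInstance:
    cell_id: int
    box: BBox
    mask: np.ndarray  # bool, image frame
    contour: np.ndarray  # (n, 2) ordered (y, x) boundary pixels
    border_pixels: np.ndarray  # bool, image frame
    interior_pixels: np.ndarray  # bool, image frame
    score: float

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))


def crop_patch(image: np.ndarray, box: BBox, margin: int = DEFAULT_PATCH_MARGIN) -> Patch:
    """Crop ``box`` expanded by ``margin`` pixels, clipped to the image."""
    h, w = image.shape[:2]
    x0 = int(np.floor(box.x_min)) - margin
    y0 = int(np.floor(box.y_min)) - margin
    x1 = int(np.ceil(box.x_max)) + margin
    y1 = int(np.ceil(box.y_max)) + margin
    x0c, y0c = max(0, x0), max(0, y0)
    x1c, y1c = min(w, x1), min(h, y1)
    if x0c >= x1c or y0c >= y1c:
        raise ValueError(f"box {box} lies outside the image")
    return Patch(pixels=image[y0c:y1c, x0c:x1c], y0=y0c, x0=x0c)


def segment_patch(patch: Patch | np.ndarray, model) -> np.ndarray:
    """Binary foreground mask of a patch via the configured model
    (largest-component post-processing is the model's responsibility)."""
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    if pixels.size == 0:
        raise ValueError("empty patch")
    return np.asarray(model.segment(pixels), bool)


def mask_to_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary pixel sequence of the largest component.

    The contour pixel set is exactly the component's 1-px border (mask
    minus its 8-connected erosion); pixels are ordered by an angular sweep
    around the component centroid (ties: radius, then row, then column),
    which yields a closed traversal for the near-star-convex cell shapes
    this pipeline segments.  Returns an (n, 2) array of (y, x) pixels, all
    belonging to the mask.
    """
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask")
    lab, n = ndimage.label(m, structure=_EIGHT)
    if n > 1:
        sizes = ndimage.sum_labels(m, lab, index=range(1, n + 1))
        m = lab == (1 + int(np.argmax(sizes)))
    if m.sum() == 1:
        y, x = np.argwhere(m)[0]
        return np.array([[y, x]], int)
    border = m & ~ndimage.binary_erosion(m, structure=_EIGHT, border_value=0)
    pts = np.argwhere(border)
    cy, cx = np.argwhere(m).mean(axis=0)
    ang = np.arctan2(pts[:, 0] - cy, pts[:, 1] - cx)
    rad = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx)
    order = np.lexsort((pts[:, 1], pts[:, 0], rad, ang))
    return pts[order]


def split_border_interior(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition a mask into its 1-px border (mask pixels with an
    8-neighbor outside the mask) and the interior remainder."""
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask")
    interior = ndimage.binary_erosion(m, structure=_EIGHT, border_value=0)
    border = m & ~interior
    return border, interior


def assemble_instances(
    boxes: list[BBox],
    patch_masks: list[np.ndarray],
    image_shape: tuple[int, int],
    min_area: int = DEFAULT_MIN_AREA,
) -> list[CellInstance]:
    """Paste patch masks into the image frame and resolve conflicts.

    Pixels claimed by several instances go to the highest-scoring one
    (ties: earlier box in score order); instances falling below
    ``min_area`` after conflict resolution are dropped.  ``patch_masks``
    are image-frame masks (already pasted) or (mask, Patch) pairs.
    """
    if len(boxes) != len(patch_masks):
        raise ValueError("one mask per box required")
    frame_masks = []
    for pm in patch_masks:
        if isinstance(pm, tuple):
            mask, patch = pm
            frame_masks.append(patch.paste_mask(np.asarray(mask, bool), image_shape))
        else:
            m = np.asarray(pm, bool)
            if m.shape != tuple(image_shape):
                raise ValueError(f"mask shape {m.shape} != image shape {image_shape}")
            frame_masks.append(m)

    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].score, i))
    owned = np.zeros(image_shape, bool)
    instances: list[CellInstance] = []
    for i in order:
        m = frame_masks[i] & ~owned
        if m.sum() < min_area:
            continue
        owned |= m
        border, interior = split_border_interior(m)
        instances.append(
            CellInstance(
                cell_id=len(instances),
                box=boxes[i],
                mask=m,
                contour=mask_to_contour(m),
                border_pixels=border,
                interior_pixels=interior,
                score=boxes[i].score,
            )
        )
    return instances
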