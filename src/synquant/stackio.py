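"""I/O for image stacks, instance annotations, and intensity tables.

Stacks are multi-page TIFF in CZYX axis order with channel-role metadata;
annotations use a COCO-like JSON dialect (uncompressed column-major RLE
masks plus [x, y, w, h] boxes); intensity tables are CSV.

Coordinate conventions used throughout the package: 0-based pixel indices,
boxes half-open ``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CHANNEL_ROLES",
    "ImageStack",
    "AnnotationSet",
    "StackContractError",
    "read_stack",
    "write_stack",
    "encode_rle",
    "decode_rle",
    "write_annotations",
    "read_annotations",
    "write_label_image",
    "read_label_image",
    "write_tfi_table",
    "read_tfi_table",
    "TFI_COLUMNS",
]

CHANNEL_ROLES = {1: "F-actin", 2: "perforin", 3: "tumor antigen", 4: "pZeta", 5: "DIC"}

TFI_COLUMNS = [
    "image_id",
    "cell_id",
    "channel",
    "area_px",
    "tfi",
    "border_intensity",
    "interior_intensity",
]


class StackContractError(ValueError):
    """An array does not satisfy the five-channel stack contract."""


@dataclass
class ImageStack:
    """Five-channel multi-Z grayscale stack, axes (channel, z, y, x)."""

    voxels: np.ndarray
    channel_roles: dict[int, str] = field(default_factory=lambda: dict(CHANNEL_ROLES))
    bit_depth: int = 16

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 4:
            raise StackContractError(f"expected 4 axes (C, Z, Y, X), got {v.ndim}")
        if v.shape[0] != 5:
            raise StackContractError(f"expected 5 channels on axis 0, got {v.shape[0]}")
        if np.issubdtype(v.dtype, np.signedinteger) and v.min() < 0:
            raise StackContractError("negative intensities")
        self.voxels = v

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def channel(self, channel: int) -> np.ndarray:
        """Return the (z, y, x) sub-stack of a 1-based channel index."""
        if not 1 <= channel <= 5:
            raise ValueError(f"channel must be in 1..5, got {channel}")
        return self.voxels[channel - 1]

    def plane(self, channel: int, z: int) -> np.ndarray:
        return self.channel(channel)[z]


@dataclass
class AnnotationSet:
    """Instances of one image: (mask, box, optional score) triples."""

    image_id: str
    masks: list[np.ndarray]
    boxes: np.ndarray  # (n, 4) half-open [x0, y0, x1, y1]
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scores is not None:
            s = np.asarray(self.scores, float)
            if s.size and (s.min() < 0 or s.max() > 1):
                raise ValueError("scores must lie in [0, 1]")
            self.scores = s

    def __len__(self) -> int:
        return len(self.masks)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    meta = {
        "axes": "CZYX",
        "channel_roles": {str(k): v for k, v in stack.channel_roles.items()},
        "bit_depth": stack.bit_depth,
    }
    tifffile.imwrite(path, stack.voxels, metadata=meta, photometric="minisblack")


def read_stack(path: str | Path) -> ImageStack:
    """Read a CZYX TIFF written by :func:`write_stack` (or any 4-D TIFF
    with 5 leading channels); channel roles fall back to the positional
    default when metadata is absent."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    roles = dict(CHANNEL_ROLES)
    if isinstance(meta, dict) and "channel_roles" in meta:
        roles = {int(k): v for k, v in meta["channel_roles"].items()}
    bit_depth = int(meta.get("bit_depth", 16)) if isinstance(meta, dict) else 16
    return ImageStack(voxels=arr, channel_roles=roles, bit_depth=bit_depth)


# ---------------------------------------------------------------------------
# RLE masks and the JSON annotation dialect

def encode_rle(mask: np.ndarray) -> dict:
    """Uncompressed column-major run-length encoding of a binary mask.

    ``counts`` alternates runs of 0s and 1s (starting with 0s) over the
    mask flattened in Fortran (column-major) order.
    """
    m = np.asarray(mask, bool)
    flat = m.flatten(order="F").astype(np.int8)
    changes = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(m.shape[0]), int(m.shape[1])], "counts": counts}


def decode_rle(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise ValueError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape((h, w), order="F")


def write_annotations(annos: AnnotationSet, path: str | Path) -> None:
    if annos.masks:
        h, w = annos.masks[0].shape
    else:
        h = w = 0
    doc = {
        "images": [{"id": annos.image_id, "height": h, "width": w}],
        "annotations": [],
    }
    for i, mask in enumerate(annos.masks):
        x0, y0, x1, y1 = (float(v) for v in annos.boxes[i])
        ann = {
            "id": i,
            "image_id": annos.image_id,
            "bbox": [x0, y0, x1 - x0, y1 - y0],
            "segmentation": encode_rle(mask),
            "area": int(np.count_nonzero(mask)),
        }
        if annos.scores is not None:
            ann["score"] = float(annos.scores[i])
        doc["annotations"].append(ann)
    Path(path).write_text(json.dumps(doc))


def read_annotations(path: str | Path) -> AnnotationSet:
    doc = json.loads(Path(path).read_text())
    image_id = str(doc["images"][0]["id"]) if doc.get("images") else ""
    masks, boxes, scores = [], [], []
    has_scores = any("score" in a for a in doc["annotations"])
    for ann in doc["annotations"]:
        masks.append(decode_rle(ann["segmentation"]))
        x, y, w, h = ann["bbox"]
        boxes.append([x, y, x + w, y + h])
        if has_scores:
            scores.append(float(ann.get("score", 1.0)))
    return AnnotationSet(
        image_id=image_id,
        masks=masks,
        boxes=np.asarray(boxes, float).reshape(-1, 4),
        scores=np.asarray(scores, float) if has_scores else None,
    )


def write_label_image(masks: list[np.ndarray], path: str | Path) -> None:
    """16-bit label image: 0 background, i+1 for instance i."""
    if not masks:
        raise ValueError("cannot write a label image with no masks")
    lab = np.zeros(masks[0].shape, np.uint16)
    for i, m in enumerate(masks):
        lab[m] = i + 1
    tifffile.imwrite(path, lab)


def read_label_image(path: str | Path) -> list[np.ndarray]:
    lab = tifffile.imread(path)
    return [lab == i for i in range(1, int(lab.max()) + 1)]


# ---------------------------------------------------------------------------
# TFI tables

def write_tfi_table(records: list[dict], path: str | Path) -> None:
    """Write per-(cell, channel) intensity records as CSV; an empty record
    list produces a header-only file."""
    df = pd.DataFrame(records, columns=TFI_COLUMNS)
    df.to_csv(path, index=False)


def read_tfi_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
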