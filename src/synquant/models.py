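"""Detection and segmentation models.

Two interchangeable model families sit behind the fixed inference
contracts (``predict_maps(image) -> KeypointMaps`` for detection,
``segment(patch) -> binary mask`` for segmentation):

* **Learned models** — compact multilayer perceptrons applied per pixel to
  a multiscale filter-bank (Gaussian-smoothed intensity, signed first
  derivatives, Laplacian and gradient magnitude at several scales).  The
  signed derivatives let the regressor discriminate the four corner
  classes and point offsets toward the instance center; the architecture
  is deliberately small so training is practical on a single CPU.
* **Threshold models** — a deterministic, non-learned path (Otsu threshold,
  hole filling, connected components).  It is exact on clean synthetic
  data and serves as a fast oracle for testing the downstream pipeline
  independently of training stochasticity.

Offsets are regressed in units of the detection-scale radius and rescaled
to pixels at inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .detect import DEFAULT_SCALES, KEYPOINT_CLASSES, BBox, KeypointMaps, keypoint_maps_from_boxes

__all__ = [
    "FEATURE_SIGMAS",
    "pixel_features",
    "ThresholdKeypointModel",
    "ThresholdSegmenter",
    "LearnedKeypointModel",
    "LearnedSegmenter",
    "foreground_components",
    "save_model",
    "load_model",
]

FEATURE_SIGMAS = (1.0, 2.0, 4.0, 8.0, 12.0)


def _normalize(image: np.ndarray) -> np.ndarray:
    """Robust contrast normalization: median -> 0, 99.5th percentile -> 1."""
    img = np.asarray(image, np.float64)
    med = np.median(img)
    hi = np.percentile(img, 99.5)
    scale = hi - med
    if scale <= 0:
        scale = img.max() - med or 1.0
    return (img - med) / scale


def pixel_features(image: np.ndarray, sigmas: tuple[float, ...] = FEATURE_SIGMAS) -> np.ndarray:
    """Per-pixel feature stack, shape (H, W, 1 + 5 * len(sigmas)).

    For each sigma: smoothed intensity, d/dx, d/dy, Laplacian, gradient
    magnitude.  Signed derivatives carry the orientation information needed
    to tell box corners apart and to regress center offsets.
    """
    img = _normalize(image)
    feats = [img]
    for s in sigmas:
        sm = ndimage.gaussian_filter(img, s)
        gx = ndimage.gaussian_filter(img, s, order=(0, 1))
        gy = ndimage.gaussian_filter(img, s, order=(1, 0))
        lap = ndimage.gaussian_laplace(img, s)
        feats.extend([sm, gx * s, gy * s, lap * s, np.hypot(gx, gy) * s])
    return np.stack(feats, axis=-1)


def foreground_components(image: np.ndarray, min_area: int = 20) -> list[np.ndarray]:
    """Otsu-threshold foreground split into filled connected components."""
    img = np.asarray(image, np.float64)
    if img.max() <= img.min():
        return []
    fg = img > threshold_otsu(img)
    fg = ndimage.binary_fill_holes(fg)
    lab, n = ndimage.label(fg, structure=np.ones((3, 3)))
    out = []
    for i in range(1, n + 1):
        m = lab == i
        if m.sum() >= min_area:
            out.append(m)
    return out


@dataclass
class ThresholdKeypointModel:
    """Non-learned detector: components of the thresholded image define
    boxes, from which ideal keypoint maps are constructed geometrically.
    Exact on clean, non-touching synthetic cells."""

    scales: tuple[float, ...] = DEFAULT_SCALES
    min_area: int = 20

    def predict_maps(self, image: np.ndarray) -> KeypointMaps:
        boxes = []
        for m in foreground_components(image, self.min_area):
            ys, xs = np.nonzero(m)
            boxes.append(
                BBox(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))
            )
        return keypoint_maps_from_boxes(boxes, image.shape, self.scales)


@dataclass
class ThresholdSegmenter:
    """Non-learned patch segmenter: Otsu threshold, hole filling, largest
    connected component."""

    def segment(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, np.float64)
        if patch.size == 0:
            raise ValueError("empty patch")
        if patch.max() <= patch.min():
            return np.zeros(patch.shape, bool)
        fg = patch > threshold_otsu(patch)
        fg = ndimage.binary_fill_holes(fg)
        lab, n = ndimage.label(fg, structure=np.ones((3, 3)))
        if n == 0:
            return np.zeros(patch.shape, bool)
        sizes = ndimage.sum_labels(fg, lab, index=range(1, n + 1))
        return lab == (1 + int(np.argmax(sizes)))


@dataclass
class LearnedKeypointModel:
    """Per-pixel MLP keypoint model.

    ``heat_models[si]`` regresses the 5 heatmap planes of scale ``si``;
    ``offset_models[si]`` regresses the 10 offset planes (in units of the
    scale radius).  Scales without a trained head emit empty maps.
    """

    scales: tuple[float, ...] = DEFAULT_SCALES
    sigmas: tuple[float, ...] = FEATURE_SIGMAS
    heat_models: dict[int, object] = field(default_factory=dict)
    offset_models: dict[int, object] = field(default_factory=dict)

    def predict_maps(self, image: np.ndarray) -> KeypointMaps:
        h, w = image.shape
        n_s = len(self.scales)
        heat = np.zeros((n_s, 5, h, w), np.float64)
        offs = np.zeros((n_s, 5, 2, h, w), np.float64)
        if not self.heat_models:
            return KeypointMaps(heat, offs, self.scales)
        x = pixel_features(image, self.sigmas).reshape(-1, 1 + 5 * len(self.sigmas))
        for si, model in self.heat_models.items():
            pred = np.clip(model.predict(x), 0.0, 1.0)
            heat[si] = pred.reshape(h, w, 5).transpose(2, 0, 1)
            om = self.offset_models.get(si)
            if om is not None:
                op = om.predict(x).reshape(h, w, 5, 2).transpose(2, 3, 0, 1)
                offs[si] = op * (self.scales[si] / 2.0)
        return KeypointMaps(heat, offs, self.scales)


@dataclass
class LearnedSegmenter:
    """Per-pixel MLP foreground classifier applied to a patch; the largest
    filled component above probability 0.5 is returned."""

    sigmas: tuple[float, ...] = FEATURE_SIGMAS
    classifier: object = None

    def segment(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, np.float64)
        if patch.size == 0:
            raise ValueError("empty patch")
        if self.classifier is None:
            raise RuntimeError("segmenter is untrained")
        x = pixel_features(patch, self.sigmas).reshape(-1, 1 + 5 * len(self.sigmas))
        prob = self.classifier.predict_proba(x)[:, 1].reshape(patch.shape)
        fg = prob > 0.5
        fg = ndimage.binary_fill_holes(fg)
        lab, n = ndimage.label(fg, structure=np.ones((3, 3)))
        if n == 0:
            return np.zeros(patch.shape, bool)
        sizes = ndimage.sum_labels(fg, lab, index=range(1, n + 1))
        return lab == (1 + int(np.argmax(sizes)))


def save_model(model, path) -> None:
    joblib.dump(model, path)


def load_model(path):
    return joblib.load(path)
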