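"""Synthetic immunological-synapse Z-stack generator.

Emulates five-channel confocal stacks of CAR-T cells spread on a
glass-supported planar lipid bilayer: each cell shows a peripheral F-actin
ring with an actin-sparse center (channel 1), central perforin / pZeta
clusters (channels 2 and 4), a central tumor-antigen accumulation
(channel 3), and a DIC-like edge image (channel 5).  Because the synapse
is pinned to the bilayer plane, signal amplitude through Z follows a
Gaussian peaked at one focal slice.

Every generated stack comes with exact ground truth (instance masks, tight
boxes, and the true integrated per-cell intensity at the focal slice), so
detection, segmentation and quantification can all be validated without
any real patient data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stackio import CHANNEL_ROLES, ImageStack

__all__ = [
    "SceneParams",
    "GroundTruth",
    "PlacementError",
    "generate_stack",
    "generate_dataset",
    "DENSITY_REGIMES",
]

# cells per 256x256 field and probability of placing a cell touching an
# existing one, for the three population regimes
DENSITY_REGIMES = {
    "sparse": (5, 0.0),
    "moderate": (15, 0.25),
    "dense": (32, 0.55),
}

# per-channel peak signal amplitude in 16-bit gray levels; confocal
# fluorescence with integrated cell signal dominating the dark offset
_BASE_AMP = {1: 3000.0, 2: 4000.0, 3: 2600.0, 4: 4000.0}
_BG_OFFSET = 50.0
_DIC_BG = 2000.0
_DIC_EDGE_AMP = 1800.0


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without violating disjointness."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene.

    ``n_cells`` is either an explicit count or a density regime name
    (``sparse``/``moderate``/``dense``); regimes scale the cell count with
    the image area and set the adhesion probability, emulating the
    sparsely, moderately and highly populated fields seen on bilayers.
    """

    image_height: int = 256
    image_width: int = 256
    n_z: int = 9
    n_cells: int | str = "sparse"
    cell_radius_range: tuple[float, float] = (10.0, 16.0)
    adhesion_prob: float | None = None  # None -> from regime, else 0
    boundary_contrast: float = 0.8
    impurity_density: float = 0.15  # impurities per 1000 px^2
    focal_z: int = 4
    axial_sigma: float = 2.0
    antigen_density: float = 1.0
    channel_scales: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    noise_sigma: float = 40.0  # additive read-noise SD, gray levels
    shot_noise: bool = True
    cell_brightness_cv: float = 0.18  # cell-to-cell lognormal variability
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_cells, str):
            if self.n_cells not in DENSITY_REGIMES:
                raise ValueError(f"unknown density regime {self.n_cells!r}")
        elif self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0 <= self.focal_z < self.n_z):
            raise ValueError("focal_z must lie in [0, n_z)")
        for name in ("boundary_contrast",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.adhesion_prob is not None and not (0.0 <= self.adhesion_prob <= 1.0):
            raise ValueError("adhesion_prob must be in [0, 1]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.cell_radius_range[0] <= 0 or (
            self.cell_radius_range[1] < self.cell_radius_range[0]
        ):
            raise ValueError("invalid cell_radius_range")

    def resolved_counts(self) -> tuple[int, float]:
        """Return (cell count, adhesion probability) for this scene."""
        if isinstance(self.n_cells, str):
            base_n, base_adh = DENSITY_REGIMES[self.n_cells]
            area_scale = (self.image_height * self.image_width) / (256.0 * 256.0)
            n = max(1, int(round(base_n * area_scale)))
            adh = base_adh if self.adhesion_prob is None else self.adhesion_prob
            return n, adh
        return int(self.n_cells), (self.adhesion_prob or 0.0)

    @property
    def effective_noise_sigma(self) -> float:
        """Conservative per-pixel noise SD (read noise plus shot noise at
        the brightest expected signal), used for intensity tolerances."""
        peak = max(_BASE_AMP.values()) * max(max(self.channel_scales), self.antigen_density, 1.0)
        shot_var = (peak + _BG_OFFSET) if self.shot_noise else 0.0
        # +0.5 covers integer quantization
        return math.sqrt(self.noise_sigma**2 + shot_var) + 0.5


@dataclass
class GroundTruth:
    """Exact per-instance annotations for one generated stack."""

    masks: list[np.ndarray]  # bool, image frame, pairwise disjoint
    boxes: np.ndarray  # (n, 4) float, half-open [x0, y0, x1, y1]
    per_cell_true_tfi: np.ndarray  # (n, 5) noiseless masked sums at focal_z
    focal_z: int
    noise_sigma: float  # per-pixel SD bound for tolerance arithmetic

    def __len__(self) -> int:
        return len(self.masks)


def _tight_box(mask: np.ndarray) -> tuple[float, float, float, float]:
    ys, xs = np.nonzero(mask)
    return float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1)


def _random_cell_mask(
    rng: np.random.Generator, r0: float, shape: tuple[int, int], center: tuple[float, float]
) -> np.ndarray:
    """Rasterize a radially Fourier-perturbed ellipse-like blob."""
    cy, cx = center
    h, w = shape
    n_harm = 4
    amps = rng.uniform(0.0, 0.07, n_harm)
    phases = rng.uniform(0.0, 2 * np.pi, n_harm)
    # slight anisotropy on top of the radial perturbation
    ecc = rng.uniform(0.85, 1.0)
    theta0 = rng.uniform(0, np.pi)

    r_max = r0 * 1.4
    y0, y1 = max(0, int(cy - r_max)), min(h, int(cy + r_max) + 2)
    x0, x1 = max(0, int(cx - r_max)), min(w, int(cx + r_max) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta0), np.sin(theta0)
    u = dx * ct + dy * st
    v = (-dx * st + dy * ct) / ecc
    rho = np.hypot(u, v)
    ang = np.arctan2(v, u)
    r_theta = r0 * (
        1.0 + sum(a * np.cos((k + 2) * ang + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    local = rho <= r_theta
    mask = np.zeros(shape, bool)
    mask[y0:y1, x0:x1] = local
    return mask


def _place_cells(params: SceneParams, rng: np.random.Generator) -> list[np.ndarray]:
    n_cells, adhesion_prob = params.resolved_counts()
    if isinstance(params.n_cells, int) and params.n_cells == 0:
        return []
    h, w = params.image_height, params.image_width
    occupied = np.zeros((h, w), bool)
    masks: list[np.ndarray] = []
    centers: list[tuple[float, float, float]] = []  # (cy, cx, r)
    max_tries = 300
    struct = np.ones((5, 5), bool)  # 2-px gap for non-touching placement

    for _ in range(n_cells):
        placed = False
        for _try in range(max_tries):
            r0 = rng.uniform(*params.cell_radius_range)
            adhesive = bool(centers) and rng.uniform() < adhesion_prob
            if adhesive:
                py, px, pr = centers[rng.integers(len(centers))]
                ang = rng.uniform(0, 2 * np.pi)
                d = (pr + r0) * rng.uniform(0.88, 1.0)
                cy, cx = py + d * np.sin(ang), px + d * np.cos(ang)
                if not (r0 * 0.5 <= cy < h - r0 * 0.5 and r0 * 0.5 <= cx < w - r0 * 0.5):
                    continue
            else:
                cy = rng.uniform(r0, h - r0)
                cx = rng.uniform(r0, w - r0)
            cand = _random_cell_mask(rng, r0, (h, w), (cy, cx))
            if not cand.any():
                continue
            if adhesive:
                cand &= ~occupied
                if cand.sum() < 0.55 * np.pi * r0 * r0:
                    continue
                # keep the main component only (carving can fragment)
                lab, nlab = ndimage.label(cand, structure=np.ones((3, 3)))
                if nlab > 1:
                    sizes = ndimage.sum_labels(cand, lab, index=range(1, nlab + 1))
                    cand = lab == (1 + int(np.argmax(sizes)))
            else:
                grown = ndimage.binary_dilation(cand, structure=struct)
                if (grown & occupied).any():
                    continue
            occupied |= cand
            masks.append(cand)
            centers.append((cy, cx, r0))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {len(masks) + 1}/{n_cells} after {max_tries} tries"
            )
    return masks


def _radial_coordinate(mask: np.ndarray) -> np.ndarray:
    """Normalized distance from the cell boundary: 0 at the center of the
    cell, 1 at its edge (computed from the Euclidean distance transform)."""
    dt = ndimage.distance_transform_edt(mask)
    m = dt.max()
    if m <= 0:
        return np.zeros_like(dt)
    return 1.0 - dt / m


def _render_channels(
    params: SceneParams, masks: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Render the in-focus, noiseless 5-channel signal (no background)."""
    h, w = params.image_height, params.image_width
    sig = np.zeros((5, h, w), np.float64)
    contrast = 0.25 + 0.75 * params.boundary_contrast
    gains = {
        1: _BASE_AMP[1] * params.channel_scales[0],
        2: _BASE_AMP[2] * params.channel_scales[1],
        3: _BASE_AMP[3] * params.channel_scales[2] * params.antigen_density,
        4: _BASE_AMP[4] * params.channel_scales[3],
    }
    for mask in masks:
        u = _radial_coordinate(mask)
        b = rng.lognormal(0.0, params.cell_brightness_cv, size=4)
        inside = mask
        # F-actin: bright peripheral ring over a dim positive floor
        ring = 0.22 + 0.78 * np.exp(-((u - 0.85) ** 2) / (2 * 0.12**2))
        sig[0][inside] += gains[1] * contrast * b[0] * ring[inside]
        # perforin, antigen, pZeta: central accumulations of varying extent
        for ch, width in ((2, 0.35), (3, 0.45), (4, 0.40)):
            prof = np.exp(-((u / width) ** 2))
            sig[ch - 1][inside] += gains[ch] * contrast * b[ch - 1] * prof[inside]
    # DIC: label-free edge image over a mid-gray background
    if masks:
        union = np.zeros((h, w), bool)
        for m in masks:
            union |= m
        edges = ndimage.gaussian_gradient_magnitude(union.astype(np.float64), 1.5)
        peak = edges.max()
        if peak > 0:
            sig[4] = _DIC_EDGE_AMP * contrast * edges / peak
    return sig


def _add_impurities(
    params: SceneParams, sig: np.ndarray, masks: list[np.ndarray], rng: np.random.Generator
) -> None:
    """Sparse bright speckles on the background (bilayer debris)."""
    h, w = params.image_height, params.image_width
    lam = params.impurity_density * h * w / 1000.0
    n_imp = int(rng.poisson(lam))
    if n_imp == 0:
        return
    forbidden = np.zeros((h, w), bool)
    for m in masks:
        forbidden |= m
    forbidden = ndimage.binary_dilation(forbidden, iterations=3)
    speck = np.zeros((h, w), np.float64)
    placed = 0
    for _ in range(n_imp * 10):
        if placed >= n_imp:
            break
        y, x = int(rng.integers(h)), int(rng.integers(w))
        if forbidden[y, x]:
            continue
        speck[y, x] += rng.uniform(1.0, 3.0)
        placed += 1
    speck = ndimage.gaussian_filter(speck, 1.2)
    peak = speck.max()
    if peak <= 0:
        return
    for c in range(4):
        amp = _BASE_AMP[c + 1] * rng.uniform(0.6, 1.4)
        sig[c] += amp * speck / peak
    # impurities are visible in DIC too
    sig[4] += 0.5 * _DIC_EDGE_AMP * speck / peak


def generate_stack(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    """Generate one five-channel Z-stack plus exact ground truth.

    The returned stack has shape (5, n_z, H, W).  Channel amplitudes follow
    a Gaussian in Z centered at ``focal_z`` with SD ``axial_sigma``, and
    out-of-focus slices are additionally blurred, so the channel-3 per-slice
    mean is unimodal with its maximum at the focal slice.
    ``per_cell_true_tfi[i, c]`` is the integrated (background-inclusive)
    noiseless intensity of channel ``c+1`` inside mask ``i`` at ``focal_z``.
    """
    rng = np.random.default_rng(params.seed)
    masks = _place_cells(params, rng)
    sig = _render_channels(params, masks, rng)
    _add_impurities(params, sig, masks, rng)

    h, w = params.image_height, params.image_width
    vmax = float(2**params.bit_depth - 1)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    stack = np.empty((5, params.n_z, h, w), dtype)

    # noiseless quantized focal slice fixes the ground-truth intensities
    focal_clean = np.clip(np.rint(sig + _dc_offsets()[:, None, None]), 0, vmax)
    tfi = np.zeros((len(masks), 5), np.float64)
    for i, m in enumerate(masks):
        for c in range(5):
            tfi[i, c] = focal_clean[c][m].sum()

    for z in range(params.n_z):
        dz = abs(z - params.focal_z)
        amp = math.exp(-(dz**2) / (2 * params.axial_sigma**2))
        blur = 0.9 * dz
        for c in range(5):
            plane = sig[c]
            if blur > 0:
                plane = ndimage.gaussian_filter(plane, blur)
            img = amp * plane + _dc_offsets()[c]
            if params.shot_noise:
                img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
            if params.noise_sigma > 0:
                img = img + rng.normal(0.0, params.noise_sigma, img.shape)
            if z == params.focal_z and not params.shot_noise and params.noise_sigma == 0:
                img = focal_clean[c]  # bit-exact against recorded TFI
            stack[c, z] = np.clip(np.rint(img), 0, vmax).astype(dtype)

    boxes = (
        np.array([_tight_box(m) for m in masks], np.float64)
        if masks
        else np.zeros((0, 4), np.float64)
    )
    gt = GroundTruth(
        masks=masks,
        boxes=boxes,
        per_cell_true_tfi=tfi,
        focal_z=params.focal_z,
        noise_sigma=params.effective_noise_sigma,
    )
    image = ImageStack(voxels=stack, channel_roles=dict(CHANNEL_ROLES), bit_depth=params.bit_depth)
    return image, gt


def _dc_offsets() -> np.ndarray:
    """Per-channel constant background offset (gray levels)."""
    return np.array([_BG_OFFSET, _BG_OFFSET, _BG_OFFSET, _BG_OFFSET, _DIC_BG])


def generate_dataset(
    n_images: int, params: SceneParams, seed: int | None = None
) -> list[tuple[ImageStack, GroundTruth]]:
    """Generate ``n_images`` independent scenes, reproducible from ``seed``.

    Each scene gets its own child seed derived from ``seed`` (or from
    ``params.seed`` when ``seed`` is None), so datasets are reproducible
    and scenes are mutually independent.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    root = params.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(root).generate_state(n_images) & 0x7FFFFFFF
    out = []
    for s in child_seeds:
        p = dataclasses.replace(params, seed=int(s))
        out.append(generate_stack(p))
    return out
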