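# Methods

## Scope and data model

`synquant` operates on five-channel, multi-Z grayscale stacks (CZYX) with the
fixed channel roles 1 = F-actin, 2 = perforin, 3 = tumor antigen, 4 = pZeta,
5 = DIC. Coordinates are 0-based; boxes are half-open
`[x_min, x_max) × [y_min, y_max)`, so areas and IoU are unambiguous integer
arithmetic on pixel grids. Masks are serialized both as 16-bit label images
and as uncompressed column-major RLE inside a COCO-like JSON dialect
(`bbox` as `[x, y, w, h]`); all readers/writers are lossless round trips at
the declared bit depth.

## Synthetic scene generator

The generator emulates what makes bilayer IS images hard — low-contrast
boundaries, background impurities, adhesion and clustering — while keeping
ground truth exact.

* **Shapes.** Cells are radially Fourier-perturbed ellipses (harmonics 2–5,
  amplitudes ≤ 0.07, mild anisotropy), rasterized without anti-aliasing so
  the mask equals the rendered support exactly. Placement is rejection
  sampling; non-adhesive cells keep a ≥ 2-px gap, adhesive cells are placed
  tangentially and carved so masks stay pairwise disjoint (they may touch).
  Impossible configurations raise after 300 tries per cell.
* **Channel layouts.** With u the normalized distance from the cell center
  (0) to its boundary (1), computed from the Euclidean distance transform:
  F-actin is a peripheral ring `0.22 + 0.78·exp(−(u−0.85)²/2·0.12²)` over a
  positive floor (actin-sparse but nonzero center); perforin, antigen and
  pZeta are central Gaussians `exp(−(u/w)²)` with widths 0.35/0.45/0.40; DIC
  is a mask-edge gradient image over a mid-gray offset. Peak amplitudes are
  3000/4000/2600/4000 gray levels (16-bit) over a DC offset of 50 — the
  integrated cell signal dominates the offset, as in confocal fluorescence,
  which is what lets raw masked sums recover relative intensity scales.
  Per-cell lognormal brightness variation (CV ≈ 0.18) provides biological
  spread; `channel_scales` and `antigen_density` rescale channels for cohort
  experiments.
* **Axial model.** Slice amplitude follows `exp(−(z−z_f)²/2σ_z²)` around the
  focal slice with additional defocus blur of 0.9·|z−z_f| px, reproducing a
  unimodal per-slice mean-intensity profile peaked at the focal slice. The
  focal slice itself is rendered unblurred.
* **Noise.** Poisson shot noise on the expected signal plus Gaussian read
  noise (SD 40 by default) plus rounding to the integer bit depth.
  Impurities are bright blurred speckles placed on the background only
  (outside dilated masks): real debris can overlap cells, but keeping them
  off-mask is what makes the generator's per-cell intensity bookkeeping an
  exact oracle. `per_cell_true_tfi` records the noiseless (offset-inclusive)
  masked sums at the focal slice, quantized, so in the noiseless
  configuration downstream sums must match to the last gray level; with
  noise, the discrepancy of a sum over area A is bounded in practice by
  3·σ_eff·A with σ_eff the conservative per-pixel SD exposed by the
  parameters.
* **Density regimes.** sparse/moderate/dense = 5/15/32 cells per 256² field
  (scaled by area) with adhesion probabilities 0/0.25/0.55.

What the generator does **not** model: real optics (PSF, TIRF), partial-pixel
coverage, temporal microcluster transport, overlapping instances, chromatic
shifts. Passing tests therefore demonstrate correctness of the pipeline's
algorithms and bookkeeping, not segmentation performance on patient data.

## Focal-plane selection

"Best slice" is read as the argmax of the per-slice **mean** intensity of the
tumor-antigen channel; a per-slice max-pixel criterion was rejected because a
single impurity speckle can dominate it. Ties break to the lowest index.

## Detection: keypoint Hough voting

* **Supervision geometry.** Each ground-truth box is assigned to the scale
  whose disk radius s_i best matches the box half-size (defaults
  s = 16/32/64/128 px). Around each of its five keypoints a disk of radius
  s_i/2 carries a truncated Gaussian (σ = s_i/6, peak 1 at the keypoint);
  offsets inside a disk point to the instance center, regressed in units of
  s_i/2.
* **Peak extraction.** Local maxima are taken on a σ = 1 px smoothed copy of
  each heatmap (3×3 neighborhood, plateaus collapse to their centroid);
  confidence is read from the raw map; threshold 0.1.
* **Accumulator.** Votes snap to the nearest multiple of the cell size
  (nearest-bin semantics, so two votes within half a cell of a common bin
  center merge). `detect_cells` uses cell size s_i/2 — s_i/4 proved too fine
  once learned offsets carry a few pixels of jitter — and additionally rebins
  under half-cell-shifted grids so votes straddling a bin boundary still meet
  in some grid; NMS dedupes the duplicates. On noiseless constructed maps the
  chain recovers every planted box with integer center exactly.
* **Box construction.** A diagonal pair (TL+BR or TR+BL) spans a box; with at
  least three members, corners pin their coordinates and the center imputes
  missing corners by reflection; multiply-supported coordinates are averaged.
  Under-determined or geometrically inconsistent groups yield nothing. The
  box score is the mean keypoint confidence; NMS suppresses at IoU ≥ 0.5.

## Models

The learned detector and segmenter are per-pixel MLPs (scikit-learn, Adam,
initial learning rate 1e-4, batch 64, one hidden layer of 64 units) over a
multiscale filter bank: raw intensity plus, at σ = 1/2/4/8/12, the smoothed
intensity, signed first derivatives (scaled by σ), Laplacian and gradient
magnitude. The signed derivatives are what let the model tell the four corner
classes apart and regress center offsets. Features are standardized; heat and
offset heads are separate regressors per scale (offsets are trained only on
in-disk pixels); the segmenter is a foreground classifier trained on
box-margin patches so train and inference distributions match. Training
records per-epoch training loss (sum of head losses) and validation loss, and
is bit-reproducible given the seed in single-threaded execution.
Augmentation (random expansion, cropping, flipping, contrast and brightness
distortion) is applied to a configurable number of extra copies per training
image (default 2); geometric ops transform image and masks identically, a
crop that would erase every instance is resampled up to 10 times and then
skipped.

A deterministic **threshold-oracle** path ships alongside the learned one:
Otsu threshold, hole filling, connected components (detection constructs
ideal keypoint maps from component boxes and runs the same Hough chain;
segmentation keeps the largest filled component of the patch). On clean
synthetic scenes it is exact end to end, which decouples testing of the
geometry/metric/quantification code from training stochasticity.

## Segmentation and assembly

Patches are boxes expanded by an 8-px margin, clipped to the image; one cell
is segmented per patch. Pasted masks are resolved by detection score (ties:
input order), instances below 20 px are dropped, and final masks are pairwise
disjoint. Components and borders use 8-connectivity: the border is the mask
minus its 8-connected erosion, the interior the remainder, and the contour is
that border ordered by an angular sweep around the component centroid —
a faithful closed traversal for the near-star-convex shapes of spread cells.

## Evaluation

Matching is greedy: predictions in descending score order, each taking the
unmatched ground truth of highest IoU if ≥ the threshold (ties to the lower
index). AP@t is the all-point-interpolated area under the precision–recall
curve (PASCAL-2010 style) × 100, pooled over images; with no ground truth it
is undefined (NaN, never 0). IOU@t is the mean IoU over matched pairs × 100 —
the reading consistent with IOU@0.7 exceeding IOU@0.5 within every row of
published grids, since a stricter gate keeps only better matches. The
benchmark comparison arithmetic takes per-cell differences and means, rounded
half-up to two decimals; the bundled grid's "overall" averages are over the
six AP cells of a section.

The dataset split is floor(0.6·n)/floor(0.2·n)/remainder after a seeded
shuffle — 93/31/32 for n = 156.

## Statistics

TFI is quantified per cell and channel at the focal slice with no background
subtraction (raw masked sums; subtraction is available as an option but off
by default since relative comparisons are the use case). Group summaries
report n, mean, unbiased variance and SEM (a single observation has variance
0 by convention). The population test is the two-sided pooled-variance
Student *t* (two i.i.d. samples; Welch available via a flag); degenerate
zero-variance inputs return t = 0, p = 1 when means agree and a p → 0
sentinel otherwise. Distribution summaries are the histogram (counts sum to
n) and the right-continuous ECDF (ends at 1). Channel 5 is never quantified.
No multiple-testing correction is applied across channels; per-channel tests
are reported as-is.

## Problem sizes used by the test suite and acceptance script

Synthetic experiments run at desk scale: 160–256 px frames, 3–9 slices,
4–32 cells. The learned smoke run trains for 10 epochs on 20 easy sparse
160² images (plus 2 augmented copies each) and is scored on held-out scenes;
cohort statistics use 50 cells per group (5 images × 10 cells) and a
20-repetition null calibration at 27 cells per arm. These sizes were chosen
so the full pipeline — generation, training, inference, statistics — is
reproducible on a single CPU in about a minute.

## Known limitations

* Detection quality is validated on synthetic scenes only; the feature-bank
  MLPs are far smaller than the deep networks one would train on GPU-scale
  annotated patient data, and the Hough-chain defaults (scales, thresholds)
  are tuned to the synthetic size range.
* Segmentation acts on the focal slice only (no volumetric masks), and
  predicted instances cannot overlap by construction.
* The angular contour ordering assumes near-star-convex cells; highly
  concave shapes would get a correct pixel set but a non-boundary-walk
  ordering.
* The exact-TFI oracle holds because synthetic impurities avoid masks; on
  real data debris inside a cell footprint is integrated into its TFI.
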