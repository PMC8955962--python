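# synquant

Machine-learning quantification of CAR-T **immunological synapse (IS) quality**
from five-channel confocal Z-stacks of cells spread on glass-supported planar
lipid bilayers.

When a CAR-T cell engages its cognate tumor antigen on a bilayer, it forms a
synapse whose molecular organization — a peripheral F-actin ring, central
perforin and pZeta clusters, accumulated tumor antigen — reflects how well the
cell will kill. Quantifying thousands of synapses by hand is slow and
inconsistent; `synquant` automates it:

1. **Focal-plane selection** — the in-focus Z slice is the one maximizing the
   per-slice mean intensity of the tumor-antigen channel (the synapse is
   pinned to the bilayer plane).
2. **Detection** — each cell is found by *multi-scale keypoint Hough voting*:
   a model predicts, at four scales *s₁…s₄*, heatmaps for five keypoint
   classes (box corners TL, TR, BL, BR and center C) plus two-channel offset
   maps pointing from each keypoint toward its instance center. Heatmap peaks
   vote at *position + offset*; votes accumulating in the same Hough cell form
   a keypoint group; a diagonal corner pair, or any three keypoints (corners
   reflected through C), fixes a bounding box; greedy NMS removes duplicates.
3. **Segmentation** — each box is expanded by a margin, cropped to a patch and
   segmented individually (so neighbors do not interfere); masks are pasted
   back, overlaps resolved by score, and decomposed into an ordered contour,
   a 1-px border, and the interior.
4. **Quantification** — the F-actin-derived masks are applied unchanged to
   channels 1–4 at the focal slice; a cell's **total fluorescence intensity**
   (TFI) in a channel is the raw sum of gray values under its mask,
   `TFI = border + interior`.
5. **Statistics** — populations are compared per channel with a two-sided
   pooled-variance Student *t* test, with histograms and empirical CDFs as
   distribution summaries; evaluation uses AP@0.5/0.7 (all-point-interpolated
   area under the precision–recall curve) and IOU@t (mean IoU over matched
   pairs) at box and mask level.

Because patient images cannot be redistributed, the package ships a
**synthetic scene generator** (`synquant.synthgen`) that renders five-channel
stacks — actin rings with actin-sparse centers, central perforin/antigen/pZeta
clusters, DIC edges, Gaussian axial intensity profiles, impurity speckles,
sparse/moderate/dense populations with optional adhesion — together with
*exact* ground truth (masks, boxes, per-cell injected intensities). Two model
families sit behind the same contracts: learned per-pixel MLPs over a
multiscale filter bank, and a deterministic threshold-oracle path that is
exact on clean scenes and validates the rest of the pipeline independently of
training stochasticity.

## Worked example

```sh
$ synquant generate --n-images 2 --density sparse --seed 1 --out demo
wrote 2 stacks to demo

$ synquant zselect demo/img000.tiff
profile: 55.63 60.58 67.05 74.65 77.59 74.83 67.42 60.34 55.49
z: 4
```

The channel-3 mean-intensity profile over the nine slices peaks at slice 4 —
that slice is used everywhere downstream.

```sh
$ synquant detect demo/img000.tiff --out demo/boxes.json
5 boxes -> demo/boxes.json
$ synquant segment demo/img000.tiff --boxes demo/boxes.json --out demo/masks.json
5 instances -> demo/masks.json
$ synquant quantify demo/img000.tiff --masks demo/masks.json --out demo/tfi.csv
20 records -> demo/tfi.csv
$ head -3 demo/tfi.csv
image_id,cell_id,channel,area_px,tfi,border_intensity,interior_intensity
img000,0,1,694,1217456.0,338368.0,879088.0
img000,0,2,694,410334.0,6771.0,403563.0
```

Five cells were detected and segmented; each contributes one row per
quantified channel (channel 5, DIC, is never quantified). Cell 0 covers
694 px and integrates 1 217 456 gray-value units of F-actin signal, of which
338 368 lie on its 1-px border. Evaluating the predictions against the
generator's ground truth:

```sh
$ synquant eval --pred demo/masks.json --gt demo/img000_gt.json
{ "box_ap@0.5": 100.0, "box_ap@0.7": 100.0, "mask_ap@0.5": 100.0,
  "mask_ap@0.7": 100.0, "mask_iou@0.5": 100.0, "mask_iou@0.7": 100.0 }
```

On an easy sparse scene the oracle path recovers every instance exactly.
`synquant train` fits the learned detector/segmenter on annotated stacks,
`synquant stats` compares two cohorts' TFI tables, `synquant compare` runs
pairwise arithmetic on a benchmark grid of published method scores
(e.g. the mean bounding-box AP advantage of the keypoint method over
CosineEmbedding across all data fractions is 60.70), and `synquant run`
executes the whole pipeline from one config.

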