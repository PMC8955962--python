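"""End-to-end orchestration: generate -> select Z -> detect -> segment ->
quantify -> evaluate/compare, with every intermediate persisted and a
manifest recording the configuration hash and seed.

All randomness flows from one root seed via named substreams (generation,
splitting/augmentation/initialization inside training), so a stored
manifest reproduces every deterministic output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthgen
from .detect import detect_cells
from .focalplane import select_focal_slice
from .models import (
    LearnedKeypointModel,
    LearnedSegmenter,
    ThresholdKeypointModel,
    ThresholdSegmenter,
    save_model,
)
from .quantify import compare_groups, distribution_summaries, per_cell_channel_table
from .segment import assemble_instances, crop_patch, segment_patch
from .stackio import AnnotationSet, write_annotations, write_label_image, write_stack, write_tfi_table
from .train_eval import EvalConfig, TrainConfig, evaluate, train_models

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "detect_and_segment"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    scene: synthgen.SceneParams = synthgen.SceneParams()
    n_images: int = 4
    model: str = "threshold"  # "threshold" | "learned"
    train: TrainConfig = TrainConfig(epochs=5)
    eval: EvalConfig = EvalConfig()
    seed: int = 0
    scene_b: synthgen.SceneParams | None = None  # optional second cohort
    stats_channel: int = 2

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # hash the computation, not its destination
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def detect_and_segment(image: np.ndarray, detector, segmenter, margin: int = 8, min_area: int = 20):
    """Detection followed by per-box patch segmentation on one 2-D image."""
    boxes = detect_cells(image, detector)
    masks = []
    kept_boxes = []
    for b in boxes:
        patch = crop_patch(image, b, margin=margin)
        m = segment_patch(patch, segmenter)
        if not m.any():
            continue
        kept_boxes.append(b)
        masks.append((m, patch))
    return assemble_instances(kept_boxes, masks, image.shape, min_area=min_area)


def _run_cohort(cfg: PipelineConfig, scene, subdir: Path, seed: int, detector, segmenter):
    dataset = synthgen.generate_dataset(cfg.n_images, scene, seed=seed)
    records = []
    preds, gts = [], []
    for i, (stack, gt) in enumerate(dataset):
        image_id = f"img{i:03d}"
        write_stack(stack, subdir / f"{image_id}.tiff")
        if gt.masks:
            write_label_image(gt.masks, subdir / f"{image_id}_labels.tiff")
        write_annotations(
            AnnotationSet(image_id=image_id, masks=gt.masks, boxes=gt.boxes),
            subdir / f"{image_id}_gt.json",
        )
        fp = select_focal_slice(stack, channel=3)
        img = stack.plane(1, fp.z_index).astype(np.float64)
        instances = detect_and_segment(img, detector, segmenter)
        preds.append(instances)
        gts.append(gt)
        if instances:
            write_annotations(
                AnnotationSet(
                    image_id=image_id,
                    masks=[inst.mask for inst in instances],
                    boxes=np.array([inst.box.as_array() for inst in instances]),
                    scores=np.array([inst.score for inst in instances]),
                ),
                subdir / f"{image_id}_pred.json",
            )
        records.extend(per_cell_channel_table(stack, fp, instances, image_id=image_id))
    write_tfi_table(records, subdir / "tfi.csv")
    result = evaluate(preds, gts, cfg.eval)
    return dataset, records, result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "generate"
    try:
        cohort_a = out / "cohort_a"
        cohort_a.mkdir(exist_ok=True)

        stage = "train"
        if config.model == "learned":
            train_set = synthgen.generate_dataset(
                max(config.n_images, 5), config.scene, seed=config.seed + 1000
            )
            detector, segmenter, curve = train_models(train_set, config.train)
            save_model(detector, out / "detector.joblib")
            save_model(segmenter, out / "segmenter.joblib")
            (out / "loss_curve.json").write_text(
                json.dumps({"train": curve.train, "val": curve.val})
            )
        elif config.model == "threshold":
            detector, segmenter = ThresholdKeypointModel(), ThresholdSegmenter()
        else:
            raise ValueError(f"unknown model kind {config.model!r}")

        stage = "evaluate"
        _, records_a, result_a = _run_cohort(
            config, config.scene, cohort_a, config.seed, detector, segmenter
        )
        report = {"cohort_a": result_a.as_dict()}

        if config.scene_b is not None:
            stage = "stats"
            cohort_b = out / "cohort_b"
            cohort_b.mkdir(exist_ok=True)
            _, records_b, result_b = _run_cohort(
                config, config.scene_b, cohort_b, config.seed + 1, detector, segmenter
            )
            report["cohort_b"] = result_b.as_dict()
            import pandas as pd

            ta, tb = pd.DataFrame(records_a), pd.DataFrame(records_b)
            stats_report = {}
            for ch in (1, 2, 3, 4):
                sa, sb, tt = compare_groups(ta, tb, ch)
                va = ta[ta["channel"] == ch]["tfi"].to_numpy()
                (hist, edges), (xs, ecdf) = distribution_summaries(va)
                stats_report[str(ch)] = {
                    "a": dataclasses.asdict(sa),
                    "b": dataclasses.asdict(sb),
                    "t": tt.t,
                    "p": tt.p,
                    "df": tt.df,
                    "significant": tt.p < 0.05,
                    "hist_counts": hist.tolist(),
                    "hist_edges": edges.tolist(),
                    "ecdf_tail": float(ecdf[-1]),
                }
            (out / "stats_report.json").write_text(json.dumps(stats_report, sort_keys=True))
            report["stats"] = {
                ch: {"p": stats_report[ch]["p"], "significant": stats_report[ch]["significant"]}
                for ch in stats_report
            }

        (out / "eval_report.json").write_text(json.dumps(report, sort_keys=True))
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "model": config.model,
            "n_images": config.n_images,
            "report": report,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True))
        return manifest
    except Exception as exc:  # noqa: BLE001 - stage attribution
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
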