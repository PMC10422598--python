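"""End-to-end orchestration: detect -> cut -> classify -> report.

A run is driven by one configuration (YAML-loadable) with per-module
sections and a single global seed, and writes every artifact — detections
JSON, crop labels, per-image emergence reports, an aggregate summary and the
resolved configuration snapshot — under one run directory. Reports contain
no timestamps, so a rerun with the same configuration and seed reproduces
byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .detect import DetectParams, FieldImage, detect_seedlings, annotate
from .crops import cut_crop, SeedlingCrop
from .net import Model, classify_crops
from .report import (StageCounts, emergence_proportion, uniformity_verdict,
                     UniformityRules, CountComparison, count_metrics)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "evaluate_run"]

log = logging.getLogger("soyemerge.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, item: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {item!r}: {cause}")
        self.stage = stage
        self.item = item
        self.cause = cause


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    model_weights: Optional[str] = None
    detect: DetectParams = field(default_factory=DetectParams)
    crop_margin: float = 0.10
    uniformity: UniformityRules = field(default_factory=UniformityRules)
    write_annotated: bool = True
    write_crops: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectParams(**raw.pop("detect", {}))
        uni = UniformityRules(**raw.pop("uniformity", {}))
        return cls(detect=det, uniformity=uni, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _load_images(input_dir: Path) -> list[Path]:
    exts = {".png", ".jpg", ".jpeg"}
    paths = sorted(p for p in input_dir.iterdir()
                   if p.suffix.lower() in exts)
    return paths


def run_pipeline(config: RunConfig) -> Path:
    """Run detection, cutting, classification and reporting over a directory.

    Returns the run directory. Every input image yields a detections JSON
    and an emergence report JSON; an aggregate summary CSV covers the batch.
    Without model weights the pipeline stops after detection and counts only.
    """
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise PipelineError("setup", str(input_dir), FileNotFoundError("no such directory"))
    images = _load_images(input_dir)
    if not images:
        raise PipelineError("setup", str(input_dir), ValueError("no input images found"))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))

    model = None
    if config.model_weights is not None:
        try:
            model = Model.load(config.model_weights)
        except Exception as exc:
            raise PipelineError("classify", str(config.model_weights), exc)

    summary_rows = []
    for path in images:
        try:
            image = FieldImage(np.asarray(Image.open(path).convert("RGB")),
                               source=str(path))
            detections, count = detect_seedlings(image, config.detect)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("detect", str(path), exc)
        log.info("detect: %s -> %d seedlings", path.name, count)

        det_payload = {
            "image": path.name,
            "count": count,
            "detections": [{"index": d.index, "bbox": list(d.rect),
                            "area": d.component.area} for d in detections],
        }
        (out / f"{path.stem}.detections.json").write_text(
            json.dumps(det_payload, indent=1))

        if config.write_annotated:
            ann = annotate(image, detections)
            Image.fromarray(ann.pixels).save(out / f"{path.stem}.annotated.png")

        labels: Optional[np.ndarray] = None
        if model is not None and detections:
            try:
                crops = [cut_crop(image, d, margin=config.crop_margin)
                         for d in detections]
                labels = classify_crops(model, crops)
            except Exception as exc:
                raise PipelineError("classify", str(path), exc)
            log.info("classify: %s -> stages %s", path.name,
                     np.bincount(labels, minlength=3).tolist())

        if labels is not None:
            counts = StageCounts(*(int(c) for c in np.bincount(labels, minlength=3)[:3]))
        else:
            counts = StageCounts(count, 0, 0)  # counting-only mode: stage unknown
        report = emergence_proportion(counts)
        verdict = uniformity_verdict(report, config.uniformity)
        rep_payload = {
            "image": path.name,
            "count": counts.total,
            "counts": {"VE": counts.ve, "VC": counts.vc, "V1": counts.v1},
            "staged": labels is not None,
            "EP": None if report.empty_field else
                  {"VE": report.ep[0], "VC": report.ep[1], "V1": report.ep[2]},
            "uniformity": {"uniform": verdict.uniform, "reasons": verdict.reasons},
        }
        (out / f"{path.stem}.report.json").write_text(json.dumps(rep_payload, indent=1))
        summary_rows.append({"image": path.name, "predicted_count": counts.total,
                             "ve": counts.ve, "vc": counts.vc, "v1": counts.v1,
                             "uniform": verdict.uniform})

    pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False)
    return out


def evaluate_run(run_dir: str | Path, truth_csv: str | Path) -> dict:
    """Compare a run's predicted counts with manual counts.

    ``truth_csv`` needs columns ``image`` and ``count``. Images missing from
    the truth table are listed, excluded and warned about. Returns per-image
    rows plus aggregate R^2 / RMSE / MAE / average accuracy, and writes
    ``evaluation.csv`` and ``evaluation.json`` into the run directory.
    """
    run = Path(run_dir)
    summary = pd.read_csv(run / "summary.csv")
    truth = pd.read_csv(truth_csv)
    if not {"image", "count"} <= set(truth.columns):
        raise ValueError("truth CSV must have columns: image, count")
    merged = summary.merge(truth[["image", "count"]], on="image", how="left")
    missing = merged[merged["count"].isna()]["image"].tolist()
    for name in missing:
        log.warning("no ground truth for %s; excluded from evaluation", name)
    rows = merged.dropna(subset=["count"])
    if len(rows) < 2:
        raise ValueError("need at least 2 images with ground truth")
    cmp = CountComparison(real=rows["count"].to_numpy(dtype=float),
                          predicted=rows["predicted_count"].to_numpy(dtype=float))
    metrics = count_metrics(cmp)
    payload = {
        "n_images": int(len(rows)),
        "missing_truth": missing,
        "r2": metrics.r2,
        "rmse": metrics.rmse,
        "mae": metrics.mae,
        "average_accuracy_pct": metrics.average_accuracy_pct,
    }
    rows = rows.assign(abs_error=(rows["predicted_count"] - rows["count"]).abs())
    rows.to_csv(run / "evaluation.csv", index=False)
    (run / "evaluation.json").write_text(json.dumps(payload, indent=1))
    return payload
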