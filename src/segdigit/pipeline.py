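"""End-to-end orchestration: per-frame localize -> classify (once per ROI)
-> annotate, plus stream evaluation and YAML configuration.

Per-frame FPS is measured over the compute path only (localization start
to annotation end); timing is logged, never asserted.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .annotate import AnnotatedFrame, annotate_frame
from .classify import predict_digit, preprocess_roi
from .cnn import CompactCNN
from .evaluate import (
    MAPResult,
    MatchConfig,
    evaluate_detections,
    match_detections,
    mean_fps,
)
from .localize import (
    AnchorSpec,
    HSVRange,
    LocalizationConfig,
    StructuringElement,
    UserROI,
    derive_anchors,
    localize_frame,
)
from .types import Dataset, Detection

__all__ = [
    "PipelineConfig",
    "StreamReport",
    "DEFAULT_FG_HSV_RANGE",
    "default_pipeline_config",
    "load_config",
    "save_config",
    "run_frame",
    "evaluate_stream",
]

logger = logging.getLogger("segdigit")

# Dark glyphs on a bright LCD background: select low-value pixels but not
# exact black, so zeroed pixels outside the user ROI stay background.
DEFAULT_FG_HSV_RANGE = HSVRange(h=(0.0, 1.0), s=(0.0, 1.0), v=(0.02, 0.45))


@dataclass
class PipelineConfig:
    """Localization settings, classifier input size and match criterion."""

    loc: LocalizationConfig
    input_size: int = 32
    match: MatchConfig = field(default_factory=MatchConfig)
    seed: int = 0


@dataclass
class StreamReport:
    """Aggregate recognition and runtime summary for a frame stream."""

    map_result: MAPResult
    mfps: float
    per_class: dict[int, dict[str, float]]
    n_frames: int
    n_excluded: int


def default_pipeline_config(
    train: Dataset,
    roi: UserROI | None = None,
    hsv: HSVRange = DEFAULT_FG_HSV_RANGE,
    anchor_tolerance: float = 0.25,
    input_size: int = 32,
    seed: int = 0,
) -> PipelineConfig:
    """Config with anchors derived per digit class from the training split
    (digit 1 is far narrower than the other glyphs, so a single median
    anchor would reject it)."""
    anchors = derive_anchors(train, rel_tolerance=anchor_tolerance, per_class=True)
    loc = LocalizationConfig(hsv=hsv, anchors=anchors, roi=roi)
    return PipelineConfig(loc=loc, input_size=input_size, seed=seed)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    obj = {
        "roi": [cfg.loc.roi.vpos, cfg.loc.roi.hpos, cfg.loc.roi.vsize, cfg.loc.roi.hsize]
        if cfg.loc.roi
        else None,
        "hsv": {"h": list(cfg.loc.hsv.h), "s": list(cfg.loc.hsv.s), "v": list(cfg.loc.hsv.v)},
        "se_width": cfg.loc.se.width,
        "anchors": [list(a) for a in cfg.loc.anchors.anchors],
        "anchor_tolerance": cfg.loc.anchors.rel_tolerance,
        "input_size": cfg.input_size,
        "iou_threshold": cfg.match.iou_threshold,
        "seed": cfg.seed,
    }
    Path(path).write_text(yaml.safe_dump(obj))


def load_config(path: str | Path) -> PipelineConfig:
    obj = yaml.safe_load(Path(path).read_text())
    hsv = HSVRange(
        h=tuple(obj["hsv"]["h"]), s=tuple(obj["hsv"]["s"]), v=tuple(obj["hsv"]["v"])
    )
    anchors = AnchorSpec(
        anchors=tuple(tuple(a) for a in obj["anchors"]),
        rel_tolerance=float(obj.get("anchor_tolerance", 0.25)),
    )
    roi = UserROI(*obj["roi"]) if obj.get("roi") else None
    loc = LocalizationConfig(
        hsv=hsv, anchors=anchors, roi=roi, se=StructuringElement(int(obj.get("se_width", 2)))
    )
    return PipelineConfig(
        loc=loc,
        input_size=int(obj.get("input_size", 32)),
        match=MatchConfig(float(obj.get("iou_threshold", 0.5))),
        seed=int(obj.get("seed", 0)),
    )


def run_frame(
    frame: np.ndarray,
    cfg: PipelineConfig,
    model: CompactCNN,
    frame_id: str = "frame",
) -> tuple[list[Detection], AnnotatedFrame, float]:
    """Localize, classify every surviving ROI, and annotate one frame.

    Returns the detections, the annotated frame and the per-frame FPS
    (1 / wall time of the detect-through-annotate path).
    """
    if model.input_size != cfg.input_size:
        raise ValueError(
            f"model input size {model.input_size} != configured {cfg.input_size}"
        )
    t0 = time.perf_counter()
    rois = localize_frame(frame, cfg.loc)
    dets: list[Detection] = []
    for box in rois:
        label, score = predict_digit(model, preprocess_roi(frame, box, cfg.input_size))
        dets.append(Detection(bbox=box, label=label, score=score))
    roi = cfg.loc.roi
    if roi is None:
        H, W = frame.shape[:2]
        roi = UserROI(0, 0, H, W)
    annotated = annotate_frame(frame, dets, roi, fps=0.0)
    elapsed = time.perf_counter() - t0
    fps = 1.0 / elapsed if elapsed > 0 else float("inf")
    annotated.records["fps"] = round(fps, 6)
    logger.info("frame=%s roi_n=%d ms=%.1f", frame_id, len(rois), elapsed * 1000)
    return dets, annotated, fps


def evaluate_stream(
    dataset: Dataset,
    cfg: PipelineConfig,
    model: CompactCNN,
) -> StreamReport:
    """Run the pipeline over an annotated stream and aggregate mAP + mFPS.

    Frames tagged as display transitions are excluded from scoring,
    mirroring the data-cleaning rule of dropping frames captured while
    the digits change.
    """
    if len(dataset) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    per_frame = []
    fps_samples = []
    n_excluded = 0
    for frame, gt in dataset.frames:
        if gt.transition:
            n_excluded += 1
            continue
        dets, _, fps = run_frame(frame, cfg, model, frame_id=gt.frame_id)
        per_frame.append((dets, gt.boxes))
        fps_samples.append(fps)
    map_result = evaluate_detections(per_frame, cfg.match)

    # per-class counts at score threshold 0, matched within each frame
    totals: dict[int, list[int]] = {}
    for dets, gts in per_frame:
        for label, c in match_detections(dets, gts, cfg.match).items():
            t = totals.setdefault(label, [0, 0, 0])
            t[0] += c.tp
            t[1] += c.fp
            t[2] += c.fn
    per_class = {
        ap.label: {
            "ap": ap.ap,
            "tp": totals.get(ap.label, [0, 0, 0])[0],
            "fp": totals.get(ap.label, [0, 0, 0])[1],
            "fn": totals.get(ap.label, [0, 0, 0])[2],
        }
        for ap in map_result.per_class
    }
    return StreamReport(
        map_result=map_result,
        mfps=mean_fps(fps_samples),
        per_class=per_class,
        n_frames=len(per_frame),
        n_excluded=n_excluded,
    )
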