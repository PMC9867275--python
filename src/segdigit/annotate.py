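"""Result annotation: burn the user ROI, detection boxes/labels and the
FPS figure into an output frame, and keep a lossless JSON record of every
overlay so downstream checks never depend on font rasterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .localize import UserROI
from .types import Detection

__all__ = ["AnnotatedFrame", "annotate_frame", "save_annotated", "load_overlay"]


@dataclass
class AnnotatedFrame:
    """Rendered frame plus the overlay records burned into it."""

    image: np.ndarray
    records: dict = field(default_factory=dict)


def _det_record(det: Detection) -> dict:
    return {"label": det.label, "score": round(float(det.score), 6), "bbox": det.bbox.as_list()}


def annotate_frame(
    frame: np.ndarray | AnnotatedFrame,
    dets: list[Detection],
    roi: UserROI,
    fps: float,
) -> AnnotatedFrame:
    """Draw the user ROI (solid black outline), each detection box with its
    label and score, and the FPS figure in the top-left corner.

    With zero detections the output is the original frame plus only the
    ROI outline and FPS text.  Re-annotating an annotated frame merges
    overlay records without duplicating them.
    """
    prior: list[dict] = []
    if isinstance(frame, AnnotatedFrame):
        prior = list(frame.records.get("detections", []))
        frame = frame.image
    roi.validate_for(frame.shape)

    det_records = list(prior)
    for det in dets:
        rec = _det_record(det)
        if rec not in det_records:
            det_records.append(rec)

    img = Image.fromarray(frame.copy())
    draw = ImageDraw.Draw(img)
    draw.rectangle(
        [roi.hpos, roi.vpos, roi.hpos + roi.hsize - 1, roi.vpos + roi.vsize - 1],
        outline=(0, 0, 0),
        width=2,
    )
    for rec in det_records:
        x, y, w, h = rec["bbox"]
        draw.rectangle([x, y, x + w - 1, y + h - 1], outline=(220, 30, 30), width=1)
        draw.text((x, max(0, y - 12)), f"{rec['label']} {rec['score']:.2f}", fill=(220, 30, 30))
    draw.text((4, 4), f"FPS {fps:.2f}", fill=(0, 0, 0))

    records = {
        "roi": [roi.vpos, roi.hpos, roi.vsize, roi.hsize],
        "fps": round(float(fps), 6),
        "detections": det_records,
    }
    return AnnotatedFrame(image=np.asarray(img), records=records)


def save_annotated(annotated: AnnotatedFrame, path: str | Path) -> Path:
    """Write the burned-in PNG plus a ``<frame>.overlay.json`` sidecar."""
    path = Path(path)
    Image.fromarray(annotated.image).save(path)
    sidecar = path.with_suffix(".overlay.json")
    sidecar.write_text(json.dumps(annotated.records, indent=2))
    return sidecar


def load_overlay(path: str | Path) -> dict:
    """Read back the overlay records written by :func:`save_annotated`."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".overlay.json")
    return json.loads(path.read_text())
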