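"""Disk formats: PNG frames and JSON-lines annotation/prediction files.

One JSON object per frame: ``{"frame_id", "boxes": [{"label", "bbox"}]}``
with ``[x, y, w, h]`` boxes in 0-based, top-left-origin, half-open pixel
coordinates; predictions add a ``"score"`` per box.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .types import BBox, Dataset, Detection, GroundTruthBox, GroundTruthFrame

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_annotations",
    "load_annotations",
    "save_detections",
    "load_detections",
]


def _gt_to_obj(gt: GroundTruthFrame) -> dict:
    obj: dict = {
        "frame_id": gt.frame_id,
        "boxes": [{"label": b.label, "bbox": b.bbox.as_list()} for b in gt.boxes],
    }
    if gt.transition:
        obj["transition"] = True
    if not gt.validated:
        obj["validated"] = False
    return obj


def _gt_from_obj(obj: dict) -> GroundTruthFrame:
    return GroundTruthFrame(
        frame_id=obj["frame_id"],
        boxes=[
            GroundTruthBox(label=int(b["label"]), bbox=BBox.from_list(b["bbox"]))
            for b in obj["boxes"]
        ],
        transition=bool(obj.get("transition", False)),
        validated=bool(obj.get("validated", True)),
    )


def save_annotations(frames: list[GroundTruthFrame], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gt in frames:
            fh.write(json.dumps(_gt_to_obj(gt)) + "\n")


def load_annotations(path: str | Path) -> list[GroundTruthFrame]:
    with open(path) as fh:
        return [_gt_from_obj(json.loads(line)) for line in fh if line.strip()]


def save_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write ``<frame_id>.png`` per frame plus ``annotations.jsonl``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for frame, gt in dataset.frames:
        iio.imwrite(out / f"{gt.frame_id}.png", frame)
    save_annotations([gt for _, gt in dataset.frames], out / "annotations.jsonl")
    return out


def load_dataset(in_dir: str | Path, split: str = "train") -> Dataset:
    in_dir = Path(in_dir)
    gts = load_annotations(in_dir / "annotations.jsonl")
    frames = [
        (np.asarray(iio.imread(in_dir / f"{gt.frame_id}.png")), gt) for gt in gts
    ]
    return Dataset(frames, split=split)


def save_detections(per_frame: list[tuple[str, list[Detection]]], path: str | Path) -> None:
    """Predictions mirror the GT schema plus a per-box ``score``."""
    with open(path, "w") as fh:
        for frame_id, dets in per_frame:
            obj = {
                "frame_id": frame_id,
                "boxes": [
                    {"label": d.label, "bbox": d.bbox.as_list(), "score": float(d.score)}
                    for d in dets
                ],
            }
            fh.write(json.dumps(obj) + "\n")


def load_detections(path: str | Path) -> list[tuple[str, list[Detection]]]:
    out: list[tuple[str, list[Detection]]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            dets = [
                Detection(bbox=BBox.from_list(b["bbox"]), label=int(b["label"]), score=float(b["score"]))
                for b in obj["boxes"]
            ]
            out.append((obj["frame_id"], dets))
    return out
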