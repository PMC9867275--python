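"""Shared value types used across the pipeline.

Boxes are axis-aligned, half-open pixel rectangles ``[x, y, width, height]``
with a top-left origin: a box covers columns ``x .. x+width-1`` and rows
``y .. y+height-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BBox",
    "Blob",
    "GroundTruthBox",
    "GroundTruthFrame",
    "Detection",
    "Dataset",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in half-open pixel coordinates."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 0 or self.height < 0:
            raise ValueError(f"negative box extent: {self}")

    @property
    def area(self) -> int:
        return self.width * self.height

    def as_list(self) -> list[int]:
        return [self.x, self.y, self.width, self.height]

    @classmethod
    def from_list(cls, xywh) -> "BBox":
        x, y, w, h = (int(round(v)) for v in xywh)
        return cls(x, y, w, h)

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices selecting the box's pixels in an image array."""
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)

    def contains(self, other: "BBox") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and other.x + other.width <= self.x + self.width
            and other.y + other.height <= self.y + self.height
        )


@dataclass(frozen=True)
class Blob:
    """Connected foreground region summary: area, centroid and bounding box.

    ``centroid`` is (x, y) with sub-pixel precision (mean pixel coordinate).
    """

    area: int
    centroid: tuple[float, float]
    bbox: BBox


@dataclass(frozen=True)
class GroundTruthBox:
    label: int
    bbox: BBox

    def __post_init__(self) -> None:
        if not 0 <= self.label <= 9:
            raise ValueError(f"digit label out of range: {self.label}")


@dataclass(frozen=True)
class Detection:
    bbox: BBox
    label: int
    score: float


@dataclass
class GroundTruthFrame:
    """Exact annotations for one frame.

    ``transition`` marks frames captured while the display was changing;
    such frames are excluded from evaluation.  ``validated`` is False for
    machine-proposed annotations that a human has not yet checked.
    """

    frame_id: str
    boxes: list[GroundTruthBox] = field(default_factory=list)
    transition: bool = False
    validated: bool = True


@dataclass
class Dataset:
    """An ordered collection of (frame, annotation) pairs with a split tag."""

    frames: list[tuple[np.ndarray, GroundTruthFrame]]
    split: str = "train"

    def __len__(self) -> int:
        return len(self.frames)

    def label_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {d: 0 for d in range(10)}
        for _, gt in self.frames:
            for box in gt.boxes:
                hist[box.label] += 1
        return hist
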