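"""Digit localization: user ROI masking, HSV thresholding, morphological
cleaning, blob analysis and anchor-box ROI filtering.

The stage chain is: restrict the frame to a user-chosen rectangle, keep
pixels whose HSV color falls in a configured range, clean the binary mask
with one erosion followed by two dilations (a square structuring element,
2 px wide by default), summarize 8-connected components as blobs, and keep
only blobs whose bounding box is close in size to a predefined anchor box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor
from skimage import measure as _skmeasure

from .types import BBox, Blob, Dataset

__all__ = [
    "UserROI",
    "HSVRange",
    "StructuringElement",
    "AnchorSpec",
    "LocalizationConfig",
    "apply_user_roi",
    "hsv_threshold",
    "clean_binary",
    "blob_analysis",
    "detect_rois",
    "derive_anchors",
    "localize_frame",
]


@dataclass(frozen=True)
class UserROI:
    """User-designated rectangle ``[vPos, hPos, vSize, hSize]`` in px from
    the top-left corner (vertical first, matching row-major indexing)."""

    vpos: int
    hpos: int
    vsize: int
    hsize: int

    def __post_init__(self) -> None:
        if min(self.vpos, self.hpos, self.vsize, self.hsize) < 0:
            raise ValueError(f"ROI entries must be >= 0: {self}")

    def validate_for(self, shape: tuple[int, ...]) -> None:
        H, W = shape[:2]
        if self.vpos + self.vsize > H or self.hpos + self.hsize > W:
            raise ValueError(f"ROI {self} exceeds frame of shape {(H, W)}")

    def as_bbox(self) -> BBox:
        return BBox(x=self.hpos, y=self.vpos, width=self.hsize, height=self.vsize)


@dataclass(frozen=True)
class HSVRange:
    """Per-channel (low, high) bounds on HSV in [0, 1]; hue wraps."""

    h: tuple[float, float] = (0.0, 1.0)
    s: tuple[float, float] = (0.0, 1.0)
    v: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("s", "v"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range inverted: {(lo, hi)}")


@dataclass(frozen=True)
class StructuringElement:
    """Square structuring element; origin at the top-left cell."""

    width: int = 2

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("structuring element width must be >= 1")


@dataclass(frozen=True)
class AnchorSpec:
    """Predefined (width, height) box templates with a relative size tolerance."""

    anchors: tuple[tuple[float, float], ...]
    rel_tolerance: float = 0.25

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("anchor list must be non-empty")
        if not 0.0 <= self.rel_tolerance < 1.0:
            raise ValueError(f"tolerance must be in [0, 1): {self.rel_tolerance}")


def apply_user_roi(frame: np.ndarray, roi: UserROI) -> np.ndarray:
    """Zero every pixel outside the user ROI; pixels inside are unchanged."""
    roi.validate_for(frame.shape)
    out = np.zeros_like(frame)
    rs = slice(roi.vpos, roi.vpos + roi.vsize)
    cs = slice(roi.hpos, roi.hpos + roi.hsize)
    out[rs, cs] = frame[rs, cs]
    return out


def hsv_threshold(frame: np.ndarray, rng: HSVRange) -> np.ndarray:
    """Binary mask of pixels whose HSV triplet lies inside ``rng``.

    Saturation and value are tested as closed intervals; hue is tested
    with wraparound when low > high (e.g. a red band (0.95, 0.05)).
    """
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("hsv_threshold expects an RGB frame")
    hsv = _skcolor.rgb2hsv(frame)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    h_lo, h_hi = rng.h
    if h_lo <= h_hi:
        h_ok = (h >= h_lo) & (h <= h_hi)
    else:
        h_ok = (h >= h_lo) | (h <= h_hi)
    s_ok = (s >= rng.s[0]) & (s <= rng.s[1])
    v_ok = (v >= rng.v[0]) & (v <= rng.v[1])
    return h_ok & s_ok & v_ok


def _erode(mask: np.ndarray, width: int) -> np.ndarray:
    """Erosion by a width x width square with top-left origin, zero-padded:
    out[p] = AND over offsets s in [0, width)^2 of mask[p + s]."""
    H, W = mask.shape
    padded = np.zeros((H + width - 1, W + width - 1), dtype=bool)
    padded[:H, :W] = mask
    out = np.ones((H, W), dtype=bool)
    for di in range(width):
        for dj in range(width):
            out &= padded[di : di + H, dj : dj + W]
    return out


def _dilate(mask: np.ndarray, width: int) -> np.ndarray:
    """Dilation by the same element: out[p] = OR over s of mask[p - s]."""
    H, W = mask.shape
    padded = np.zeros((H + width - 1, W + width - 1), dtype=bool)
    padded[width - 1 :, width - 1 :] = mask
    out = np.zeros((H, W), dtype=bool)
    for di in range(width):
        for dj in range(width):
            out |= padded[width - 1 - di : width - 1 - di + H, width - 1 - dj : width - 1 - dj + W]
    return out


def clean_binary(mask: np.ndarray, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """One erosion (speckle removal) followed by two dilations (stroke
    thickening): ``((mask - SE) + SE) + SE`` with zero-padded borders."""
    mask = np.asarray(mask, dtype=bool)
    return _dilate(_dilate(_erode(mask, se.width), se.width), se.width)


def blob_analysis(mask: np.ndarray) -> list[Blob]:
    """Summarize each 8-connected foreground component as a Blob.

    Blobs carry pixel area, sub-pixel (x, y) centroid and the tight
    ``[x, y, width, height]`` bounding box, sorted by (y, x) of the box's
    top-left corner.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled = _skmeasure.label(mask, connectivity=2)
    blobs: list[Blob] = []
    for region in _skmeasure.regionprops(labeled):
        minr, minc, maxr, maxc = region.bbox
        cy, cx = region.centroid
        blobs.append(
            Blob(
                area=int(region.area),
                centroid=(float(cx), float(cy)),
                bbox=BBox(x=int(minc), y=int(minr), width=int(maxc - minc), height=int(maxr - minr)),
            )
        )
    blobs.sort(key=lambda b: (b.bbox.y, b.bbox.x))
    return blobs


def detect_rois(blobs: list[Blob], anchors: AnchorSpec) -> list[BBox]:
    """Keep a blob's box iff some anchor (w_a, h_a) satisfies
    |w - w_a| <= tol * w_a and |h - h_a| <= tol * h_a (boundary inclusive);
    input order is preserved."""
    tol = anchors.rel_tolerance
    kept: list[BBox] = []
    for blob in blobs:
        w, h = blob.bbox.width, blob.bbox.height
        for wa, ha in anchors.anchors:
            if abs(w - wa) <= tol * wa and abs(h - ha) <= tol * ha:
                kept.append(blob.bbox)
                break
    return kept


@dataclass
class LocalizationConfig:
    """Everything the localization stage needs for one display setup."""

    hsv: HSVRange
    anchors: AnchorSpec
    roi: UserROI | None = None
    se: StructuringElement = field(default_factory=StructuringElement)


def localize_frame(frame: np.ndarray, cfg: LocalizationConfig) -> list[BBox]:
    """Run the full localization chain on one frame and return candidate
    digit boxes: user ROI -> HSV threshold -> morphology -> blobs -> anchors."""
    img = apply_user_roi(frame, cfg.roi) if cfg.roi is not None else frame
    mask = hsv_threshold(img, cfg.hsv)
    mask = clean_binary(mask, cfg.se)
    return detect_rois(blob_analysis(mask), cfg.anchors)


def derive_anchors(
    train: Dataset,
    rel_tolerance: float = 0.25,
    per_class: bool = False,
) -> AnchorSpec:
    """Anchor sizes from the training annotations.

    Default: one anchor at the median (width, height) over all ground-truth
    boxes.  With ``per_class=True`` one anchor per digit class is derived
    (and deduplicated); useful because digit 1 is far narrower than its
    display-mates.
    """
    sizes: dict[int, list[tuple[int, int]]] = {}
    for _, gt in train.frames:
        for box in gt.boxes:
            sizes.setdefault(box.label, []).append((box.bbox.width, box.bbox.height))
    all_sizes = [wh for group in sizes.values() for wh in group]
    if not all_sizes:
        raise ValueError("cannot derive anchors from a dataset with no boxes")

    def median_wh(group: list[tuple[int, int]]) -> tuple[float, float]:
        arr = np.asarray(group, dtype=float)
        return (float(np.median(arr[:, 0])), float(np.median(arr[:, 1])))

    if per_class:
        anchors = sorted({median_wh(group) for group in sizes.values()})
    else:
        anchors = [median_wh(all_sizes)]
    return AnchorSpec(anchors=tuple(anchors), rel_tolerance=rel_tolerance)
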