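"""Synthetic seven-segment LCD frame generator with exact ground truth.

Emulates a bench rig in which a small LCD shows a row of seven-segment
digits that change every few seconds while a fixed camera records VGA
frames.  Glyphs are unions of axis-aligned segment rectangles on an
LCD-like background; foreground/background colors are specified in HSV,
per-glyph scale jitter perturbs the glyph height, and i.i.d. Gaussian
pixel noise (clipped to [0, 255]) models sensor noise.  Every rendered
glyph is annotated with the tight bounding box of its foreground pixels,
so downstream localization and classification can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import colorsys

import numpy as np

from .types import BBox, Dataset, GroundTruthBox, GroundTruthFrame

__all__ = [
    "SegmentPattern",
    "SceneSpec",
    "segment_pattern",
    "glyph_mask",
    "render_frame",
    "make_dataset",
    "default_scene",
]

# Segment order: (a, b, c, d, e, f, g) = top, top-right, bottom-right,
# bottom, bottom-left, top-left, middle.
_SEGMENTS = "abcdefg"

_DIGIT_SEGMENTS: dict[int, str] = {
    0: "abcdef",
    1: "bc",
    2: "abdeg",
    3: "abcdg",
    4: "bcfg",
    5: "acdfg",
    6: "acdefg",
    7: "abc",
    8: "abcdefg",
    9: "abcdfg",
}

# Glyph width as a fraction of glyph height (standard narrow LCD aspect).
_WIDTH_FRACTION = 0.55


@dataclass(frozen=True)
class SegmentPattern:
    """On/off state of the seven segments in (a..g) order."""

    bits: tuple[bool, bool, bool, bool, bool, bool, bool]

    def __post_init__(self) -> None:
        if len(self.bits) != 7:
            raise ValueError("a segment pattern has exactly seven bits")


def segment_pattern(digit: int) -> SegmentPattern:
    """Canonical seven-segment encoding of a decimal digit."""
    if not isinstance(digit, (int, np.integer)) or not 0 <= digit <= 9:
        raise ValueError(f"digit must be in 0..9, got {digit!r}")
    on = _DIGIT_SEGMENTS[int(digit)]
    return SegmentPattern(tuple(s in on for s in _SEGMENTS))


@dataclass
class SceneSpec:
    """Full description of one synthetic frame.

    ``digits`` lists (value, (x, y) top-left corner in px, glyph height px).
    HSV components are in [0, 1]; ``noise_sd`` is on the 0-255 intensity
    scale; ``scale_jitter`` is a multiplicative (low, high) range applied
    to each glyph height independently.
    """

    frame_size: tuple[int, int] = (480, 640)  # (height, width)
    digits: list[tuple[int, tuple[int, int], int]] = field(default_factory=list)
    stroke_fraction: float = 0.15
    fg_hsv: tuple[float, float, float] = (0.33, 0.20, 0.16)
    bg_hsv: tuple[float, float, float] = (0.33, 0.45, 0.75)
    noise_sd: float = 0.0
    scale_jitter: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scale_jitter
        if not (0.0 < lo <= hi <= 2.0):
            raise ValueError(f"scale_jitter must lie in (0, 2], got {self.scale_jitter}")
        for value, (x, y), height in self.digits:
            if not 0 <= value <= 9:
                raise ValueError(f"digit value out of range: {value}")
            if height < 8:
                raise ValueError(f"glyph height must be >= 8 px, got {height}")
            self._check_fit(x, y, height, hi)

    def _check_fit(self, x: int, y: int, height: int, scale_hi: float) -> None:
        H, W = self.frame_size
        h_max = int(round(height * scale_hi))
        w_max = _glyph_width(h_max)
        if x < 0 or y < 0 or y + h_max > H or x + w_max > W:
            raise ValueError(
                f"glyph at ({x}, {y}) with height {height} (max scale {scale_hi}) "
                f"does not fit a {H}x{W} frame"
            )


def _glyph_width(height: int) -> int:
    return max(int(round(_WIDTH_FRACTION * height)), 4)


def glyph_mask(digit: int, height: int, stroke_fraction: float = 0.15) -> np.ndarray:
    """Rasterize one seven-segment glyph as a boolean (height x width) mask.

    Segments are axis-aligned rectangles: horizontal strokes span the full
    glyph width, vertical strokes span half the glyph height, so adjacent
    segments overlap at the corners and every digit is one connected region.
    """
    pattern = segment_pattern(digit)
    h = int(height)
    w = _glyph_width(h)
    t = max(1, int(round(stroke_fraction * h)))
    mid = (h - t) // 2
    half = h // 2
    rects = {
        "a": (slice(0, t), slice(0, w)),
        "b": (slice(0, half), slice(w - t, w)),
        "c": (slice(half, h), slice(w - t, w)),
        "d": (slice(h - t, h), slice(0, w)),
        "e": (slice(half, h), slice(0, t)),
        "f": (slice(0, half), slice(0, t)),
        "g": (slice(mid, mid + t), slice(0, w)),
    }
    mask = np.zeros((h, w), dtype=bool)
    for seg, on in zip(_SEGMENTS, pattern.bits):
        if on:
            mask[rects[seg]] = True
    return mask


def _tight_bbox(mask: np.ndarray, x0: int, y0: int) -> BBox:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return BBox(
        x=x0 + int(cols[0]),
        y=y0 + int(rows[0]),
        width=int(cols[-1] - cols[0] + 1),
        height=int(rows[-1] - rows[0] + 1),
    )


def render_frame(spec: SceneSpec, frame_id: str = "frame") -> tuple[np.ndarray, GroundTruthFrame]:
    """Render one frame and its exact ground truth.

    Deterministic for a fixed ``spec`` (including its seed).  Returns a
    uint8 RGB image of ``spec.frame_size`` and one tight ground-truth box
    per digit in ``spec.digits``.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.frame_size
    bg = np.array(colorsys.hsv_to_rgb(*spec.bg_hsv)) * 255.0
    fg = np.array(colorsys.hsv_to_rgb(*spec.fg_hsv)) * 255.0
    frame = np.empty((H, W, 3), dtype=np.float64)
    frame[:] = bg

    boxes: list[GroundTruthBox] = []
    for value, (x, y), height in spec.digits:
        lo, hi = spec.scale_jitter
        scale = rng.uniform(lo, hi)
        h = max(8, int(round(height * scale)))
        mask = glyph_mask(value, h, spec.stroke_fraction)
        gh, gw = mask.shape
        if y + gh > H or x + gw > W:
            raise ValueError(f"glyph for digit {value} leaves the frame at ({x}, {y})")
        region = frame[y : y + gh, x : x + gw]
        region[mask] = fg
        boxes.append(GroundTruthBox(label=int(value), bbox=_tight_bbox(mask, x, y)))

    if spec.noise_sd > 0:
        frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
    frame = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return frame, GroundTruthFrame(frame_id=frame_id, boxes=boxes)


def default_scene(
    n_digits: int = 4,
    frame_size: tuple[int, int] = (480, 640),
    glyph_height: int = 64,
    spacing: int = 100,
    **kwargs,
) -> SceneSpec:
    """A centered row of ``n_digits`` placeholder digits (values 0..)."""
    H, W = frame_size
    w = _glyph_width(glyph_height)
    row_width = (n_digits - 1) * spacing + w if n_digits else 0
    x0 = (W - row_width) // 2
    y0 = (H - glyph_height) // 2
    digits = [(d % 10, (x0 + i * spacing, y0), glyph_height) for i, d in enumerate(range(n_digits))]
    return SceneSpec(frame_size=frame_size, digits=digits, **kwargs)


def _balanced_deck(rng: np.random.Generator, count: int) -> list[int]:
    """``count`` digit values drawn from shuffled decks of 0..9.

    Guarantees every class appears once per ten draws, so even small
    snapshot sets cover all ten classes (iid sampling would miss a class
    with non-negligible probability at 40 draws).
    """
    deck: list[int] = []
    while len(deck) < count:
        deck.extend(rng.permutation(10).tolist())
    return deck[:count]


def make_dataset(
    train_frames: int,
    test_frames: int,
    spec_template: SceneSpec,
    seed: int = 0,
    change_every: int = 10,
) -> tuple[Dataset, Dataset]:
    """Generate a snapshot training split and a streaming test split.

    Training frames are independent snapshots with freshly dealt digit
    values.  Test frames form an ordered stream whose displayed values
    change every ``change_every`` frames; the first frame of each new
    group is rendered mid-refresh (a mix of old and new values) and
    tagged ``transition=True`` so evaluation can exclude it, mirroring
    the data-cleaning step of dropping frames captured while the display
    changes.
    """
    if train_frames < 0 or test_frames < 0:
        raise ValueError("frame counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_pos = len(spec_template.digits)

    def scene_with(values: list[int]) -> SceneSpec:
        digits = [
            (v, pos, h) for v, (_, pos, h) in zip(values, spec_template.digits)
        ]
        return replace(spec_template, digits=digits, seed=int(rng.integers(2**31)))

    train_list: list[tuple[np.ndarray, GroundTruthFrame]] = []
    deck = _balanced_deck(rng, train_frames * n_pos)
    for i in range(train_frames):
        values = deck[i * n_pos : (i + 1) * n_pos]
        frame, gt = render_frame(scene_with(values), frame_id=f"train_{i:04d}")
        train_list.append((frame, gt))

    test_list: list[tuple[np.ndarray, GroundTruthFrame]] = []
    if test_frames > 0:
        n_groups = -(-test_frames // change_every)
        group_deck = _balanced_deck(rng, n_groups * n_pos)
        prev_values: list[int] | None = None
        idx = 0
        for g in range(n_groups):
            values = group_deck[g * n_pos : (g + 1) * n_pos]
            for j in range(change_every):
                if idx >= test_frames:
                    break
                transition = j == 0 and prev_values is not None
                shown = values
                if transition:
                    # mid-refresh: leading half of the display still shows
                    # the previous values
                    shown = prev_values[: n_pos // 2] + values[n_pos // 2 :]
                frame, gt = render_frame(scene_with(shown), frame_id=f"test_{idx:04d}")
                gt.transition = transition
                test_list.append((frame, gt))
                idx += 1
            prev_values = values

    return Dataset(train_list, split="train"), Dataset(test_list, split="test")
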