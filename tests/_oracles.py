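"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-pixel loops, deliberately separate
from the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def erode_oracle(mask: np.ndarray, width: int) -> np.ndarray:
    """Set erosion by a width x width square, origin at the top-left cell,
    borders treated as background."""
    H, W = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for i in range(H):
        for j in range(W):
            ok = True
            for di in range(width):
                for dj in range(width):
                    r, c = i + di, j + dj
                    if r >= H or c >= W or not mask[r, c]:
                        ok = False
                        break
                if not ok:
                    break
            out[i, j] = ok
    return out


def dilate_oracle(mask: np.ndarray, width: int) -> np.ndarray:
    """Set dilation by the same element: union of mask translated by every
    offset in [0, width)^2."""
    H, W = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for i in range(H):
        for j in range(W):
            hit = False
            for di in range(width):
                for dj in range(width):
                    r, c = i - di, j - dj
                    if 0 <= r < H and 0 <= c < W and mask[r, c]:
                        hit = True
                        break
                if hit:
                    break
            out[i, j] = hit
    return out


def clean_oracle(mask: np.ndarray, width: int) -> np.ndarray:
    return dilate_oracle(dilate_oracle(erode_oracle(mask, width), width), width)


def blobs_oracle(mask: np.ndarray) -> list[dict]:
    """8-connected components by explicit flood fill; per blob: area,
    (x, y) centroid, [x, y, w, h] box.  Sorted by (y, x) of the box."""
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    blobs = []
    for i in range(H):
        for j in range(W):
            if not mask[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            pixels = []
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            rows = [p[0] for p in pixels]
            cols = [p[1] for p in pixels]
            blobs.append(
                {
                    "area": len(pixels),
                    "centroid": (sum(cols) / len(cols), sum(rows) / len(rows)),
                    "bbox": [min(cols), min(rows), max(cols) - min(cols) + 1, max(rows) - min(rows) + 1],
                }
            )
    blobs.sort(key=lambda b: (b["bbox"][1], b["bbox"][0]))
    return blobs


def iou_pixel_oracle(a: list[int], b: list[int]) -> float:
    """IoU of two [x, y, w, h] boxes by literal pixel-set counting."""
    sa = {(x, y) for x in range(a[0], a[0] + a[2]) for y in range(a[1], a[1] + a[3])}
    sb = {(x, y) for x in range(b[0], b[0] + b[2]) for y in range(b[1], b[1] + b[3])}
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def rasterize_digit_oracle(digit: int, height: int, stroke_fraction: float = 0.15) -> np.ndarray:
    """Per-pixel seven-segment rasterizer: a pixel is foreground iff it lies
    inside any active segment rectangle (full-width horizontals, half-height
    verticals, stroke t = round(stroke_fraction * height))."""
    on = {
        0: "abcdef", 1: "bc", 2: "abdeg", 3: "abcdg", 4: "bcfg",
        5: "acdfg", 6: "acdefg", 7: "abc", 8: "abcdefg", 9: "abcdfg",
    }[digit]
    h = height
    w = max(int(round(0.55 * h)), 4)
    t = max(1, int(round(stroke_fraction * h)))
    mid = (h - t) // 2
    half = h // 2

    def inside(r: int, c: int, seg: str) -> bool:
        if seg == "a":
            return r < t
        if seg == "d":
            return r >= h - t
        if seg == "g":
            return mid <= r < mid + t
        if seg == "b":
            return r < half and c >= w - t
        if seg == "c":
            return r >= half and c >= w - t
        if seg == "e":
            return r >= half and c < t
        if seg == "f":
            return r < half and c < t
        raise AssertionError(seg)

    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            out[r, c] = any(inside(r, c, seg) for seg in on)
    return out


def greedy_match_oracle(dets, gts, tau):
    """dets: list of (score, [x,y,w,h], label); gts: list of ([x,y,w,h], label).
    Greedy descending-score one-to-one matching; returns TP flags in the
    sorted detection order along with that order."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][0], dets[i][1][0], dets[i][1][1]))
    used = [False] * len(gts)
    flags = []
    for i in order:
        score, box, label = dets[i]
        best, best_iou = -1, tau
        for g, (gbox, glabel) in enumerate(gts):
            if used[g] or glabel != label:
                continue
            ov = iou_pixel_oracle(box, gbox)
            if ov >= best_iou:
                best, best_iou = g, ov
        if best >= 0:
            used[best] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags, order


def ap_oracle(dets, gts, tau=0.5) -> float:
    """Average precision by exhaustive threshold enumeration and loop-based
    monotone-envelope integration (single class, single frame)."""
    flags, order = greedy_match_oracle(dets, gts, tau)
    scores = [dets[i][0] for i in order]
    points = []
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for s, f in zip(scores, flags) if s >= thr and f)
        fp = sum(1 for s, f in zip(scores, flags) if s >= thr and not f)
        p = tp / (tp + fp)
        r = tp / len(gts) if gts else 0.0
        points.append((r, p))
    if not points:
        return 0.0
    ap = 0.0
    prev_r = 0.0
    for r, _ in sorted(points):
        if r <= prev_r:
            continue
        p_env = max(p2 for r2, p2 in points if r2 >= r)
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap
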