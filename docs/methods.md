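# Methods

## Problem setting

The package reads decimal digits off seven-segment LCD displays from RGB
camera frames (default VGA, 640 × 480). Recognition is treated as object
detection with ten classes: localization proposes candidate digit boxes,
a classifier assigns each box a digit and a confidence, and detection mAP
at a fixed IoU threshold scores the combined system.

## Localization model

The localization chain assumes digits are the only objects inside a
user-designated rectangle whose color separates from the display
background in HSV space.

- **User ROI** `[vPos, hPos, vSize, hSize]`: pixels outside the rectangle
  are set to zero. The default foreground HSV range keeps value in
  [0.02, 0.45] — dark glyphs on a bright background — with the floor above
  exact black so zeroed pixels never enter the mask.
- **HSV thresholding**: closed intervals per channel on [0, 1]; hue wraps
  when low > high (red bands). Conversion uses scikit-image's RGB→HSV.
- **Morphological cleaning**: one erosion then two dilations with a square
  structuring element of width 2 px (default). Erosion removes isolated
  noise pixels; the two dilations re-thicken strokes so a glyph's segments
  form a single connected region. The element's origin is its top-left
  cell (an even-width element has no central pixel; fixing the origin
  makes the operation exactly reproducible) and borders are zero-padded.
  The net effect grows each glyph's box by about one pixel per side
  relative to the tight ground-truth box.
- **Blob analysis**: 8-connected components (seven-segment strokes can
  touch only diagonally at corners), each summarized by pixel area,
  sub-pixel centroid, and tight `[x, y, w, h]` box, sorted by (y, x).
- **Anchor filtering**: a blob survives iff some anchor `(w_a, h_a)`
  satisfies `|w − w_a| ≤ tol·w_a` and `|h − h_a| ≤ tol·h_a`
  (boundary-inclusive, `tol` = 0.25). Anchors are derived from training
  annotations. The default is the single median (width, height); the
  pipeline helper uses one anchor per digit class instead, because digit 1
  occupies only the right stroke of the glyph cell — its tight box is
  roughly a stroke width wide, far outside the tolerance band of the
  median digit width, so a single anchor would discard every 1.

## Classifier

Candidate crops are normalized before classification: grayscale, global
binarization at mid-intensity 0.5 (crops come from a high-contrast
display, so a fixed threshold suffices and is configurable), complement
`|I − 1|` so the glyph is the bright foreground, zero-padding to a square
with `X = ⌊(side−i)/2⌋` rows on top / `Y = ⌊(side−j)/2⌋` columns on the
left (odd remainders go to the bottom/right), resize to the model side
`n = 32`, and replication to three identical channels.

**Resize kernel.** The default is anti-aliased bilinear. Nearest-neighbor
resizing (available via `order=0`, and exactly what a binarity-preserving
pipeline would naively choose) turned out to be the single largest error
source end to end: localized boxes are one pixel wider than the tight
training boxes, and under nearest resampling that one-pixel shift can
delete an entire stroke column of the 32 × 32 input. Digit pairs that
differ by one segment (9 vs 5, 6 vs 5, 8 vs 9) were then confused
systematically. Bilinear resampling turns the same shift into a small
intensity change at stroke edges and removes the failure mode.

The reference model is a compact CNN — two 3 × 3 convolution + ReLU +
2 × 2 max-pool blocks (8 and 16 channels) and a fully connected softmax
head — implemented directly on numpy (im2col convolutions, explicit
backward pass) and trained from scratch. Digit classification on a single
display is a simple, nearly separable task for which a shallow network is
appropriate and fast on one CPU; the training interface is
architecture-agnostic so other models can be plugged in.

Training uses stochastic gradient descent with momentum 0.9, mini-batch
32, constant learning rate 3 × 10⁻⁴, and at most 100 epochs, with 10% of
the crops held out and checked every 3 epochs. Early stopping (patience 5
checks) monitors the held-out **cross-entropy**, not accuracy: accuracy
saturates at 1.0 within a handful of epochs on separable crops, and
stopping there leaves the decision margins so thin that the one-pixel
train/test box mismatch flips predictions. Validation loss keeps
decreasing while margins widen, so the loss plateau is the meaningful
stopping signal. The best-loss weights are restored at the end. All
randomness (initialization, shuffling, validation split) derives from the
training seed.

**Augmentation.** The ten-snapshot training set is replicated ×10
(configurable 10–100); each replicate rescales every glyph crop in place
by a factor drawn uniformly from [0.9, 1.0], re-centered in its original
box with the frame's median color as background fill, and the box shrunk
to match. Only scale is perturbed: for a camera that can approach a
display frontally, scale is the dominant geometric nuisance.

**Auto-labeler.** A linear SVM (one-vs-one) over HOG descriptors
(9 orientations, 8 × 8 cells, 2 × 2 blocks) of the same preprocessed
crops proposes labels for unlabeled streams. Proposals are explicitly
flagged unvalidated; confirming them is the caller's job.

## Evaluation

Detections are matched per frame, per class, greedily in descending
confidence (ties broken by box position), one-to-one against ground truth
at IoU ≥ τ (default 0.5, on half-open integer boxes). Matched detections
are TP, unmatched detections FP, unmatched ground truths FN; TN is carried
for API completeness but is undefined for detection and unused. Precision
is TP/(TP+FP), recall TP/(TP+FN), with 0/0 defined as precision 1 and
recall 0. The PR curve sweeps the unique detection scores; AP integrates
the monotone precision envelope over recall increments (all-point
interpolation); mAP averages AP over the classes present in the ground
truth. Runtime is summarized as the arithmetic mean of per-frame FPS,
where each frame's FPS is 1 / wall time of the localize-through-annotate
compute path (disk IO excluded); timing is logged, never asserted.

## Synthetic data generator

The generator emulates a bench rig: a fixed camera records an LCD showing
a row of seven-segment digits that change every few seconds.

- Glyphs are unions of axis-aligned segment rectangles (full-width
  horizontals, half-height verticals, stroke = 0.15 × glyph height,
  width = 0.55 × height), which keeps every digit a single 8-connected
  region and makes exact per-pixel ground truth trivial.
- Default palette: dark desaturated glyphs (HSV 0.33, 0.20, 0.16) on a
  bright green LCD background (0.33, 0.45, 0.75), i.i.d. Gaussian pixel
  noise clipped to [0, 255], per-glyph multiplicative scale jitter.
- Ground-truth boxes are computed from the rendered mask, so they are
  tight by construction regardless of rounding.
- Digit values are dealt from shuffled decks of 0–9 rather than iid
  draws: a 10-snapshot × 4-digit training split must cover all ten
  classes (an iid draw misses one with probability ≈ 0.15), and balanced
  decks guarantee it without skewing the per-class frequencies.
- The test split is an ordered frame sequence whose values change every
  k frames (default 10); the first frame of each new group is rendered
  mid-refresh (half old, half new values) and tagged as a transition
  frame, which stream evaluation excludes — the synthetic counterpart of
  discarding video frames captured while a display updates.

What the generator does **not** model: camera tilt, defocus, reflections,
brightness gradients, perspective, rolling-shutter artifacts, or font
differences between devices. Passing the end-to-end tests therefore shows
the pipeline's stages compose correctly and the small-data recipe works
under controlled noise and scale variation — not that the system is
deployment-ready for arbitrary real displays, which need per-device
calibration of the HSV range, anchors and training crops.

## Experiment sizes and numerical choices

The standard recovery experiment uses 10 training snapshots and a
200-frame test stream with 4 digits per frame, noise SD 5 (of 255) and
scale jitter [0.95, 1.05]; augmentation ×10 gives 400 training crops.
These sizes keep the full experiment at a few minutes on one CPU while
leaving ~720 scored boxes, enough to resolve mAP differences of a few
parts per thousand. The directional augmentation comparison uses a
noisier variant (noise SD 15, jitter [0.9, 1.1], 60-frame stream) where
the unaugmented ten-image baseline is measurably imperfect.

Degenerate inputs are handled explicitly: empty scenes render background
only; empty masks yield no blobs; a 1 × 1 crop preprocesses to a constant
input; a 10-way softmax always has a maximum ≥ 0.1; empty detection sets
give a degenerate PR curve with AP 0; empty datasets, out-of-range
digits, out-of-bounds boxes and inverted ranges raise `ValueError`.

## Known limitations

- The localization chain has no merge/split rule: lighting that fractures
  a glyph into two blobs, or fuses neighbors, produces boxes the anchor
  filter may reject (no such rule is defined for the base method either).
- The anchor filter assumes digits of one display share a size; mixed
  font sizes need explicit anchor lists.
- The compact CNN is trained per display; no transfer learning or
  pretrained backbones are bundled.
- FPS figures depend entirely on host hardware and are reported, not
  guaranteed.
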