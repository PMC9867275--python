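# segdigit

Optical digit recognition for seven-segment LCD displays, of the kind found
on bedside medical devices (infusion pumps, ventilators, hemodynamic
monitors) that have no data interface: the only way to log their readings is
to point a camera at the screen and read the digits off the frames.
Seven-segment glyphs are made of disconnected bar strokes, which defeats
general-purpose OCR engines, so the pipeline here is purpose-built:

1. **Localization** — restrict the frame to a user-chosen region of
   interest, binarize by HSV color thresholding, clean the mask with one
   erosion followed by two dilations (square structuring element, 2 px),
   extract 8-connected blobs with area/centroid/bounding-box statistics,
   and keep only boxes whose size matches a predefined anchor box within a
   relative tolerance.
2. **Classification** — crop each surviving box, convert to grayscale,
   binarize, complement (|I − 1|, so the glyph becomes the bright
   foreground), zero-pad to a square with margins
   X = ⌊(max(i,j)−i)/2⌋, Y = ⌊(max(i,j)−j)/2⌋, resize to the model input
   n×n, replicate to three identical channels, and classify with a compact
   CNN (two 3×3 conv + ReLU + max-pool blocks and a softmax head) trained
   with SGDM (mini-batch 32, initial learning rate 0.0003, validation check
   every 3 epochs, at most 100 epochs).
3. **Annotation** — draw the user ROI, each detection with its label and
   confidence, and the per-frame FPS; every overlay is also written to a
   lossless JSON sidecar.

Evaluation uses the standard detection metrics: IoU-thresholded greedy
matching (τ = 0.5), precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
per-class average precision as the area under the interpolated
precision–recall curve `AP = Σ [r(τ)−r(τ+1)]·p̃(τ)`, the class mean
`mAP = (1/C) Σ AP(k)`, and mean FPS for runtime.

Because training data for such displays is scarce, the package follows a
small-data recipe: only ten annotated snapshot images, replicated ×10–100
with random rescaling in [0.9, 1.0] (the camera can move closer, so scale
is the dominant nuisance), plus a HOG + SVM auto-labeler for proposing
labels on video streams that a human then validates.

A synthetic seven-segment LCD generator (`segdigit.synthdigit`) renders
frames with exact ground-truth boxes — controllable colors, per-glyph scale
jitter, Gaussian pixel noise, and streaming splits whose displayed values
change every k frames — so the entire pipeline is testable end to end
without any camera.

## Worked example

```python
import segdigit as sd

# ten annotated training snapshots and a 200-frame test stream
template = sd.default_scene(n_digits=4, noise_sd=5.0, scale_jitter=(0.95, 1.05))
train, test = sd.make_dataset(10, 200, template, seed=42)

# small-data training recipe: x10 replication, scale jitter 0.9-1.0
model = sd.train_classifier(
    train,
    aug=sd.AugmentationConfig(replication_factor=10, scale_range=(0.9, 1.0)),
    tc=sd.TrainConfig(seed=42),
)

cfg = sd.default_pipeline_config(train, seed=42)   # anchors derived from train
report = sd.evaluate_stream(test, cfg, model)
print(f"mAP {report.map_result.map:.3f} over {report.n_frames} frames "
      f"(excluded {report.n_excluded} transition frames)")
```

prints

```
mAP 1.000 over 181 frames (excluded 19 transition frames)
```

i.e. every digit on every evaluable frame was localized with IoU ≥ 0.5 and
classified correctly; the 19 frames captured while the displayed values
changed are excluded from scoring, mirroring standard data cleaning for
display recordings.

The same workflow is available from the shell:

```sh
segdigit generate --train 10 --test 200 --seed 42 --out data/
segdigit train --data data/train --aug-factor 10 --scale 0.9 1.0 --seed 42 --out model.npz
segdigit evaluate-stream --model model.npz --data data/test
```

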