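"""Digit classification: ROI preprocessing, scale-jitter augmentation,
CNN training, prediction, and the HOG+SVM semi-automatic labeler.

Each candidate box is cropped from the frame, converted to grayscale,
binarized, complemented (so the glyph is the bright foreground),
zero-padded to a square, resized to the model's input side ``n`` and
replicated to three identical channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor
from skimage import transform as _sktransform
from skimage.feature import hog as _hog
from sklearn.svm import SVC

from .cnn import CompactCNN
from .localize import LocalizationConfig, localize_frame
from .types import BBox, Dataset, Detection, GroundTruthBox, GroundTruthFrame

__all__ = [
    "AugmentationConfig",
    "TrainConfig",
    "pad_square",
    "complement_binary",
    "to_model_input",
    "preprocess_roi",
    "augment_dataset",
    "train_classifier",
    "predict_digit",
    "HOGSVMLabeler",
    "train_autolabeler",
    "auto_label",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """Duplicate the training set ``replication_factor`` times, rescaling
    every duplicate by a factor drawn uniformly from ``scale_range``."""

    replication_factor: int = 10
    scale_range: tuple[float, float] = (0.9, 1.0)

    def __post_init__(self) -> None:
        if self.replication_factor < 1:
            raise ValueError("replication factor must be >= 1")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi <= 2.0):
            raise ValueError(f"scale range must lie in (0, 2]: {self.scale_range}")


@dataclass(frozen=True)
class TrainConfig:
    """SGDM training recipe for the digit classifier."""

    optimizer: str = "sgdm"
    mini_batch: int = 32
    initial_lr: float = 0.0003
    momentum: float = 0.9
    validation_frequency: int = 3  # epochs between held-out accuracy checks
    max_epochs: int = 100
    patience: int = 5  # validation checks without improvement before stopping
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mini_batch, self.validation_frequency, self.max_epochs) < 1:
            raise ValueError("mini_batch, validation_frequency and max_epochs must be positive")
        if self.initial_lr <= 0:
            raise ValueError("learning rate must be positive")


# ---- preprocessing stages ----------------------------------------------


def pad_square(img: np.ndarray) -> np.ndarray:
    """Zero-pad a rectangular crop to a square of side max(i, j).

    The original is placed with ``X = floor((max(i,j)-i)/2)`` rows of
    padding on top and ``Y = floor((max(i,j)-j)/2)`` columns on the left;
    any odd remainder goes to the bottom/right.
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("pad_square expects a non-empty 2-D crop")
    i, j = img.shape
    side = max(i, j)
    top = (side - i) // 2
    left = (side - j) // 2
    out = np.zeros((side, side), dtype=img.dtype)
    out[top : top + i, left : left + j] = img
    return out


def complement_binary(img: np.ndarray) -> np.ndarray:
    """Invert a {0, 1} image: ``|I - 1|`` elementwise."""
    img = np.asarray(img)
    if not np.isin(img, (0, 1)).all():
        raise ValueError("complement_binary expects values in {0, 1}")
    return np.abs(img - 1).astype(img.dtype)


def to_model_input(img: np.ndarray, n: int, order: int = 1) -> np.ndarray:
    """Resize a square image to n x n and replicate it to three identical
    channels (n, n, 3).

    ``order=1`` (default) is anti-aliased bilinear: a one-pixel change in
    the source box nudges stroke-edge intensities instead of deleting a
    whole stroke column, which matters for digit pairs that differ by a
    single segment.  ``order=0`` is nearest neighbor and preserves
    binarity exactly.
    """
    if n < 1:
        raise ValueError("model input side must be >= 1")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("to_model_input expects a square 2-D image")
    if img.shape[0] != n:
        img = _sktransform.resize(
            img, (n, n), order=order, anti_aliasing=order > 0, preserve_range=True
        )
    return np.stack([img, img, img], axis=-1)


def preprocess_roi(
    frame: np.ndarray,
    bbox: BBox,
    n: int,
    binarize_threshold: float = 0.5,
    resize_order: int = 1,
) -> np.ndarray:
    """Crop -> grayscale -> binarize -> complement -> pad to square ->
    resize to the model input.  Returns an (n, n, 3) float array in [0, 1]
    with identical channels; the glyph is the bright foreground."""
    H, W = frame.shape[:2]
    if bbox.x < 0 or bbox.y < 0 or bbox.x + bbox.width > W or bbox.y + bbox.height > H:
        raise ValueError(f"box {bbox} lies outside a {H}x{W} frame")
    if bbox.width < 1 or bbox.height < 1:
        raise ValueError("empty crop")
    crop = frame[bbox.slices()]
    gray = _skcolor.rgb2gray(crop) if crop.ndim == 3 else np.asarray(crop, dtype=float)
    binary = (gray > binarize_threshold).astype(float)
    glyph = complement_binary(binary)  # glyph darker than LCD background
    return to_model_input(pad_square(glyph), n, order=resize_order)


# ---- augmentation -------------------------------------------------------


def _rescale_crop_in_frame(
    frame: np.ndarray, box: BBox, scale: float, fill: np.ndarray
) -> tuple[np.ndarray, BBox]:
    """Replace the content of ``box`` with a rescaled copy of itself,
    re-centered in place; returns the new frame and the shrunken box."""
    if scale == 1.0:
        return frame, box
    new_w = max(1, int(round(box.width * scale)))
    new_h = max(1, int(round(box.height * scale)))
    crop = frame[box.slices()].astype(float)
    resized = _sktransform.resize(
        crop, (new_h, new_w, crop.shape[2]), order=1, anti_aliasing=False, preserve_range=True
    )
    out = frame.copy()
    out[box.slices()] = fill
    nx = box.x + (box.width - new_w) // 2
    ny = box.y + (box.height - new_h) // 2
    new_box = BBox(x=nx, y=ny, width=new_w, height=new_h)
    out[new_box.slices()] = np.clip(np.rint(resized), 0, 255).astype(frame.dtype)
    return out, new_box


def augment_dataset(train: Dataset, cfg: AugmentationConfig, seed: int = 0) -> Dataset:
    """Duplicate every annotated frame ``replication_factor`` times with a
    fresh per-glyph scale factor in ``scale_range`` for each duplicate.

    Output size = input size x replication_factor, labels preserved,
    deterministic for a fixed seed.
    """
    if len(train) == 0:
        raise ValueError("cannot augment an empty dataset")
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, GroundTruthFrame]] = []
    for rep in range(cfg.replication_factor):
        for frame, gt in train.frames:
            new_frame = frame
            # frame-median color stands in for the LCD background fill
            fill = np.median(frame.reshape(-1, frame.shape[2]), axis=0).astype(frame.dtype)
            new_boxes: list[GroundTruthBox] = []
            for box in gt.boxes:
                s = float(rng.uniform(*cfg.scale_range))
                new_frame, new_bbox = _rescale_crop_in_frame(new_frame, box.bbox, s, fill)
                new_boxes.append(GroundTruthBox(label=box.label, bbox=new_bbox))
            out.append(
                (
                    new_frame,
                    GroundTruthFrame(
                        frame_id=f"{gt.frame_id}_aug{rep:03d}",
                        boxes=new_boxes,
                        transition=gt.transition,
                    ),
                )
            )
    return Dataset(out, split=train.split)


# ---- training and prediction -------------------------------------------


def _extract_crops(dataset: Dataset, n: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for frame, gt in dataset.frames:
        for box in gt.boxes:
            xs.append(preprocess_roi(frame, box.bbox, n).transpose(2, 0, 1))
            ys.append(box.label)
    if not xs:
        raise ValueError("dataset contains no annotated boxes")
    return np.stack(xs), np.asarray(ys, dtype=int)


def _check_all_classes(y: np.ndarray) -> None:
    missing = sorted(set(range(10)) - set(int(v) for v in y))
    if missing:
        raise ValueError(f"training data misses digit classes {missing}")


def train_classifier(
    train: Dataset,
    aug: AugmentationConfig | None = None,
    tc: TrainConfig = TrainConfig(),
    input_size: int = 32,
) -> CompactCNN:
    """Train the compact CNN on the (optionally augmented) crop set.

    Uses SGDM with the configured mini-batch size, initial learning rate,
    max epoch count, and held-out accuracy checks every
    ``validation_frequency`` epochs with early stopping on plateau.
    """
    base_x, base_y = _extract_crops(train, input_size)
    _check_all_classes(base_y)
    data = augment_dataset(train, aug, seed=tc.seed) if aug is not None else train
    X, y = _extract_crops(data, input_size)

    rng = np.random.default_rng(tc.seed)
    model = CompactCNN(input_size=input_size, seed=tc.seed)

    n_val = int(round(tc.val_fraction * len(X)))
    if n_val >= 1:
        order = rng.permutation(len(X))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        X_val, y_val = X[val_idx], y[val_idx]
        X_tr, y_tr = X[tr_idx], y[tr_idx]
    else:
        X_val = y_val = None
        X_tr, y_tr = X, y

    # plateau detection tracks validation cross-entropy: accuracy saturates
    # almost immediately on this near-separable problem, while continued
    # loss descent keeps widening the decision margins.
    best_loss, best_state, bad_checks = np.inf, None, 0
    for epoch in range(1, tc.max_epochs + 1):
        order = rng.permutation(len(X_tr))
        for i in range(0, len(order), tc.mini_batch):
            idx = order[i : i + tc.mini_batch]
            model.train_batch(X_tr[idx], y_tr[idx], lr=tc.initial_lr, momentum=tc.momentum)
        model.epochs_run = epoch
        if X_val is not None and epoch % tc.validation_frequency == 0:
            val_loss, _ = model.evaluate(X_val, y_val)
            if val_loss < best_loss - 1e-6:
                best_loss, best_state, bad_checks = val_loss, model.state_dict(), 0
            else:
                bad_checks += 1
                if bad_checks >= tc.patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model


def predict_digit(model: CompactCNN, x: np.ndarray) -> tuple[int, float]:
    """Classify one preprocessed (n, n, 3) input; returns (label, score)
    where score is the maximum of the 10-way probability vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.input_size, model.input_size, 3):
        raise ValueError(
            f"input shape {x.shape} does not match model input size {model.input_size}"
        )
    probs = model.predict_proba(x.transpose(2, 0, 1)[None])[0]
    label = int(probs.argmax())
    return label, float(probs[label])


# ---- HOG + SVM semi-automatic labeler -----------------------------------


@dataclass
class HOGSVMLabeler:
    """Support vector machine over HOG descriptors of preprocessed crops,
    used to propose labels for unlabeled frames (one-vs-one multiclass)."""

    svm: SVC
    input_size: int = 32

    def describe(self, x: np.ndarray) -> np.ndarray:
        """HOG descriptor of an (n, n, 3) preprocessed crop (deterministic)."""
        return _hog(
            x[..., 0],
            orientations=9,
            pixels_per_cell=(8, 8),
            cells_per_block=(2, 2),
            feature_vector=True,
        )

    def predict(self, x: np.ndarray) -> int:
        return int(self.svm.predict(self.describe(x)[None])[0])


def train_autolabeler(train: Dataset, input_size: int = 32) -> HOGSVMLabeler:
    """Fit the SVM labeler on HOG features of the training crops."""
    X, y = _extract_crops(train, input_size)
    _check_all_classes(y)
    labeler = HOGSVMLabeler(svm=SVC(kernel="linear", C=10.0), input_size=input_size)
    feats = np.stack([labeler.describe(x.transpose(1, 2, 0)) for x in X])
    labeler.svm.fit(feats, y)
    return labeler


def auto_label(
    labeler: HOGSVMLabeler,
    frames: list[np.ndarray],
    loc_cfg: LocalizationConfig,
) -> list[GroundTruthFrame]:
    """Localize and label each frame; proposals are marked unvalidated
    (a human confirms them before they become ground truth)."""
    proposals: list[GroundTruthFrame] = []
    for i, frame in enumerate(frames):
        boxes = [
            GroundTruthBox(
                label=labeler.predict(preprocess_roi(frame, box, labeler.input_size)),
                bbox=box,
            )
            for box in localize_frame(frame, loc_cfg)
        ]
        proposals.append(
            GroundTruthFrame(frame_id=f"proposed_{i:04d}", boxes=boxes, validated=False)
        )
    return proposals
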