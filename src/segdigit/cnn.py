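"""A compact convolutional network for 10-way digit classification.

Two 3x3 conv + ReLU + 2x2 max-pool blocks followed by a fully connected
softmax head.  Implemented directly on numpy (im2col convolutions) and
trained with stochastic gradient descent with momentum (SGDM).  The model
is deliberately small: seven-segment glyph crops are close to linearly
separable, and a shallow network keeps training fast on a single CPU.

Weights are stored as a ``.npz`` archive with a JSON sidecar holding the
architecture id, input size, class order and training seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CompactCNN", "softmax"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patch matrix for stride-1 conv."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # B, C, H, W, k, k
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)


def _col2im(dcols: np.ndarray, shape: tuple[int, ...], k: int, pad: int) -> np.ndarray:
    """Adjoint of ``_im2col``: scatter-add patch gradients back to the image."""
    B, C, H, W = shape
    d = dcols.reshape(B, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + H, dj : dj + W] += d[:, :, :, :, di, dj]
    return dxp[:, :, pad : pad + H, pad : pad + W]


class CompactCNN:
    """conv(3x3) -> ReLU -> pool(2) -> conv(3x3) -> ReLU -> pool(2) -> FC -> softmax."""

    architecture = "compact-cnn"

    def __init__(
        self,
        input_size: int = 32,
        channels: tuple[int, int] = (8, 16),
        n_classes: int = 10,
        seed: int = 0,
    ) -> None:
        if input_size < 4 or input_size % 4:
            raise ValueError("input size must be a positive multiple of 4")
        self.input_size = int(input_size)
        self.channels = tuple(int(c) for c in channels)
        self.n_classes = int(n_classes)
        self.seed = int(seed)
        self.epochs_run = 0
        rng = np.random.default_rng(seed)
        c1, c2 = self.channels
        m = input_size // 4  # spatial side after two 2x2 pools
        # He-normal initialization
        self.params: dict[str, np.ndarray] = {
            "W1": rng.normal(0, np.sqrt(2.0 / (3 * 9)), size=(c1, 3, 3, 3)),
            "b1": np.zeros(c1),
            "W2": rng.normal(0, np.sqrt(2.0 / (c1 * 9)), size=(c2, c1, 3, 3)),
            "b2": np.zeros(c2),
            "W3": rng.normal(0, np.sqrt(2.0 / (c2 * m * m)), size=(c2 * m * m, n_classes)),
            "b3": np.zeros(n_classes),
        }
        self._velocity = {k: np.zeros_like(v) for k, v in self.params.items()}

    # ---- forward -------------------------------------------------------

    def _conv_forward(self, x, W, b):
        F = W.shape[0]
        B, _, H, Wd = x.shape
        cols = _im2col(x, 3, 1)
        out = cols @ W.reshape(F, -1).T + b
        return out.transpose(0, 2, 1).reshape(B, F, H, Wd), cols

    @staticmethod
    def _pool_forward(x):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        return out, mask

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """x: (B, 3, n, n) float array in [0, 1]. Returns class logits."""
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.input_size:
            raise ValueError(f"expected (B, 3, {self.input_size}, {self.input_size}) input")
        p = self.params
        x0 = x - 0.5  # center binary inputs
        z1, cols1 = self._conv_forward(x0, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0)
        p1, m1 = self._pool_forward(a1)
        z2, cols2 = self._conv_forward(p1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0)
        p2, m2 = self._pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        logits = flat @ p["W3"] + p["b3"]
        if keep_cache:
            self._cache = (x0, cols1, z1, m1, p1, cols2, z2, m2, p2, flat)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    # ---- backward ------------------------------------------------------

    def _grads(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        x0, cols1, z1, m1, p1, cols2, z2, m2, p2, flat = self._cache
        B = x0.shape[0]
        g: dict[str, np.ndarray] = {}
        g["W3"] = flat.T @ dlogits
        g["b3"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["W3"].T
        dp2 = dflat.reshape(p2.shape)

        da2 = self._pool_backward(dp2, m2)
        dz2 = da2 * (z2 > 0)
        g["W2"], g["b2"], dp1 = self._conv_backward(dz2, cols2, p["W2"], p1.shape)

        da1 = self._pool_backward(dp1, m1)
        dz1 = da1 * (z1 > 0)
        g["W1"], g["b1"], _ = self._conv_backward(dz1, cols1, p["W1"], x0.shape)
        for k in g:
            g[k] = g[k] / B
        return g

    @staticmethod
    def _pool_backward(dout, mask):
        B, C, Hp, Wp = dout.shape
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = mask * (dout[:, :, :, None, :, None] / counts)
        return d.reshape(B, C, Hp * 2, Wp * 2)

    @staticmethod
    def _conv_backward(dz, cols, W, in_shape):
        F = W.shape[0]
        B = dz.shape[0]
        dflat = dz.reshape(B, F, -1).transpose(0, 2, 1)  # B, H*W, F
        dW = np.einsum("bpf,bpc->fc", dflat, cols).reshape(W.shape)
        db = dz.sum(axis=(0, 2, 3))
        dcols = dflat @ W.reshape(F, -1)
        dx = _col2im(dcols, in_shape, 3, 1)
        return dW, db, dx

    # ---- training ------------------------------------------------------

    def train_batch(self, x, y, lr: float, momentum: float = 0.9) -> float:
        """One SGDM update on a mini-batch; returns the batch cross-entropy."""
        logits = self.forward(x, keep_cache=True)
        probs = softmax(logits)
        B = x.shape[0]
        loss = -np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean()
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        grads = self._grads(dlogits)
        for k, gk in grads.items():
            v = self._velocity[k]
            v *= momentum
            v -= lr * gk
            self.params[k] += v
        return float(loss)

    def accuracy(self, x, y, batch: int = 256) -> float:
        correct = 0
        for i in range(0, len(x), batch):
            pred = self.forward(x[i : i + batch]).argmax(axis=1)
            correct += int((pred == y[i : i + batch]).sum())
        return correct / len(x)

    def evaluate(self, x, y, batch: int = 256) -> tuple[float, float]:
        """(mean cross-entropy, accuracy) over a dataset."""
        loss_sum, correct = 0.0, 0
        for i in range(0, len(x), batch):
            probs = softmax(self.forward(x[i : i + batch]))
            yi = y[i : i + batch]
            loss_sum += float(-np.log(np.clip(probs[np.arange(len(yi)), yi], 1e-12, None)).sum())
            correct += int((probs.argmax(axis=1) == yi).sum())
        return loss_sum / len(x), correct / len(x)

    # ---- persistence ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=float).copy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.params)
        meta = {
            "architecture": self.architecture,
            "input_size": self.input_size,
            "channels": list(self.channels),
            "classes": list(range(self.n_classes)),
            "seed": self.seed,
            "epochs_run": self.epochs_run,
        }
        sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" else path.with_suffix(".json")
        sidecar.write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CompactCNN":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        model = cls(
            input_size=meta["input_size"],
            channels=tuple(meta["channels"]),
            n_classes=len(meta["classes"]),
            seed=meta["seed"],
        )
        model.epochs_run = meta.get("epochs_run", 0)
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model
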