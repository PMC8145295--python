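"""A small trainable CNN, implemented in numpy.

Architecture (ten layers): input, conv1 3x3x64 + ReLU, conv2 3x3x64 + ReLU,
max-pool 2x2 stride 2, conv3 3x3x128 + ReLU, fully connected, softmax.  All
convolutions are stride 1 with 'same' zero padding, so one pooling stage
halves the spatial grid exactly once.  Training is plain SGD with momentum
(v <- m*v - r*grad; w <- w + v) on the softmax cross-entropy.

Convolutions are computed as nine offset-slice matrix products (one per
kernel tap), which keeps both the forward and backward passes inside BLAS
without materializing an im2col buffer.  Inputs are standardized per image
and per channel before entering the network, so activation magnitude tracks
deviation from the typical (background) intensity rather than raw
brightness — the property the downstream saliency map relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

LAYER_NAMES = ("input", "conv1", "relu1", "conv2", "relu2", "maxpool",
               "conv3", "relu3", "fc", "softmax")


@dataclass
class SaliencyNetSpec:
    """Hyperparameters of the small CNN.

    input_size 224 matches the common pretrained-backbone resolution; the
    desk-scale default is 64.  learning_rate 0.001 and batch_size 28 follow
    the training protocol the segmentation network was tuned with.
    """

    input_size: int = 64
    n_classes: int = 2
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 5
    batch_size: int = 28
    seed: int = 0
    conv_filters: tuple[int, int, int] = (64, 64, 128)

    def validate(self) -> None:
        if self.input_size < 4 or self.input_size % 2 != 0:
            raise ValueError("input_size must be even and >= 4")
        if self.n_classes < 2:
            raise ValueError("at least two classes are required")
        if self.conv_filters != (64, 64, 128):
            raise ValueError("the architecture fixes conv filters at (64, 64, 128)")


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 stride-1 'same' convolution of (B,H,W,Cin) with (3,3,Cin,Cout)."""
    B, H, W, _ = x.shape
    cout = w.shape[3]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.zeros((B, H, W, cout), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            out += xp[:, i:i + H, j:j + W, :] @ w[i, j]
    out += b
    return out


def _conv_same_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    """Gradients of _conv_same: returns (dx, dw, db)."""
    B, H, W, cin = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    flat_dout = dout.reshape(-1, dout.shape[3])
    for i in range(3):
        for j in range(3):
            patch = xp[:, i:i + H, j:j + W, :].reshape(-1, cin)
            dw[i, j] = patch.T @ flat_dout
            dxp[:, i:i + H, j:j + W, :] += dout @ w[i, j].T
    db = dout.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _maxpool2(x: np.ndarray):
    B, H, W, C = x.shape
    xr = x.reshape(B, H // 2, 2, W // 2, 2, C)
    out = xr.max(axis=(2, 4))
    return out, xr


def _maxpool2_backward(xr: np.ndarray, out: np.ndarray, dout: np.ndarray) -> np.ndarray:
    # Route gradient to the (first) max position in each 2x2 window.
    mask = (xr == out[:, :, None, :, None, :])
    mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
    dxr = mask * dout[:, :, None, :, None, :]
    B, Hh, _, Wh, _, C = dxr.shape
    return dxr.reshape(B, Hh * 2, Wh * 2, C)


class SaliencyNet:
    """Ten-layer CNN classifier exposing its third-conv-layer activations."""

    def __init__(self, spec: SaliencyNetSpec):
        spec.validate()
        self.spec = spec
        self.layer_names = LAYER_NAMES
        f1, f2, f3 = spec.conv_filters
        rng = np.random.default_rng(spec.seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        s = spec.input_size
        self.params = {
            "w1": he((3, 3, 3, f1), 27), "b1": np.zeros(f1, dtype=np.float32),
            "w2": he((3, 3, f1, f2), 9 * f1), "b2": np.zeros(f2, dtype=np.float32),
            "w3": he((3, 3, f2, f3), 9 * f2), "b3": np.zeros(f3, dtype=np.float32),
            "wfc": he(((s // 2) ** 2 * f3, spec.n_classes), (s // 2) ** 2 * f3),
            "bfc": np.zeros(spec.n_classes, dtype=np.float32),
        }
        self.velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.loss_history: list[float] = []
        self.trained = False

    # ---- data plumbing -------------------------------------------------

    def preprocess(self, image: np.ndarray) -> np.ndarray:
        """Resize to the input grid and standardize per channel."""
        arr = np.asarray(image)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        arr = arr.astype(np.float32)
        s = self.spec.input_size
        if arr.shape[:2] != (s, s):
            arr = resize(arr, (s, s), order=1, preserve_range=True,
                         anti_aliasing=False).astype(np.float32)
        mean = arr.mean(axis=(0, 1), keepdims=True)
        sd = arr.std(axis=(0, 1), keepdims=True)
        return (arr - mean) / (sd + 1e-6)

    def _forward_convs(self, x: np.ndarray):
        p = self.params
        c1 = np.maximum(_conv_same(x, p["w1"], p["b1"]), 0.0)
        c2 = np.maximum(_conv_same(c1, p["w2"], p["b2"]), 0.0)
        pooled, xr = _maxpool2(c2)
        c3 = np.maximum(_conv_same(pooled, p["w3"], p["b3"]), 0.0)
        return {"x": x, "c1": c1, "c2": c2, "xr": xr, "pooled": pooled, "c3": c3}

    def forward(self, x: np.ndarray):
        """Logits for a preprocessed batch (B, s, s, 3)."""
        cache = self._forward_convs(x)
        flat = cache["c3"].reshape(x.shape[0], -1)
        logits = flat @ self.params["wfc"] + self.params["bfc"]
        cache["flat"] = flat
        return logits, cache

    def conv_activations(self, image: np.ndarray) -> np.ndarray:
        """Post-ReLU activations of the third conv layer, (s/2, s/2, 128)."""
        x = self.preprocess(image)[None]
        return self._forward_convs(x)["c3"][0]

    # ---- training ------------------------------------------------------

    def _backward(self, cache, dlogits):
        p = self.params
        grads = {}
        grads["wfc"] = cache["flat"].T @ dlogits
        grads["bfc"] = dlogits.sum(axis=0)
        dc3 = (dlogits @ p["wfc"].T).reshape(cache["c3"].shape)
        dc3 = dc3 * (cache["c3"] > 0)
        dpooled, grads["w3"], grads["b3"] = _conv_same_backward(cache["pooled"], p["w3"], dc3)
        dc2 = _maxpool2_backward(cache["xr"], cache["pooled"], dpooled)
        dc2 = dc2 * (cache["c2"] > 0)
        dc1, grads["w2"], grads["b2"] = _conv_same_backward(cache["c1"], p["w2"], dc2)
        dc1 = dc1 * (cache["c1"] > 0)
        _, grads["w1"], grads["b1"] = _conv_same_backward(cache["x"], p["w1"], dc1)
        return grads

    def sgd_step(self, grads) -> None:
        r, m = self.spec.learning_rate, self.spec.momentum
        for k, g in grads.items():
            v = self.velocity[k]
            v *= m
            v -= r * g.astype(np.float32)
            self.params[k] += v

    def train(self, images, labels) -> list[float]:
        """SGD-with-momentum training on (image, class-label) pairs.

        Returns the per-epoch mean cross-entropy history (also stored on the
        net).  Deterministic given the spec seed.
        """
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if classes.size < 2:
            raise ValueError("training requires at least two classes")
        y = np.searchsorted(classes, labels)
        self.classes_ = classes
        X = np.stack([self.preprocess(img) for img in images])
        rng = np.random.default_rng(self.spec.seed + 1)
        n = X.shape[0]
        for _ in range(self.spec.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.spec.batch_size):
                idx = order[start:start + self.spec.batch_size]
                logits, cache = self.forward(X[idx])
                z = logits - logits.max(axis=1, keepdims=True)
                expz = np.exp(z)
                probs = expz / expz.sum(axis=1, keepdims=True)
                losses.append(float(-np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12).mean()))
                dlogits = probs
                dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                dlogits /= len(idx)
                self.sgd_step(self._backward(cache, dlogits))
            self.loss_history.append(float(np.mean(losses)))
        self.trained = True
        return self.loss_history

    def predict(self, images) -> np.ndarray:
        X = np.stack([self.preprocess(img) for img in images])
        logits, _ = self.forward(X)
        return self.classes_[np.argmax(logits, axis=1)]


def sgd_momentum_step(w, v, grad, learning_rate, momentum):
    """One reference SGD+momentum update: v <- m*v - r*grad; w <- w + v."""
    v = momentum * v - learning_rate * grad
    return w + v, v
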