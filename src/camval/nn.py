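"""Minimal deterministic NumPy neural-network layers for small CNNs.

Provides exactly what the desk-scale classifiers and Score-CAM need: 3x3
same-padded convolutions (im2col), ReLU, 2x2 max pooling, global average
pooling, dense layers, a softmax cross-entropy loss and an Adam optimizer
with the legacy additive inverse-time learning-rate decay
``lr_t = lr / (1 + decay * t)``.  Everything runs on CPU (float32 by
default, float64 selectable per layer) and is bit-reproducible for a
fixed seed.

Layers store parameters in ``.params`` / gradients in ``.grads`` (dicts of
arrays updated in place).  :class:`Sequential` chains named layers and can
capture intermediate activations by name, which is how the saliency stage
reads convolutional activation maps.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}  # non-trainable buffers
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches with same zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


class Conv2D(Layer):
    """3x3 (configurable) same convolution, stride 1, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.k = k
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in)).astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(self.params["w"].dtype, copy=False)
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        self._cols, self._shape = cols, x.shape
        out = cols @ self.params["w"].T + self.params["b"]
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad.astype(self.params["w"].dtype, copy=False)
        n, _, h, w = self._shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        cols2 = self._cols.reshape(n * h * w, -1)
        self.grads["w"][...] = g.T @ cols2
        self.grads["b"][...] = g.sum(axis=0)
        # dx = same-conv of grad with spatially flipped, channel-swapped kernel
        wk = self.params["w"].reshape(self.out_ch, self.in_ch, self.k, self.k)
        wk = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.in_ch, -1)
        gcols = _im2col(grad.reshape(n, self.out_ch, h, w), self.k)
        dx = gcols @ wk.T
        return dx.reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)


class Center(Layer):
    """Subtract a fixed offset (input centering; gradient is identity)."""

    def __init__(self, offset: float = 0.5):
        super().__init__()
        self.offset = offset

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x - self.offset

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class Standardize(Layer):
    """Per-sample zero-mean/unit-variance input scaling.

    Used as the first layer only (input preprocessing): the backward pass
    treats the per-sample statistics as constants, which is exact for the
    parameters above it because no trainable parameters sit below.
    """

    def __init__(self, eps: float = 1e-6):
        super().__init__()
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(1, x.ndim))
        m = x.mean(axis=axes, keepdims=True)
        s = x.std(axis=axes, keepdims=True)
        self._s = s
        return (x - m) / (s + self.eps)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad / (self._s + self.eps)


class BatchNorm2D(Layer):
    """Per-channel batch normalization for (N, C, H, W) activations.

    Batch statistics during training (with running-average tracking,
    momentum 0.9); running statistics at inference.  Stabilizes the early
    optimization of small conv nets, whose plain ReLU/GAP training
    otherwise sits on a long chance-level plateau.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.state["running_mean"] = np.zeros(channels, dtype=dtype)
        self.state["running_var"] = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.state["running_mean"][...] = (m * self.state["running_mean"]
                                               + (1 - m) * mu)
            self.state["running_var"][...] = (m * self.state["running_var"]
                                              + (1 - m) * var)
            self._x = x
            self._mu = mu[None, :, None, None]
            self._istd = 1.0 / np.sqrt(var[None, :, None, None] + self.eps)
            self._xhat = (x - self._mu) * self._istd
            return g * self._xhat + b
        mu = self.state["running_mean"][None, :, None, None]
        var = self.state["running_var"][None, :, None, None]
        return g * (x - mu) / np.sqrt(var + self.eps) + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        m = n * h * w
        self.grads["gamma"][...] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.params["gamma"][None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return self._istd / m * (m * dxhat - s1 - self._xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; input H, W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._idx[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), (n, c, h, w)).copy()


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / in_dim), (out_dim, in_dim)).astype(dtype)
        self.params["b"] = np.zeros(out_dim, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(self.params["w"].dtype, copy=False)
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad.astype(self.params["w"].dtype, copy=False)
        self.grads["w"][...] = grad.T @ self._x
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.params["w"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean two-class cross-entropy (== binary cross-entropy) and dLoss/dlogits."""
    probs = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), y] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Sequential:
    """Named layer chain with activation capture and weight snapshots."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers
        self._names = [n for n, _ in layers]

    def forward(self, x: np.ndarray,
                capture: Iterable[str] = ()) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        capture = set(capture)
        unknown = capture - set(self._names)
        if unknown:
            raise KeyError(f"unknown layer(s) {sorted(unknown)}; have {self._names}")
        captured: dict[str, np.ndarray] = {}
        for name, layer in self.layers:
            x = layer.forward(x)
            if name in capture:
                captured[name] = x
        return x, captured

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.forward(x)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [softmax(self.predict_logits(x[i:i + batch_size]))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(layer.params[k], layer.grads[k])
                for _, layer in self.layers for k in sorted(layer.params)]

    def train_mode(self, flag: bool) -> None:
        for _, layer in self.layers:
            layer.training = flag

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for _, layer in self.layers:
            out += [layer.params[k].copy() for k in sorted(layer.params)]
            out += [layer.state[k].copy() for k in sorted(layer.state)]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for _, layer in self.layers:
            for k in sorted(layer.params):
                layer.params[k][...] = weights[i]
                i += 1
            for k in sorted(layer.state):
                layer.state[k][...] = weights[i]
                i += 1

    @property
    def layer_names(self) -> list[str]:
        return list(self._names)


class Adam:
    """Adam with optional legacy inverse-time lr decay or L2 weight decay.

    ``decay_mode="lr"`` applies ``lr_t = lr / (1 + decay * t)`` per update
    step; ``decay_mode="weight"`` instead adds ``decay * w`` to the gradient.
    """

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, decay: float = 0.0, decay_mode: str = "lr",
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if decay_mode not in ("lr", "weight"):
            raise ValueError("decay_mode must be 'lr' or 'weight'")
        self.params = params
        self.lr, self.decay, self.decay_mode = lr, decay, decay_mode
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        lr = self.lr
        if self.decay_mode == "lr":
            lr = self.lr / (1.0 + self.decay * self.t)
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            if self.decay_mode == "weight" and self.decay:
                g = g + self.decay * p
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def save_weights(path, model: Sequential, header: dict) -> None:
    """Write weights plus a JSON header into a single .npz checkpoint."""
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    arrays["header_json"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[dict, list[np.ndarray]]:
    with np.load(path) as data:
        header = json.loads(bytes(data["header_json"]).decode("utf-8"))
        n = sum(1 for k in data.files if k.startswith("w") and k != "header_json")
        weights = [data[f"w{i}"] for i in range(n)]
    return header, weights
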