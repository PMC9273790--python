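"""Small convolutional network for deep-feature extraction from stacked TFMs.

Architecture: two or three blocks of [3x3 conv (same padding) -> batch
normalization -> ReLU -> 2x2 max pool, stride 2] with 8, 16 (and 32)
filters, followed by flatten and a 2-unit softmax head.  The classifier
head only drives training; the *features* handed to dimensionality
reduction are the flattened activations of the last pooling layer
(channel-major), 16 * 55 * 55 = 48,400 values for the two-layer network
at a 220 x 220 input.

The network is implemented directly on numpy (im2col + BLAS matmul for
the convolutions) with Adam and cross-entropy; everything is seeded, so
training is bit-reproducible at a fixed thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError
from .stockwell import StackedTFM

__all__ = ["CNNConfig", "FeatureVector", "CNNModel", "build_cnn", "train_cnn", "extract_features"]

_F32 = np.float32


@dataclass(frozen=True)
class CNNConfig:
    n_conv_layers: int = 2
    input_size: int = 220
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    #: filter counts per layer follow the fixed (8, 16, 32) prefix
    @property
    def filters(self) -> tuple[int, ...]:
        return (8, 16, 32)[: self.n_conv_layers]

    def __post_init__(self) -> None:
        if self.n_conv_layers not in (2, 3):
            raise ParameterError(f"n_conv_layers must be 2 or 3, got {self.n_conv_layers}")
        if self.input_size < 2**self.n_conv_layers:
            raise ParameterError("input_size too small for the pooling stack")

    @property
    def feature_dim(self) -> int:
        """Flattened size after the last pooling (floor division per pool)."""
        size = self.input_size
        for _ in range(self.n_conv_layers):
            size //= 2
        return self.filters[-1] * size * size


@dataclass
class FeatureVector:
    values: np.ndarray

    @property
    def dim(self) -> int:
        return self.values.size


# ---------------------------------------------------------------- layers


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*9) patches of the 1-padded input."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (B, C, H, W, 3, 3) -> (B, H, W, C, 3, 3)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(b * h * w, c * 9)


class _Conv3x3:
    """Same-padding 3x3 convolution; weights He-initialized, biases zero."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_out, c_in * 9)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col3(x)
        out = (cols @ self.W.T + self.b).reshape(b, h, w, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (b, c, h, w) = self._cache
        dm = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(b * h * w, -1)
        self.dW = dm.T @ cols
        self.db = dm.sum(axis=0)
        dcols = (dm @ self.W).reshape(b, h, w, c, 3, 3)
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=_F32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [("W", self.W), ("b", self.b)]


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        sh = (1, -1, 1, 1)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        if train:
            self._cache = (xhat, inv)
        return self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        sh = (1, -1, 1, 1)
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.reshape(sh)
        return (
            inv.reshape(sh)
            / n
            * (
                n * dxhat
                - self.dbeta.reshape(sh)
                - xhat * self.dgamma.reshape(sh)
            )
        ).astype(_F32)

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class _MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        r = x[:, :, : h2 * 2, : w2 * 2].reshape(b, c, h2, 2, w2, 2)
        r = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 3, 5)).reshape(b, c, h2, w2, 4)
        if train:
            self._idx = r.argmax(axis=-1)
            self._shape = (b, c, h, w)
        return r.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dr = np.zeros((b, c, h2, w2, 4), dtype=_F32)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None].astype(_F32), axis=-1)
        dx = np.zeros((b, c, h, w), dtype=_F32)
        dr = dr.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h2 * 2, w2 * 2
        )
        dx[:, :, : h2 * 2, : w2 * 2] = dr
        return dx

    def params(self):
        return []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_out, d_in)) * scale).astype(_F32)
        self.b = np.zeros(d_out, dtype=_F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [("W", self.W), ("b", self.b)]


# ---------------------------------------------------------------- model


class CNNModel:
    """Conv stack + softmax head; see module docstring for the layout."""

    def __init__(self, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks = []
        c_in = 1
        for c_out in config.filters:
            self.blocks.append(
                {
                    "conv": _Conv3x3(c_in, c_out, rng),
                    "bn": _BatchNorm(c_out),
                    "relu": _ReLU(),
                    "pool": _MaxPool2(),
                }
            )
            c_in = c_out
        self.head = _Dense(config.feature_dim, 2, rng)
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward passes

    def _conv_forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for blk in self.blocks:
            x = blk["conv"].forward(x, train)
            x = blk["bn"].forward(x, train)
            x = blk["relu"].forward(x, train)
            x = blk["pool"].forward(x, train)
        return x

    def features(self, images: np.ndarray) -> np.ndarray:
        """Flattened last-pooling activations (channel-major), inference mode."""
        x = self._as_batch(images)
        out = self._conv_forward(x, train=False)
        return out.reshape(out.shape[0], -1).astype(np.float64)

    def logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._as_batch(images)
        out = self._conv_forward(x, train)
        return self.head.forward(out.reshape(out.shape[0], -1), train)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.logits(images).argmax(axis=1)

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=_F32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise DataError(
                f"expected {self.config.input_size}x{self.config.input_size} images, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        return x

    # -- training

    def _layers(self):
        for blk in self.blocks:
            yield from (blk["conv"], blk["bn"], blk["relu"], blk["pool"])
        yield self.head

    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for layer in self._layers():
            for name, p in layer.params():
                g = getattr(layer, "d" + name)
                key = (id(layer), name)
                if key not in self._adam_state:
                    self._adam_state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self._adam_state[key]
                m += (1 - beta1) * (g - m)
                v += (1 - beta2) * (g * g - v)
                mh = m / (1 - beta1**t)
                vh = v / (1 - beta2**t)
                p -= (lr * mh / (np.sqrt(vh) + eps)).astype(p.dtype)

    def train_batch(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One optimizer step on a batch; returns the mean cross-entropy."""
        logits = self.logits(x, train=True)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        n = len(y)
        loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
        dlogits = p
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dflat = self.head.backward(dlogits.astype(_F32))
        b = len(y)
        c = self.config.filters[-1]
        side = self.config.input_size
        for _ in range(self.config.n_conv_layers):
            side //= 2
        dout = dflat.reshape(b, c, side, side)
        for blk in reversed(self.blocks):
            dout = blk["pool"].backward(dout)
            dout = blk["relu"].backward(dout)
            dout = blk["bn"].backward(dout)
            dout = blk["conv"].backward(dout)
        self._adam_step(lr)
        return loss


def build_cnn(config: CNNConfig) -> CNNModel:
    """Construct the network with seed-controlled initial weights."""
    return CNNModel(config)


def train_cnn(
    model: CNNModel,
    images: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig | None = None,
) -> tuple[CNNModel, list[float]]:
    """Train with Adam on cross-entropy; returns (model, per-epoch loss).

    ``epochs == 0`` returns the initialized model and an empty history.
    """
    config = config or model.config
    labels = np.asarray(labels)
    images = np.asarray(images, dtype=_F32)
    if images.ndim == 3:
        images = images[:, None]
    if len(images) != len(labels):
        raise DataError("images and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise DataError("training requires examples from both classes")
    rng = np.random.default_rng(config.seed + 1)
    history: list[float] = []
    n = len(labels)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            losses.append(model.train_batch(images[idx], labels[idx], config.learning_rate))
        history.append(float(np.mean(losses)))
    return model, history


def extract_features(model: CNNModel, stacked: StackedTFM | np.ndarray) -> FeatureVector:
    """Deep features of one stacked TFM: last-pooling activations, flattened."""
    img = stacked.image if isinstance(stacked, StackedTFM) else np.asarray(stacked)
    return FeatureVector(values=model.features(img)[0])
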