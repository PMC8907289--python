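"""Minimal NumPy engine for the dual-path 3-D CNN.

Implements exactly the layer set the architecture needs — 3x3x3 same-padding
convolution, ReLU, inverted dropout, 2x2x2 max-pooling, flatten/concat, dense,
softmax cross-entropy — with hand-written backward passes and Adam.  Arrays
are float32 throughout; convolutions use an im2col / GEMM formulation.

Weighted layers are initialized with a Glorot normal scheme: draws from a
standard normal truncated at +/-2 SD, rescaled so the *realized* standard
deviation equals sqrt(2 / (fan_in + fan_out)).  Truncation at +/-2 shrinks the
variance of a unit normal by the factor

    1 - 2 a phi(a) / (Phi(a) - Phi(-a)),  a = 2

i.e. the raw truncated draw has SD ~0.8796; we divide by that constant so the
sample SD matches the nominal Glorot value.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TRUNC_BOUND",
    "TRUNC_STD_FACTOR",
    "glorot_std",
    "truncated_normal",
    "Conv3D",
    "ReLU",
    "Dropout",
    "MaxPool3D",
    "Dense",
    "softmax",
    "cross_entropy",
    "DualPathNet",
    "AdamOptimizer",
]

TRUNC_BOUND = 2.0
# variance shrinkage of a unit normal truncated to [-2, 2]
_phi = math.exp(-0.5 * TRUNC_BOUND**2) / math.sqrt(2 * math.pi)
_mass = math.erf(TRUNC_BOUND / math.sqrt(2.0))
TRUNC_STD_FACTOR = math.sqrt(1.0 - 2.0 * TRUNC_BOUND * _phi / _mass)


def glorot_std(fan_in: int, fan_out: int) -> float:
    """sqrt(2 / (fan_in + fan_out)); fans must be positive."""
    if fan_in <= 0 or fan_out <= 0:
        raise ValueError(f"fans must be positive, got ({fan_in}, {fan_out})")
    return math.sqrt(2.0 / (fan_in + fan_out))


def truncated_normal(shape, std: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-centred truncated normal (+/-2 SD) whose realized SD equals ``std``."""
    out = rng.standard_normal(shape)
    bad = np.abs(out) > TRUNC_BOUND
    while bad.any():
        out[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(out) > TRUNC_BOUND
    return (out * (std / TRUNC_STD_FACTOR)).astype(np.float32)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, D, H, W) -> (N*D*H*W, C*27) patches for a 3x3x3 same-pad conv."""
    n, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))  # (N,C,D,H,W,3,3,3)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, c * 27)
    return np.ascontiguousarray(cols, dtype=np.float32)


class Conv3D:
    """3x3x3 convolution, stride 1, same padding."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.fan_in = in_channels * 27
        self.fan_out = out_channels * 27
        std = glorot_std(self.fan_in, self.fan_out)
        self.weight = truncated_normal((out_channels, in_channels * 27), std, rng)
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._in_spatial: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"conv expected {self.in_channels} channels, got {c}")
        cols = _im2col(x)
        out = cols @ self.weight.T + self.bias
        if training:
            self._cols = cols
            self._in_spatial = (n, d, h, w)
        return out.reshape(n, d, h, w, self.out_channels).transpose(0, 4, 1, 2, 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._in_spatial is not None
        n, d, h, w = self._in_spatial
        dy_mat = dy.transpose(0, 2, 3, 4, 1).reshape(n * d * h * w, self.out_channels)
        dy_mat = np.ascontiguousarray(dy_mat, dtype=np.float32)
        self.dweight = dy_mat.T @ self._cols
        self.dbias = dy_mat.sum(axis=0)
        # dx: correlate dy with the spatially flipped, channel-transposed kernel
        w_t = (
            self.weight.reshape(self.out_channels, self.in_channels, 3, 3, 3)[
                :, :, ::-1, ::-1, ::-1
            ]
            .transpose(1, 0, 2, 3, 4)
            .reshape(self.in_channels, self.out_channels * 27)
        )
        dy_cols = _im2col(dy)
        dx = dy_cols @ np.ascontiguousarray(w_t).T
        self._cols = None
        return dx.reshape(n, d, h, w, self.in_channels).transpose(0, 4, 1, 2, 3)

    def parameters(self):
        yield "weight", self
        yield "bias", self


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, training):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dy):
        return dy * self._mask


class Dropout:
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None
        self.rng: np.random.Generator | None = None

    def forward(self, x, training):
        if not training or self.rate == 0:
            return x
        assert self.rng is not None, "training forward requires an rng"
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class MaxPool3D:
    """2x2x2 max pooling, stride 2."""

    def __init__(self):
        self._argmax = None
        self._in_shape = None

    def forward(self, x, training):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"pooling requires even spatial dims, got {(d, h, w)}")
        blocks = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // 2, h // 2, w // 2, 8
        )
        if training:
            self._argmax = blocks.argmax(axis=-1)
            self._in_shape = (n, c, d, h, w)
        return blocks.max(axis=-1)

    def backward(self, dy):
        n, c, d, h, w = self._in_shape
        out = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(out, self._argmax[..., None], dy[..., None], axis=-1)
        out = out.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return out.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)


class Dense:
    def __init__(self, in_width: int, out_width: int, rng: np.random.Generator):
        self.fan_in, self.fan_out = in_width, out_width
        std = glorot_std(in_width, out_width)
        self.weight = truncated_normal((in_width, out_width), std, rng)
        self.bias = np.zeros(out_width, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._x = None

    def forward(self, x, training):
        if training:
            self._x = x
        return x @ self.weight + self.bias

    def backward(self, dy):
        self.dweight = self._x.T @ dy
        self.dbias = dy.sum(axis=0)
        return dy @ self.weight.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


class _Encoder:
    """One encoding path: (conv-relu-dropout-conv-relu-pool) x levels."""

    def __init__(self, in_channels: int, filters: list[int], dropout_rate: float, rng):
        self.layers: list = []
        c = in_channels
        for f in filters:
            self.layers += [
                Conv3D(c, f, rng),
                ReLU(),
                Dropout(dropout_rate),
                Conv3D(f, f, rng),
                ReLU(),
                MaxPool3D(),
            ]
            c = f
        self.out_channels = c

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class DualPathNet:
    """The full classifier: one or two encoders, flatten/concat, FC head.

    ``model_state`` throughout the package is simply an instance of this class.
    Construction consumes the given generator for weight init; a separate
    generator (seeded per training run) drives dropout masks.
    """

    def __init__(
        self,
        mode: str,
        in_channels_per_path: list[int],
        filters_per_path: list[list[int]],
        fc_widths: tuple[int, ...],
        dropout_rate: float,
        input_shape: tuple[int, int, int],
        rng: np.random.Generator,
    ):
        if mode not in ("dual_path", "single_path"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.input_shape = tuple(input_shape)
        self.encoders = [
            _Encoder(c, f, dropout_rate, rng)
            for c, f in zip(in_channels_per_path, filters_per_path)
        ]
        levels = len(filters_per_path[0])
        reduced = tuple(s // (2**levels) for s in input_shape)
        if min(reduced) < 1:
            raise ValueError("encoder pools the volume below one voxel")
        self._reduced = reduced
        feat = int(np.prod(reduced)) * sum(e.out_channels for e in self.encoders)
        self.feature_length = feat
        self.head: list = []
        widths = (feat, *fc_widths)
        for i in range(len(fc_widths)):
            self.head.append(Dense(widths[i], widths[i + 1], rng))
            if i < len(fc_widths) - 1:
                self.head.append(Dropout(dropout_rate))
        self._split_sizes = [
            int(np.prod(reduced)) * e.out_channels for e in self.encoders
        ]

    # -- plumbing -----------------------------------------------------------
    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self._all_layers():
            if isinstance(layer, Dropout):
                layer.rng = rng

    def _all_layers(self):
        for enc in self.encoders:
            yield from enc.layers
        yield from self.head

    def parameters(self):
        """Yield (name, layer) for every weighted layer."""
        idx = 0
        for layer in self._all_layers():
            if isinstance(layer, (Conv3D, Dense)):
                yield f"layer{idx}", layer
                idx += 1

    def state_copy(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {
            name: (layer.weight.copy(), layer.bias.copy())
            for name, layer in self.parameters()
        }

    def load_state(self, state) -> None:
        for name, layer in self.parameters():
            w, b = state[name]
            layer.weight[...] = w
            layer.bias[...] = b

    def n_parameters(self) -> int:
        return sum(l.weight.size + l.bias.size for _, l in self.parameters())

    # -- forward / backward -------------------------------------------------
    def _split_input(self, x: np.ndarray) -> list[np.ndarray]:
        if self.mode == "dual_path":
            return [x[:, 0:1], x[:, 1:2]]
        return [x]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch ``x`` of shape (N, C, D, H, W)."""
        if tuple(x.shape[2:]) != self.input_shape:
            raise ValueError(
                f"input spatial shape {x.shape[2:]} != configured {self.input_shape}"
            )
        x = np.ascontiguousarray(x, dtype=np.float32)
        feats = [
            enc.forward(part, training)
            for enc, part in zip(self.encoders, self._split_input(x))
        ]
        n = x.shape[0]
        flat = np.concatenate([f.reshape(n, -1) for f in feats], axis=1)
        self._feat_shapes = [f.shape for f in feats]
        out = flat
        for layer in self.head:
            out = layer.forward(out, training)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits
        for layer in reversed(self.head):
            dy = layer.backward(dy)
        offset = 0
        for enc, size, shape in zip(self.encoders, self._split_sizes, self._feat_shapes):
            part = dy[:, offset : offset + size].reshape(shape)
            enc.backward(np.ascontiguousarray(part))
            offset += size

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def loss_and_grad(self, x: np.ndarray, labels: np.ndarray) -> float:
        """Cross-entropy on a batch; leaves gradients in the layers."""
        logits = self.forward(x, training=True)
        probs = softmax(logits)
        loss = cross_entropy(probs, labels)
        n = len(labels)
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        self.backward((dlogits / n).astype(np.float32))
        return loss


class AdamOptimizer:
    def __init__(self, model: DualPathNet, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.model = model
        for name, layer in model.parameters():
            for p in ("weight", "bias"):
                arr = getattr(layer, p)
                self.m[f"{name}.{p}"] = np.zeros_like(arr)
                self.v[f"{name}.{p}"] = np.zeros_like(arr)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for name, layer in self.model.parameters():
            for p in ("weight", "bias"):
                g = getattr(layer, "d" + p)
                key = f"{name}.{p}"
                self.m[key] = b1 * self.m[key] + (1 - b1) * g
                self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
                mhat = self.m[key] / bias1
                vhat = self.v[key] / bias2
                getattr(layer, p)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
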