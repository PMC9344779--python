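"""Minimal NumPy neural-network engine: the layers the patch classifier needs.

Implements exactly the building blocks of the classifier — convolution,
max-pooling, ReLU/sigmoid activations, dropout, affine (fully-connected)
layers, a softmax output with categorical cross-entropy, and the Adam
update rule.  Convolutions use im2col so all heavy lifting is one matmul.
Everything is float32, NCHW, and deterministic under a seeded Generator.
"""

from __future__ import annotations

import numpy as np


def im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for a stride-1, 'same' conv."""
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(N, C, H, W, k, k),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]), writeable=False)
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k)


def col2im(cols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col` (scatter-add of patch gradients)."""
    N, C, H, W = shape
    xp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(N, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + H, j:j + W] += cols[:, :, :, :, i, j]
    return xp[:, :, pad:pad + H, pad:pad + W]


class Layer:
    counted = True  # contributes to the architecture's layer count
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 stride-1 'same' convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, gain: float = 2.0) -> None:
        super().__init__()
        self.k, self.pad = k, k // 2
        scale = np.sqrt(gain / (c_in * k * k))
        self.W = (rng.standard_normal((c_in * k * k, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self.x_shape = x.shape
        N, C, H, W = x.shape
        self.cols = im2col(x, self.k, self.pad)
        out = self.cols @ self.W + self.b
        return out.reshape(N, H, W, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        N, C, H, W = self.x_shape
        d = dout.transpose(0, 2, 3, 1).reshape(-1, self.W.shape[1])
        self.grads[0][...] = self.cols.T @ d
        self.grads[1][...] = d.sum(axis=0)
        return col2im(d @ self.W.T, self.x_shape, self.k, self.pad)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input H, W assumed even)."""

    def forward(self, x, train):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        self.mask = xr == out[:, :, :, None, :, None]
        # break ties so the gradient routes to a single argmax per cell
        flat = self.mask.reshape(N, C, H // 2, W // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self.mask = (flat & first).reshape(self.mask.shape)
        return out

    def backward(self, dout):
        d = dout[:, :, :, None, :, None] * self.mask
        N, C, Hh, _, Wh, _ = d.shape
        return d.reshape(N, C, Hh * 2, Wh * 2)


class ReLU(Layer):
    def forward(self, x, train):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


class Sigmoid(Layer):
    def forward(self, x, train):
        self.out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self.out

    def backward(self, dout):
        return dout * self.out * (1.0 - self.out)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self.mask

    def backward(self, dout):
        return dout if self.mask is None else dout * self.mask


class Flatten(Layer):
    counted = False  # pure reshape, not a layer of the architecture

    def forward(self, x, train):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.shape)


class Affine(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = 2.0) -> None:
        super().__init__()
        scale = np.sqrt(gain / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self.x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Softmax(Layer):
    """Output softmax; gradient is handled jointly with cross-entropy."""

    def forward(self, x, train):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self.out = e / e.sum(axis=1, keepdims=True)
        return self.out

    def backward(self, dout):  # dout is already (p - y)/N from the loss
        return dout


def softmax_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                          eps: float = 1e-12) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and the gradient w.r.t. the logits.

    ``probs`` are softmax outputs, ``labels`` integer class ids.  The
    returned gradient (p - onehot)/N feeds :meth:`Softmax.backward`.
    """
    n = probs.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + eps).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam update rule (decoupled per-parameter first/second moments)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
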