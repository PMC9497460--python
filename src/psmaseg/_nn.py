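"""Minimal numpy neural-network engine for the 3D voxel classifier.

Implements exactly what the encoder-decoder segmentation network needs:
3D "same" convolutions with hand-derived backprop (im2col + matmul),
2x2x2 max pooling, nearest-neighbour upsampling, inverted dropout, softmax,
and the Nadam optimiser (Adam with Nesterov momentum). Arrays are
channel-first ``(N, C, D, H, W)``.

Backprop through a same-padded cross-correlation uses the standard
identity: the input gradient is the same-padded cross-correlation of the
output gradient with the spatially flipped, channel-transposed kernel
(exact for odd kernel sizes).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_same(x: np.ndarray, W: np.ndarray, b: np.ndarray | float,
               return_cols: bool = False):
    """Same-padded cross-correlation; x (N,C,D,H,W), W (F,C,k,k,k)."""
    F, C, k = W.shape[0], W.shape[1], W.shape[2]
    N, _, D, H, Wd = x.shape
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(N * D * H * Wd, C * k**3)
    y = cols @ W.reshape(F, C * k**3).T
    if not np.isscalar(b):
        y += b
    y = y.reshape(N, D, H, Wd, F).transpose(0, 4, 1, 2, 3)
    if return_cols:
        return np.ascontiguousarray(y), cols
    return np.ascontiguousarray(y)


class Conv3D:
    """Same-padded 3D convolution layer (odd kernel), He-initialised."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3,
                 dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        scale = np.sqrt(2.0 / (cin * k**3))
        self.W = rng.normal(0.0, scale, size=(cout, cin, k, k, k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(self.W.dtype, copy=False)
        y, self._cols = _conv_same(x, self.W, self.b, return_cols=True)
        self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        F = self.W.shape[0]
        k = self.W.shape[2]
        N, _, D, H, Wd = self._in_shape
        dym = dy.transpose(0, 2, 3, 4, 1).reshape(N * D * H * Wd, F)
        self.dW[...] = (dym.T @ self._cols).reshape(self.W.shape)
        self.db[...] = dym.sum(axis=0)
        Wt = self.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        dx = _conv_same(dy.astype(self.W.dtype, copy=False), np.ascontiguousarray(Wt), 0.0)
        self._cols = None
        return dx

    def astype(self, dtype) -> None:
        self.W = self.W.astype(dtype)
        self.b = self.b.astype(dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy, mask):
    return dy * mask


def maxpool2_forward(x):
    N, C, D, H, W = x.shape
    xr = x.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
    y = xr.max(axis=(3, 5, 7))
    yexp = y[:, :, :, None, :, None, :, None]
    mask = xr == yexp
    # distribute gradient equally among (rare) ties
    ties = mask.sum(axis=(3, 5, 7))[:, :, :, None, :, None, :, None]
    return y, (mask, ties, x.shape)


def maxpool2_backward(dy, cache):
    mask, ties, in_shape = cache
    dyexp = dy[:, :, :, None, :, None, :, None]
    dxr = mask * (dyexp / ties)
    return dxr.reshape(in_shape)


def upsample2_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)


def upsample2_backward(dy):
    N, C, D, H, W = dy.shape
    return dy.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(3, 5, 7))


def dropout_forward(x, rate: float, rng: np.random.Generator):
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    keep = keep.astype(x.dtype)
    return x * keep, keep


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Nadam:
    """Adam with Nesterov momentum (Nadam), per Dozat's formulation."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params_and_grads: list[tuple[np.ndarray, np.ndarray]],
             lr: float) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in params_and_grads]
            self._v = [np.zeros_like(p) for p, _ in params_and_grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, (p, g) in enumerate(params_and_grads):
            m, v = self._m[i], self._v[i]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / bc1
            v_hat = v / bc2
            nesterov = b1 * m_hat + (1 - b1) * g / bc1
            p -= lr * nesterov / (np.sqrt(v_hat) + self.eps)
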