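"""Minimal NumPy convolution-network engine for desk-scale segmentation nets.

Implements exactly the pieces the segmentation U-Nets need — 3x3/1x1
convolutions (im2col + BLAS matmul), batch normalisation, ReLU, 2x2 max
pooling, exact separable bilinear 2x up-sampling with its adjoint, softmax
cross-entropy with per-pixel loss weights, and Adam — each with a hand-written
backward pass.  Arrays are NCHW ``float32``; batch size follows the training
protocol (1).  Everything is deterministic given the initialisation seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "Upsample2xBilinear",
    "softmax",
    "weighted_cross_entropy",
    "Adam",
]

_F = np.float32


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_F)


class Layer:
    """Base: trainable layers expose ``params()`` as a list of (value, grad)
    pairs updated in place by the optimiser."""

    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k same-padded convolution (k odd) via im2col."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.w = _he_init(rng, (out_ch, in_ch * k * k), in_ch * k * k)
        self.b = np.zeros(out_ch, dtype=_F)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _im2col(self, x):
        n, c, h, w = x.shape
        p = self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))  # n,c,h,w,k,k
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * self.k * self.k)

    def forward(self, x, train=True):
        n, _, h, w = x.shape
        col = self._im2col(x)
        if train:
            self._col, self._xshape = col, x.shape
        y = col @ self.w.T + self.b
        return y.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, _, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, h * w, self.out_ch)
        self.dw += np.einsum("npo,npc->oc", dyf, self._col, optimize=True)
        self.db += dyf.sum(axis=(0, 1))
        dcol = dyf @ self.w  # n, h*w, c*k*k
        c = self._xshape[1]
        p = self.k // 2
        dcol = dcol.reshape(n, h, w, c, self.k, self.k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=_F)
        self.beta = np.zeros(ch, dtype=_F)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(ch, dtype=_F)
        self.run_var = np.ones(ch, dtype=_F)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dy):
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma += np.sum(dy * self._xhat, axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[:, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (self._inv[:, None, None] / m) * (m * dxhat - s1 - self._xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == y[:, :, :, None, :, None]
            self._shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        dyr = dy[:, :, :, None, :, None] * self._mask
        return dyr.reshape(n, c, h, w)


def _up_matrix(n: int) -> sparse.csr_matrix:
    """Sparse (2n, n) separable bilinear x2 up-sampling operator
    (half-pixel-centre convention; edge rows clamp)."""
    rows, cols, vals = [], [], []
    for i in range(2 * n):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        for j, v in ((lo, 1 - frac), (lo + 1, frac)):
            j = min(max(j, 0), n - 1)
            if v > 0:
                rows.append(i)
                cols.append(j)
                vals.append(v)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(2 * n, n), dtype=_F)


class Upsample2xBilinear(Layer):
    """Exact separable bilinear 2x up-sampling; backward is the transpose."""

    _cache: dict[int, sparse.csr_matrix] = {}

    @classmethod
    def _mat(cls, n: int) -> sparse.csr_matrix:
        if n not in cls._cache:
            cls._cache[n] = _up_matrix(n)
        return cls._cache[n]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._hw = (h, w)
        mh, mw = self._mat(h), self._mat(w)
        y = mh @ x.transpose(2, 0, 1, 3).reshape(h, -1)
        y = y.reshape(2 * h, n, c, w).transpose(1, 2, 0, 3)
        y = (mw @ y.transpose(3, 0, 1, 2).reshape(w, -1)).reshape(2 * w, n, c, 2 * h)
        return np.ascontiguousarray(y.transpose(1, 2, 3, 0))

    def backward(self, dy):
        h, w = self._hw
        n, c = dy.shape[:2]
        mh, mw = self._mat(h), self._mat(w)
        g = mw.T @ dy.transpose(3, 0, 1, 2).reshape(2 * w, -1)
        g = g.reshape(w, n, c, 2 * h).transpose(1, 2, 3, 0)
        g = (mh.T @ g.transpose(2, 0, 1, 3).reshape(2 * h, -1)).reshape(h, n, c, w)
        return np.ascontiguousarray(g.transpose(1, 2, 0, 3))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Per-pixel weighted softmax cross-entropy over 2 classes.

    ``logits`` is (N, 2, H, W), ``labels`` a (N, H, W) binary array (1 =
    epithelium), ``weights`` (N, H, W) with mean 1.  Returns the scalar loss
    and the gradient with respect to the logits.
    """
    p = softmax(logits)
    n, _, h, w = logits.shape
    labels = labels.astype(int)
    if weights is None:
        weights = np.ones((n, h, w), dtype=_F)
    idx_n, idx_r, idx_c = np.meshgrid(
        np.arange(n), np.arange(h), np.arange(w), indexing="ij"
    )
    p_true = p[idx_n, labels, idx_r, idx_c]
    loss = float(np.mean(weights * -np.log(np.maximum(p_true, 1e-12))))
    onehot = np.zeros_like(p)
    onehot[idx_n, labels, idx_r, idx_c] = 1.0
    dlogits = (p - onehot) * weights[:, None, :, :] / (n * h * w)
    return loss, dlogits.astype(_F)


class Adam:
    """Adam with the training protocol's defaults (beta1 = beta2 = 0.99)."""

    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.99,
                 beta2: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
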