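"""Minimal 3-D convolutional-network layers with reverse-mode gradients.

Implemented directly on numpy: 3-D convolution (stride 1, zero-padded,
as one BLAS contraction per kernel offset over shifted views), batch
normalization, ReLU, 2x2x2 max-pooling, 2x2x2 stride-2 transposed
convolution, softmax cross-entropy, and the Adam optimizer with Xavier
(Glorot-uniform) weight initialization.

Design notes
------------
* Activations are ``(N, C, D, H, W)`` float32 arrays.
* Each layer stores the cache of its last training-mode forward pass and
  consumes it in ``backward`` (single-threaded, one use per pass).
* The input gradient of a stride-1 zero-padded convolution is computed as
  another zero-padded convolution of the output gradient with the
  spatially flipped, channel-transposed kernel — reusing the fast
  forward path instead of a scatter-add.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


def xavier_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    if not p:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _conv_padded(xp: np.ndarray, weight: np.ndarray, out_shape) -> np.ndarray:
    """Correlate a pre-padded (N,C,D+2p,...) input with (C_out,C_in,k,k,k).

    One GEMM per kernel offset on a shifted view of the input — avoids the
    27-fold data blow-up of an im2col patch matrix.
    """
    n, _, d, h, w = out_shape
    co, _, k, _, _ = weight.shape
    dtype = np.result_type(xp, weight)
    acc = np.zeros((co, n * d * h * w), dtype=dtype)
    buf = np.empty((xp.shape[1], n * d * h * w), dtype=dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xs = xp[:, :, i : i + d, j : j + h, l : l + w]
                # contiguous (cin, n*dhw) copy of the shifted view, then GEMM
                np.copyto(buf, xs.transpose(1, 0, 2, 3, 4).reshape(buf.shape))
                acc += weight[:, :, i, j, l] @ buf
    y = acc.reshape(co, n, d, h, w)
    return np.ascontiguousarray(y.transpose(1, 0, 2, 3, 4))


def _conv_raw(x: np.ndarray, weight: np.ndarray, k: int) -> np.ndarray:
    """Stride-1 same-padding correlation; weight (C_out, C_in, k, k, k)."""
    return _conv_padded(_pad_same(x, k), weight, x.shape)


class Conv3d:
    """3-D convolution, odd kernel, stride 1, zero padded (shape preserving)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel must be odd for same-padding conv")
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(
            xavier_uniform(rng, (c_out, c_in, k, k, k), c_in * k**3, c_out * k**3)
        )
        self.bias = Param(np.zeros(c_out))
        self._xp: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        xp = _pad_same(x, self.k)
        y = _conv_padded(xp, self.weight.data, x.shape)
        y += self.bias.data.reshape(1, -1, 1, 1, 1)
        if train:
            self._xp = xp
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xp is not None
        xp, k = self._xp, self.k
        self._xp = None
        n, _, d, h, w = self._in_shape
        dW = self.weight.grad
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i : i + d, j : j + h, l : l + w]
                    # contract over batch and space: (co, cin)
                    dW[:, :, i, j, l] += np.tensordot(
                        dy, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                    )
        self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        # grad wrt input: correlate dy with flipped, channel-swapped kernel
        w_flip = self.weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return _conv_raw(dy, np.ascontiguousarray(w_flip), k)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return dy * self._mask


class BatchNorm3d:
    """Per-channel batch normalization over (N, D, H, W).

    Training uses batch statistics and updates exponential running averages
    (momentum 0.1); inference uses the frozen running statistics.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv_std = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = dy.size / dy.shape[1]
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.data.reshape(shape)
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        ) * inv_std.reshape(shape)
        return dx.astype(np.float32)


class MaxPool3d:
    """2x2x2 max pooling, stride 2; gradient split equally among ties."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        x6 = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = x6.max(axis=(3, 5, 7))
        if train:
            self._cache = (x6, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x6, y = self._cache
        self._cache = None
        yb = y[:, :, :, None, :, None, :, None]
        mask = x6 == yb
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        dyb = dy[:, :, :, None, :, None, :, None] / counts
        dx6 = mask * dyb
        n, c, d2, _, h2, _, w2, _ = x6.shape
        return dx6.reshape(n, c, d2 * 2, h2 * 2, w2 * 2).astype(np.float32)


class ConvTranspose3d:
    """Transposed convolution with 2x2x2 kernel, stride 2 (edge doubling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(
            xavier_uniform(rng, (c_in, c_out, 2, 2, 2), c_in * 8, c_out * 8)
        )
        self.bias = Param(np.zeros(c_out))
        self._xm: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, ci, d, h, w = x.shape
        co = self.c_out
        # one GEMM: each input voxel produces its own 2x2x2 output block
        xm = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1)).reshape(-1, ci)
        ym = xm @ self.weight.data.reshape(ci, co * 8)
        if train:
            self._xm = xm
            self._in_shape = x.shape
        y8 = ym.reshape(n, d, h, w, co, 2, 2, 2)
        y = np.ascontiguousarray(y8.transpose(0, 4, 1, 5, 2, 6, 3, 7)).reshape(
            n, co, 2 * d, 2 * h, 2 * w
        )
        return y + self.bias.data.reshape(1, -1, 1, 1, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xm is not None
        xm = self._xm
        self._xm = None
        n, ci, d, h, w = self._in_shape
        co = self.c_out
        dy8 = dy.reshape(n, co, d, 2, h, 2, w, 2)
        dym = np.ascontiguousarray(dy8.transpose(0, 2, 4, 6, 1, 3, 5, 7)).reshape(
            -1, co * 8
        )
        self.weight.grad += (xm.T @ dym).reshape(self.weight.data.shape)
        self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        dxm = dym @ self.weight.data.reshape(ci, co * 8).T
        dx = dxm.reshape(n, d, h, w, ci).transpose(0, 4, 1, 2, 3)
        return np.ascontiguousarray(dx).astype(np.float32, copy=False)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean voxelwise multi-class cross-entropy and its logit gradient.

    ``logits``: (N, K, D, H, W); ``target``: (N, D, H, W) integer class
    indices.  No class or voxel weighting.
    """
    probs = softmax(logits, axis=1)
    n, k = logits.shape[:2]
    flat = probs.transpose(0, 2, 3, 4, 1).reshape(-1, k)
    tflat = target.reshape(-1)
    m = flat.shape[0]
    eps = 1e-12
    loss = float(-np.log(flat[np.arange(m), tflat] + eps).mean())
    dflat = flat
    dflat[np.arange(m), tflat] -= 1.0
    dflat /= m
    dlogits = dflat.reshape(logits.shape[0], *logits.shape[2:], k)
    return loss, np.ascontiguousarray(
        dlogits.transpose(0, 4, 1, 2, 3)
    ).astype(np.float32)


class Adam:
    """Adam with externally scheduled learning rate."""

    def __init__(
        self,
        params: list[Param],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
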