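"""Minimal neural-network layers with explicit forward/backward passes.

Implemented directly on numpy so the latent-representation branch trains on
any CPU-only host. Scope is exactly what the VAE-GAN needs: strided 4x4
convolutions and their transposes (stride 2, padding 1, i.e. exact 2x down-
and up-sampling), batch normalization, dense layers, ReLU/LeakyReLU/Sigmoid,
and Adam. Every primitive is validated against finite differences in the
test suite.

Layers cache the intermediates of their last forward call; call ``backward``
before the next ``forward`` whenever the input gradient matters.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

K = 4  # kernel size
S = 2  # stride
P = 1  # padding


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


# ---------------------------------------------------------------------------
# convolution primitives (kernel 4, stride 2, pad 1)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho*Wo, C*K*K) with Ho = H//2."""
    xp = np.pad(x, ((0, 0), (0, 0), (P, P), (P, P)))
    v = sliding_window_view(xp, (K, K), axis=(2, 3))[:, :, ::S, ::S]  # N,C,Ho,Wo,K,K
    n, c, ho, wo = v.shape[:4]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho * wo, c * K * K)


def _col2im(gcols: np.ndarray, xshape: tuple) -> np.ndarray:
    """Adjoint of _im2col: scatter-add (N, Ho*Wo, C*K*K) back to (N, C, H, W)."""
    n, c, h, w = xshape
    ho, wo = h // S, w // S
    g = gcols.reshape(n, ho, wo, c, K, K).transpose(0, 3, 1, 2, 4, 5)
    xp = np.zeros((n, c, h + 2 * P, w + 2 * P), dtype=gcols.dtype)
    for ki in range(K):
        for kj in range(K):
            xp[:, :, ki : ki + S * ho : S, kj : kj + S * wo : S] += g[:, :, :, :, ki, kj]
    return xp[:, :, P : P + h, P : P + w]


def conv_fwd(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlate x (N,C,H,W) with w (F,C,K,K); returns (y, cols cache)."""
    n, c, h, wid = x.shape
    f = w.shape[0]
    cols = _im2col(x)
    y = cols @ w.reshape(f, -1).T  # (N, Ho*Wo, F)
    return y.transpose(0, 2, 1).reshape(n, f, h // S, wid // S), cols


def conv_bwd_input(gy: np.ndarray, w: np.ndarray, xshape: tuple) -> np.ndarray:
    n, f, ho, wo = gy.shape
    gcols = gy.reshape(n, f, ho * wo).transpose(0, 2, 1) @ w.reshape(f, -1)
    return _col2im(gcols, xshape)


def conv_bwd_weight(cols: np.ndarray, gy: np.ndarray, wshape: tuple) -> np.ndarray:
    n, f, ho, wo = gy.shape
    gyf = gy.reshape(n, f, ho * wo)
    gw = np.einsum("npk,nfp->fk", cols, gyf)
    return gw.reshape(wshape)


class Conv2d:
    """4x4 stride-2 convolution halving the spatial size."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * K * K))
        self.w = Param(rng.normal(0, scale, size=(c_out, c_in, K, K)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._xshape = x.shape
        y, self._cols = conv_fwd(x, self.w.data)
        return y + self.b.data[None, :, None, None]

    def backward(self, gy):
        self.w.grad += conv_bwd_weight(self._cols, gy, self.w.data.shape)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        return conv_bwd_input(gy, self.w.data, self._xshape)


class ConvTranspose2d:
    """4x4 stride-2 transposed convolution doubling the spatial size.

    Forward is the adjoint of :class:`Conv2d`'s forward, so the weight is
    stored in conv layout ``(c_in, c_out, K, K)`` and reused through the
    same primitives with roles swapped.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * K * K))
        self.w = Param(rng.normal(0, scale, size=(c_in, c_out, K, K)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._x = x
        c_out = self.w.data.shape[1]
        self._yshape = (n, c_out, h * S, w * S)
        y = conv_bwd_input(x, self.w.data, self._yshape)
        return y + self.b.data[None, :, None, None]

    def backward(self, gy):
        gy_cols = _im2col(gy)
        # weight grad: correlate upstream grad (conv-input role) with x (conv-output role)
        self.w.grad += conv_bwd_weight(gy_cols, self._x, self.w.data.shape)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gx = gy_cols @ self.w.data.reshape(self.w.data.shape[0], -1).T
        n, c, h, w = self._x.shape
        return gx.transpose(0, 2, 1).reshape(n, c, h, w)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, gy):
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.data.T


class BatchNorm2d:
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        return self.gamma.data[None, :, None, None] * self._xhat + self.beta.data[None, :, None, None]

    def backward(self, gy):
        xhat = self._xhat
        axes = (0, 2, 3)
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = gy * self.gamma.data[None, :, None, None]
        gm = g.mean(axis=axes, keepdims=True)
        gxm = (g * xhat).mean(axis=axes, keepdims=True)
        return (g - gm - xhat * gxm) / self._std


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=True):
        self._m = x > 0
        return x * self._m

    def backward(self, gy):
        return gy * self._m


class LeakyReLU:
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def params(self):
        return []

    def forward(self, x, train=True):
        self._m = x > 0
        return np.where(self._m, x, self.alpha * x)

    def backward(self, gy):
        return np.where(self._m, gy, self.alpha * gy)


class Sigmoid:
    def params(self):
        return []

    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Flatten:
    def params(self):
        return []

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Reshape:
    def __init__(self, shape: tuple):
        self.shape = shape

    def params(self):
        return []

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def forward_taps(self, x, train=True):
        """Forward returning every layer's output (for feature taps)."""
        outs = []
        for l in self.layers:
            x = l.forward(x, train=train)
            outs.append(x)
        return outs

    def backward(self, gy, tap_grads: dict[int, np.ndarray] | None = None):
        """Backprop; ``tap_grads[i]`` is added to the gradient flowing out of layer i."""
        for i in reversed(range(len(self.layers))):
            if tap_grads and i in tap_grads:
                gy = gy + tap_grads[i]
            gy = self.layers[i].backward(gy)
        return gy

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, clip_norm: float | None = 10.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2)) for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    p.grad *= scale
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
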