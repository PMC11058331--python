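"""Neural-network layers built on the autodiff engine.

Layers follow a functional-parameter convention: ``forward(x, params)``
consumes parameters from an iterator, so a model can be evaluated either
at its own parameters or at an externally supplied (e.g. adapted)
parameter list of the same layout.  This is what makes the one-step
inner adaptation of the meta objective expressible without copying
modules.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Tensor,
    broadcast_to,
    concat,
    matmul,
    pad2d,
    relu,
    reshape,
    sigmoid,
    take,
)

_CONV_IDX_CACHE: dict = {}
_POOL_IDX_CACHE: dict = {}
_UPSAMPLE_MAT_CACHE: dict = {}


def _conv_indices(n, c, hp, wp, kh, kw):
    """Flat gather indices turning a padded (N,C,Hp,Wp) block into columns."""
    key = (n, c, hp, wp, kh, kw)
    idx = _CONV_IDX_CACHE.get(key)
    if idx is None:
        ho, wo = hp - kh + 1, wp - kw + 1
        base = np.arange(c)[:, None, None] * (hp * wp) + (
            np.arange(kh)[None, :, None] * wp + np.arange(kw)[None, None, :]
        )  # (C, kh, kw)
        offs = (np.arange(ho)[:, None] * wp + np.arange(wo)[None, :]).ravel()
        per_img = base.reshape(-1, 1) + offs[None, :]  # (C*kh*kw, Ho*Wo)
        idx = (
            np.arange(n)[:, None, None] * (c * hp * wp) + per_img[None]
        )  # (N, C*kh*kw, Ho*Wo)
        _CONV_IDX_CACHE[key] = idx
    return idx


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int = 1) -> Tensor:
    """2-D convolution (stride 1) via im2col + matmul."""
    n, c, h, wid = x.shape
    o, _, kh, kw = w.shape
    xp = pad2d(x, pad)
    hp, wp = h + 2 * pad, wid + 2 * pad
    ho, wo = hp - kh + 1, wp - kw + 1
    idx = _conv_indices(n, c, hp, wp, kh, kw)
    cols = take(xp, idx)  # (N, C*kh*kw, Ho*Wo)
    wm = reshape(w, (o, c * kh * kw))
    out = matmul(wm, cols)  # (N, O, Ho*Wo)
    out = out + reshape(b, (1, o, 1))
    return reshape(out, (n, o, ho, wo))


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2, expressed as a gather at the argmax."""
    n, c, h, w = x.shape
    d = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    d = d.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    key = (n, c, h, w)
    cand = _POOL_IDX_CACHE.get(key)
    if cand is None:
        flat = np.arange(n * c * h * w).reshape(n, c, h // 2, 2, w // 2, 2)
        cand = flat.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        _POOL_IDX_CACHE[key] = cand
    arg = d.argmax(axis=-1)
    idx = np.take_along_axis(cand, arg[..., None], axis=-1)[..., 0]
    return take(x, idx)


def _bilinear_matrix(n_in: int, scale: int = 2) -> np.ndarray:
    """Interpolation matrix for 1-D bilinear upsampling (align_corners=False)."""
    key = (n_in, scale)
    mat = _UPSAMPLE_MAT_CACHE.get(key)
    if mat is None:
        n_out = n_in * scale
        mat = np.zeros((n_out, n_in))
        src = (np.arange(n_out) + 0.5) / scale - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        hi = np.clip(lo + 1, 0, n_in - 1)
        frac = np.clip(src - np.floor(src), 0.0, 1.0)
        frac[src < 0] = 0.0
        frac[src > n_in - 1] = 0.0
        mat[np.arange(n_out), lo] += 1.0 - frac
        mat[np.arange(n_out), hi] += frac
        _UPSAMPLE_MAT_CACHE[key] = mat
    return mat


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling as two dense interpolation matmuls."""
    _, _, h, w = x.shape
    uh = Tensor(_bilinear_matrix(h))
    uw = Tensor(_bilinear_matrix(w).T)
    return matmul(matmul(uh, x), uw)


class Module:
    """Base class: ordered parameter list + functional forward."""

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def forward(self, x: Tensor, params) -> Tensor:
        raise NotImplementedError

    def __call__(self, x: Tensor, params=None) -> Tensor:
        if params is None:
            params = iter(self.parameters())
        elif not hasattr(params, "__next__"):
            params = iter(params)
        return self.forward(x, params)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator, pad=None):
        fan_in = cin * ksize * ksize
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.weight = Tensor(
            rng.normal(0.0, std, size=(cout, cin, ksize, ksize)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.pad = (ksize // 2) if pad is None else pad

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, params):
        w, b = next(params), next(params)
        return conv2d(x, w, b, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, params):
        gamma, beta = next(params), next(params)
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * reshape(gamma, (1, c, 1, 1)) + reshape(beta, (1, c, 1, 1))


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def parameters(self):
        return [p for m in self.modules for p in m.parameters()]

    def forward(self, x, params):
        for m in self.modules:
            x = m.forward(x, params)
        return x


class ReLU(Module):
    def parameters(self):
        return []

    def forward(self, x, params):
        return relu(x)


class SGD:
    """SGD with momentum and decoupled-from-inner-loop weight decay.

    Update rule (matching the common deep-learning convention):
    ``v = momentum * v + (g + wd * p); p -= lr * v``.
    """

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.velocity = [np.zeros(p.shape) for p in self.params]

    def step(self, grads: list[Tensor]) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            gd = g.data + self.weight_decay * p.data
            v *= self.momentum
            v += gd
            p.data -= self.lr * v
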