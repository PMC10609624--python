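"""Minimal CPU tensor library with reverse-mode autodiff.

Just enough machinery for the restoration networks in this package: NCHW
float32 tensors, 'same'-padded convolution via im2col, batch normalization,
pixel shuffle, elementwise ops with broadcasting, L1/MSE losses and Adam.
Written for clarity and desk-scale problem sizes, not for GPU-scale training.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Var", "backward", "constant",
    "conv2d", "relu", "sigmoid", "add", "mul", "concat",
    "global_avg_pool", "pixel_shuffle", "batch_norm",
    "l1_loss", "mse_loss",
    "Conv2d", "BatchNorm2d", "Adam",
    "he_init",
]


class Var:
    """A tensor node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires")

    def __init__(self, data, parents: tuple = (), backward_fn=None,
                 requires: bool | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward: Callable[[np.ndarray], None] | None = backward_fn
        if requires is None:
            requires = any(p.requires for p in parents)
        self.requires = requires

    @property
    def shape(self):
        return self.data.shape


def constant(data) -> Var:
    return Var(data, requires=False)


def _accum(v: Var, g: np.ndarray) -> None:
    if not v.requires:
        return
    g = g.astype(np.float32, copy=False)
    v.grad = g if v.grad is None else v.grad + g


def backward(loss: Var) -> None:
    """Reverse-mode sweep from a scalar loss (iterative topological order)."""
    topo: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen and p.requires:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Ops
# ---------------------------------------------------------------------------

def _fold_edge_padding(gxp: np.ndarray, pad: int) -> np.ndarray:
    """Collapse gradients on replicate-padded borders back onto the edges."""
    gxp[:, :, pad, :] += gxp[:, :, :pad, :].sum(axis=2)
    gxp[:, :, -pad - 1, :] += gxp[:, :, -pad:, :].sum(axis=2)
    core = gxp[:, :, pad:-pad, :]
    core[:, :, :, pad] += core[:, :, :, :pad].sum(axis=3)
    core[:, :, :, -pad - 1] += core[:, :, :, -pad:].sum(axis=3)
    return core[:, :, :, pad:-pad]


def conv2d(x: Var, w: Var, b: Var | None = None,
           pad_mode: str = "zero") -> Var:
    """'Same'-padded stride-1 convolution, NCHW x (O,C,k,k).

    ``pad_mode='edge'`` replicates border pixels instead of zero-filling,
    which keeps constants constant through the layer -- important for image
    networks whose untrained state should act like an interpolator.
    """
    k = w.data.shape[2]
    pad = k // 2
    xd = x.data
    n, c, h, wd = xd.shape
    o = w.data.shape[0]
    if pad_mode == "edge":
        xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="edge")
    elif pad_mode == "zero":
        xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        raise ValueError(f"unknown pad_mode {pad_mode!r}")
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * wd, c * k * k)
    wm = w.data.reshape(o, c * k * k)
    out = cols @ wm.T
    if b is not None:
        out = out + b.data
    outd = out.transpose(0, 2, 1).reshape(n, o, h, wd)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g: np.ndarray) -> None:
        gm = g.reshape(n, o, h * wd).transpose(0, 2, 1)
        if w.requires:
            gw = np.tensordot(gm, cols, axes=([0, 1], [0, 1]))
            _accum(w, gw.reshape(w.data.shape))
        if b is not None and b.requires:
            _accum(b, gm.sum(axis=(0, 1)))
        if x.requires:
            gcols = gm @ wm
            gc = gcols.reshape(n, h, wd, c, k, k)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + h, j:j + wd] += gc[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if pad_mode == "edge" and pad > 0:
                _accum(x, _fold_edge_padding(gxp, pad))
            else:
                _accum(x, gxp[:, :, pad:pad + h, pad:pad + wd])

    return Var(outd, parents, bw)


def relu(x: Var) -> Var:
    mask = x.data > 0

    def bw(g):
        _accum(x, g * mask)

    return Var(x.data * mask, (x,), bw)


def sigmoid(x: Var) -> Var:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        _accum(x, g * s * (1.0 - s))

    return Var(s, (x,), bw)


def add(x: Var, y: Var) -> Var:
    def bw(g):
        _accum(x, _unbroadcast(g, x.data.shape))
        _accum(y, _unbroadcast(g, y.data.shape))

    return Var(x.data + y.data, (x, y), bw)


def mul(x: Var, y: Var) -> Var:
    def bw(g):
        _accum(x, _unbroadcast(g * y.data, x.data.shape))
        _accum(y, _unbroadcast(g * x.data, y.data.shape))

    return Var(x.data * y.data, (x, y), bw)


def concat(xs: Sequence[Var], axis: int = 1) -> Var:
    sizes = [v.data.shape[axis] for v in xs]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for v, a, b in zip(xs, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            _accum(v, g[tuple(sl)])

    return Var(np.concatenate([v.data for v in xs], axis=axis), tuple(xs), bw)


def global_avg_pool(x: Var) -> Var:
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def bw(g):
        _accum(x, np.broadcast_to(g / (h * w), x.data.shape))

    return Var(out, (x,), bw)


def pixel_shuffle(x: Var, r: int) -> Var:
    n, crr, h, w = x.data.shape
    if crr % (r * r) != 0:
        raise ValueError(f"channels {crr} not divisible by r^2 = {r * r}")
    c = crr // (r * r)
    out = (
        x.data.reshape(n, c, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * r, w * r)
    )

    def bw(g):
        gx = (
            g.reshape(n, c, h, r, w, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, crr, h, w)
        )
        _accum(x, gx)

    return Var(out, (x,), bw)


def batch_norm(x: Var, gamma: Var, beta: Var, running: dict,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Var:
    """Per-channel batch normalization over (N, H, W)."""
    xd = x.data
    n, c, h, w = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu = running["mean"]
        var = running["var"]
    std = np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        if gamma.requires:
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires:
            m = n * h * w
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (dxhat - s1 / m - xhat * s2 / m) / std[None, :, None, None]
            else:
                gx = dxhat / std[None, :, None, None]
            _accum(x, gx)

    return Var(out, (x, gamma, beta), bw)


def l1_loss(pred: Var, target: np.ndarray) -> Var:
    diff = pred.data - np.asarray(target, dtype=np.float32)

    def bw(g):
        _accum(pred, g * np.sign(diff) / diff.size)

    return Var(np.mean(np.abs(diff)), (pred,), bw)


def mse_loss(pred: Var, target: np.ndarray) -> Var:
    diff = pred.data - np.asarray(target, dtype=np.float32)

    def bw(g):
        _accum(pred, g * 2.0 * diff / diff.size)

    return Var(np.mean(diff**2), (pred,), bw)


# ---------------------------------------------------------------------------
# Layers and optimizer
# ---------------------------------------------------------------------------

def he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d:
    """'Same'-padded convolution layer with owned weight/bias parameters."""

    def __init__(self, in_ch: int, out_ch: int, k: int,
                 rng: np.random.Generator, bias: bool = True,
                 init: str = "he", pad_mode: str = "zero"):
        shape = (out_ch, in_ch, k, k)
        if init == "he":
            w = he_init(rng, shape)
        elif init == "zero":
            w = np.zeros(shape, dtype=np.float32)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.w = Var(w, requires=True)
        self.b = Var(np.zeros(out_ch, dtype=np.float32), requires=True) if bias else None
        self.pad_mode = pad_mode

    def __call__(self, x: Var) -> Var:
        return conv2d(x, self.w, self.b, pad_mode=self.pad_mode)

    @property
    def params(self) -> list[Var]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params)


class BatchNorm2d:
    def __init__(self, ch: int, momentum: float = 0.1):
        self.gamma = Var(np.ones(ch, dtype=np.float32), requires=True)
        self.beta = Var(np.zeros(ch, dtype=np.float32), requires=True)
        self.running = {"mean": np.zeros(ch, dtype=np.float32),
                        "var": np.ones(ch, dtype=np.float32)}
        self.training = True
        self.momentum = momentum

    def __call__(self, x: Var) -> Var:
        return batch_norm(x, self.gamma, self.beta, self.running,
                          self.training, momentum=self.momentum)

    @property
    def params(self) -> list[Var]:
        return [self.gamma, self.beta]


class Adam:
    """Adam optimizer over a list of :class:`Var` parameters."""

    def __init__(self, params: Sequence[Var], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
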