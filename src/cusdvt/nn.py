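"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the compression-ultrasound network: 2-D
convolutions via im2col/col2im, dense layers, ReLU / sigmoid / channel
softmax, nearest-neighbour upsampling, channel concatenation, global
average pooling and clipped binary-cross-entropy reductions, plus an Adam
optimizer.  Float32 by default (ops preserve dtype, so float64 graphs work
for finite-difference checks); seeded; no external framework.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

EPS = 1e-7   # probability clipping before logs

# single-precision keeps CPU training memory-bound ops fast; ops preserve
# dtype, so float64 graphs (e.g. for finite-difference checks) work too
DTYPE = np.float32


class Tensor:
    """A node in the computation graph: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents: tuple = (), backward: Callable | None = None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(DTYPE)
        self.data = arr
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE))


# ---------------------------------------------------------------------------
# im2col convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int):
    """Unfold (N, C, H, W) into (N, C·k·k, Ho·Wo) patch columns."""
    n, c, h, w = xp.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + ho * stride:stride,
                                  j:j + wo * stride:stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, xp_shape, k: int, stride: int, ho: int, wo: int):
    """Scatter-add patch-column gradients back onto the padded input."""
    n, c, _, _ = xp_shape
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + ho * stride:stride,
                j:j + wo * stride:stride] += d[:, :, i, j]
    return dxp


def _zero_pad(x: np.ndarray, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    xp[:, :, pad:pad + h, pad:pad + w] = x
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, square kernel, symmetric zero padding."""
    n, c, h, ww = x.shape
    o, c2, k, _ = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    xp = _zero_pad(x.data, pad) if pad else x.data
    cols, ho, wo = _im2col(xp, k, stride)                      # N, CKK, L
    wmat = w.data.reshape(o, -1)
    out_data = (wmat @ cols).reshape(n, o, ho, wo) + b.data[None, :, None, None]

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(n, o, ho * wo)
        # batched GEMM per sample avoids the large transposed copy of cols
        dw = np.matmul(cols, np.swapaxes(g2, 1, 2)).sum(axis=0).T
        w.accumulate(dw.reshape(w.shape))
        b.accumulate(g.sum(axis=(0, 2, 3)))
        dcols = wmat.T @ g2                                    # N, CKK, L
        dxp = _col2im(dcols, xp.shape, k, stride, ho, wo)
        x.accumulate(dxp[:, :, pad:pad + h, pad:pad + ww] if pad else dxp)

    return Tensor(out_data, (x, w, b), backward)


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine layer: x (N, D) @ w (D, M) + b (M,)."""
    out_data = x.data @ w.data + b.data

    def backward(g: np.ndarray) -> None:
        x.accumulate(g @ w.data.T)
        w.accumulate(x.data.T @ g)
        b.accumulate(g.sum(axis=0))

    return Tensor(out_data, (x, w, b), backward)


# ---------------------------------------------------------------------------
# Elementwise and structural ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g: np.ndarray) -> None:
        x.accumulate(g * mask)

    return Tensor(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def backward(g: np.ndarray) -> None:
        x.accumulate(g * s * (1.0 - s))

    return Tensor(s, (x,), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray) -> None:
        dot = (g * p).sum(axis=axis, keepdims=True)
        x.accumulate(p * (g - dot))

    return Tensor(p, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling (NCHW)."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.shape

    def backward(g: np.ndarray) -> None:
        x.accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(out_data, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def backward(g: np.ndarray) -> None:
        a.accumulate(g[:, :ca])
        b.accumulate(g[:, ca:])

    return Tensor(out_data, (a, b), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g: np.ndarray) -> None:
        x.accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).copy())

    return Tensor(out_data, (x,), backward)


def grid_pool(x: Tensor, g: int) -> Tensor:
    """Adaptive average pool to a g×g grid, flattened to (N, C·g·g).

    Keeps coarse spatial layout (which quadrant holds which vessel), unlike
    a global pool.  Requires H and W divisible by g.
    """
    n, c, h, w = x.shape
    if h % g or w % g:
        raise ValueError(f"spatial size {h}x{w} not divisible by grid {g}")
    bh, bw = h // g, w // g
    pooled = x.data.reshape(n, c, g, bh, g, bw).mean(axis=(3, 5))

    def backward(grad: np.ndarray) -> None:
        gg = grad.reshape(n, c, g, g)[:, :, :, None, :, None] / (bh * bw)
        x.accumulate(np.broadcast_to(gg, (n, c, g, bh, g, bw)).reshape(x.shape).copy())

    return Tensor(pooled.reshape(n, c * g * g), (x,), backward)


def grid_max_pool(x: Tensor, g: int) -> Tensor:
    """Adaptive max pool to a g×g grid, flattened to (N, C·g·g).

    Complements :func:`grid_pool` for detection-style heads: a faint local
    probability bump survives max pooling even when the block mean is tiny.
    """
    n, c, h, w = x.shape
    if h % g or w % g:
        raise ValueError(f"spatial size {h}x{w} not divisible by grid {g}")
    bh, bw = h // g, w // g
    blocks = x.data.reshape(n, c, g, bh, g, bw)
    pooled = blocks.max(axis=(3, 5))
    is_max = blocks == pooled[:, :, :, None, :, None]
    # split ties evenly so the gradient check stays consistent
    counts = is_max.sum(axis=(3, 5), keepdims=True)

    def backward(grad: np.ndarray) -> None:
        gg = grad.reshape(n, c, g, g)[:, :, :, None, :, None]
        x.accumulate((is_max * gg / counts).reshape(x.shape))

    return Tensor(pooled.reshape(n, c * g * g), (x,), backward)


def select_channel(x: Tensor, idx: int) -> Tensor:
    """Keep one channel as (N, 1, H, W)."""
    out_data = x.data[:, idx:idx + 1]

    def backward(g: np.ndarray) -> None:
        dx = np.zeros_like(x.data)
        dx[:, idx:idx + 1] = g
        x.accumulate(dx)

    return Tensor(out_data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.shape

    def backward(g: np.ndarray) -> None:
        x.accumulate(g.reshape(old))

    return Tensor(x.data.reshape(shape), (x,), backward)


def weighted_sum(terms: Sequence[tuple[float, Tensor]]) -> Tensor:
    """Σ w_i · t_i over scalar tensors."""
    out_data = sum(w * t.data for w, t in terms)

    def backward(g: np.ndarray) -> None:
        for w, t in terms:
            t.accumulate(g * w)

    return Tensor(out_data, tuple(t for _, t in terms), backward)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_elements(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Elementwise clipped binary cross-entropy -[y log p + (1-y) log(1-p)]."""
    pc = np.clip(p, EPS, 1.0 - EPS)
    return -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))


def bce(p: Tensor, y: np.ndarray, scale: float,
        weight: np.ndarray | None = None) -> Tensor:
    """scale · Σ weighted elementwise BCE, as a scalar graph node.

    ``scale = 1/p.size`` gives the mean; ``scale = 1/batch`` gives the
    per-sample class sum used for the landmark head.  ``weight`` (broadcast
    against the prediction) masks out elements whose label is undefined.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != p.data.shape:
        raise ValueError(f"shape mismatch: pred {p.data.shape}, target {y.shape}")
    pc = np.clip(p.data, EPS, 1.0 - EPS)
    elems = bce_elements(p.data, y)
    if weight is not None:
        elems = elems * weight
    value = scale * float(elems.sum())
    interior = (p.data > EPS) & (p.data < 1.0 - EPS)

    def backward(g: np.ndarray) -> None:
        dp = scale * (-(y / pc) + (1.0 - y) / (1.0 - pc)) * interior
        if weight is not None:
            dp = dp * weight
        p.accumulate(g * dp)

    return Tensor(value, (p,), backward)


# ---------------------------------------------------------------------------
# Initialisation and optimisation
# ---------------------------------------------------------------------------

def he_conv(rng: np.random.Generator, o: int, c: int, k: int) -> np.ndarray:
    return (rng.standard_normal((o, c, k, k)) * math.sqrt(2.0 / (c * k * k))).astype(DTYPE)


def he_dense(rng: np.random.Generator, d: int, m: int) -> np.ndarray:
    return (rng.standard_normal((d, m)) * math.sqrt(2.0 / d)).astype(DTYPE)


class Adam:
    """Adam with bias correction; beta1 is the momentum parameter (0.9)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def concat_features(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two (N, D) feature tensors along the feature axis."""
    da = a.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def backward(g: np.ndarray) -> None:
        a.accumulate(g[:, :da])
        b.accumulate(g[:, da:])

    return Tensor(out_data, (a, b), backward)
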