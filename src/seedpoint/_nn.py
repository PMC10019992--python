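"""Minimal reverse-mode autodiff on NumPy arrays, with the handful of
convolutional-network operations the seed counter needs.

Everything runs in float32, NCHW layout, stride-1 convolutions (all spatial
downsampling happens in ceil-mode 2x2 max pooling).  The graph is rebuilt on
every forward pass and freed once ``backward`` has run, so memory stays
bounded at one image's activations.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference paths)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # release the graph
        for node in topo:
            node._parents = ()
            node._backward = None

    # -- arithmetic sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul_scalar(_wrap(other), -1.0))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return mul_scalar(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t, g):
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _make(data, parents, backward):
    if not _GRAD_ENABLED:
        return Tensor(data)
    track = any(p.requires_grad or p._parents for p in parents)
    if not track:
        return Tensor(data)
    return Tensor(data, _parents=parents, _backward=backward)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def add(a, b):
    out = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out, (a, b), bwd)


def mul(a, b):
    out = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), bwd)


def mul_scalar(a, s):
    out = a.data * s

    def bwd(g):
        _accum(a, g * s)

    return _make(out, (a,), bwd)


def relu(a):
    mask = a.data > 0
    out = a.data * mask

    def bwd(g):
        _accum(a, g * mask)

    return _make(out, (a,), bwd)


def sigmoid(a):
    out = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        _accum(a, g * out * (1.0 - out))

    return _make(out, (a,), bwd)


def sum_all(a):
    out = a.data.sum()

    def bwd(g):
        _accum(a, np.full_like(a.data, g))

    return _make(out, (a,), bwd)


def mean_all(a):
    n = a.data.size
    out = a.data.mean()

    def bwd(g):
        _accum(a, np.full_like(a.data, g / n))

    return _make(out, (a,), bwd)


def take(a, idx):
    """Row gather along axis 0 (used to pick matched proposals)."""
    idx = np.asarray(idx, dtype=np.intp)
    out = a.data[idx]

    def bwd(g):
        acc = np.zeros_like(a.data)
        np.add.at(acc, idx, g)
        _accum(a, acc)

    return _make(out, (a,), bwd)


def reshape(a, shape):
    out = a.data.reshape(shape)
    orig = a.data.shape

    def bwd(g):
        _accum(a, g.reshape(orig))

    return _make(out, (a,), bwd)


def transpose(a, axes):
    out = np.ascontiguousarray(a.data.transpose(axes))
    inv = np.argsort(axes)

    def bwd(g):
        _accum(a, np.ascontiguousarray(g.transpose(inv)))

    return _make(out, (a,), bwd)


def concat(tensors, axis=1):
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(out, tuple(tensors), bwd)


def channel_mean(a):
    out = a.data.mean(axis=1, keepdims=True)
    c = a.data.shape[1]

    def bwd(g):
        _accum(a, np.broadcast_to(g / c, a.data.shape).astype(np.float32))

    return _make(out, (a,), bwd)


def channel_max(a):
    idx = a.data.argmax(axis=1, keepdims=True)
    out = np.take_along_axis(a.data, idx, axis=1)

    def bwd(g):
        acc = np.zeros_like(a.data)
        np.put_along_axis(acc, idx, g, axis=1)
        _accum(a, acc)

    return _make(out, (a,), bwd)


def global_avg_pool(a):
    n, c, h, w = a.data.shape
    out = a.data.mean(axis=(2, 3), keepdims=True)

    def bwd(g):
        _accum(a, np.broadcast_to(g / (h * w), a.data.shape).astype(np.float32))

    return _make(out, (a,), bwd)


# ---------------------------------------------------------------------------
# convolution / pooling / resampling
# ---------------------------------------------------------------------------

def pad_edge(x, p):
    """Replicate-pad the two spatial axes by ``p`` (gradients fold back)."""
    n, c, h, w = x.data.shape
    out = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")
    iy = np.clip(np.arange(h + 2 * p) - p, 0, h - 1)
    ix = np.clip(np.arange(w + 2 * p) - p, 0, w - 1)

    def bwd(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, (slice(None), slice(None), iy[:, None], ix[None, :]), g)
        _accum(x, acc)

    return _make(out, (x,), bwd)


def conv2d(x, w, b, dilation=1, padding=None):
    """Stride-1 convolution; w is (Cout, Cin, k, k), k odd.

    ``padding=None`` means zero-padded 'same'; an integer gives explicit
    zero padding (0 = 'valid').
    """
    n, cin, h, wd = x.data.shape
    cout, cin_w, k, k2 = w.data.shape
    assert cin == cin_w and k == k2 and k % 2 == 1
    d = int(dilation)
    p = d * (k // 2) if padding is None else int(padding)
    h_out = h + 2 * p - d * (k - 1)
    w_out = wd + 2 * p - d * (k - 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    acc = np.zeros((cout, n, h_out, w_out), dtype=np.float32)
    for ki in range(k):
        for kj in range(k):
            xs = xp[:, :, ki * d: ki * d + h_out, kj * d: kj * d + w_out]
            # (Cout,Cin) . (N,Cin,H,W) -> (Cout,N,H,W)
            acc += np.tensordot(w.data[:, :, ki, kj], xs, axes=([1], [1]))
    out = np.ascontiguousarray(acc.transpose(1, 0, 2, 3))
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)

    def bwd(g):
        gt = np.ascontiguousarray(g.transpose(1, 0, 2, 3))  # (Cout,N,H,W)
        if x.requires_grad or x._parents:
            dxp = np.zeros((n, cin, h + 2 * p, wd + 2 * p), dtype=np.float32)
            for ki in range(k):
                for kj in range(k):
                    # (Cin,Cout) . (Cout,N,H,W) -> (Cin,N,H,W)
                    dxs = np.tensordot(w.data[:, :, ki, kj], gt, axes=([0], [0]))
                    dxp[:, :, ki * d: ki * d + h_out, kj * d: kj * d + w_out] += (
                        dxs.transpose(1, 0, 2, 3)
                    )
            _accum(x, dxp[:, :, p: p + h, p: p + wd] if p else dxp)
        dw = np.empty_like(w.data)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki * d: ki * d + h_out, kj * d: kj * d + w_out]
                dw[:, :, ki, kj] = np.tensordot(
                    gt, xs, axes=([1, 2, 3], [0, 2, 3])
                )
        _accum(w, dw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))

    parents = (x, w, b) if b is not None else (x, w)
    return _make(out, parents, bwd)


def maxpool2x2(x):
    """2x2 max pool, stride 2, ceil mode (odd sizes padded with -inf)."""
    n, c, h, w = x.data.shape
    h2, w2 = -(-h // 2), -(-w // 2)
    ph, pw = h2 * 2 - h, w2 * 2 - w
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (0, ph), (0, pw)),
                    constant_values=-np.inf)
    xr = xp.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h2, w2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        acc = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(acc, idx[..., None], g[..., None], axis=-1)
        acc = acc.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        acc = np.ascontiguousarray(acc).reshape(n, c, h2 * 2, w2 * 2)
        _accum(x, acc[:, :, :h, :w])

    return _make(out, (x,), bwd)


def _resize_coords(n_in, n_out):
    pos = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    pos = np.clip(pos, 0.0, n_in - 1.0)
    lo = np.floor(pos).astype(np.intp)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (pos - lo).astype(np.float32)
    return lo, hi, frac


def resize_bilinear(x, out_hw):
    """Bilinear resampling (up or down) to ``out_hw``, half-pixel centers."""
    n, c, h, w = x.data.shape
    ho, wo = out_hw
    if (ho, wo) == (h, w):
        return x
    y0, y1, fy = _resize_coords(h, ho)
    x0, x1, fx = _resize_coords(w, wo)
    fy = fy[:, None]
    fx = fx[None, :]
    w00 = (1 - fy) * (1 - fx)
    w01 = (1 - fy) * fx
    w10 = fy * (1 - fx)
    w11 = fy * fx
    d = x.data
    out = (d[:, :, y0[:, None], x0[None, :]] * w00
           + d[:, :, y0[:, None], x1[None, :]] * w01
           + d[:, :, y1[:, None], x0[None, :]] * w10
           + d[:, :, y1[:, None], x1[None, :]] * w11)

    def bwd(g):
        acc = np.zeros_like(x.data)
        for yy, xx, ww in ((y0, x0, w00), (y0, x1, w01),
                           (y1, x0, w10), (y1, x1, w11)):
            np.add.at(acc, (slice(None), slice(None),
                            yy[:, None], xx[None, :]), g * ww)
        _accum(x, acc)

    return _make(out.astype(np.float32), (x,), bwd)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_with_logits(logits, targets, weights):
    """Weighted binary cross-entropy, normalized by the sum of weights.

    Numerically stable form: max(z,0) - z*t + log(1 + exp(-|z|)).
    """
    z = logits.data
    t = np.asarray(targets, dtype=np.float32)
    w = np.asarray(weights, dtype=np.float32)
    wsum = float(w.sum())
    per = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = float((w * per).sum() / wsum)

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-z))
        _accum(logits, (g * w * (p - t) / wsum).astype(np.float32))

    return _make(np.float32(out), (logits,), bwd)


# ---------------------------------------------------------------------------
# layers and optimizer
# ---------------------------------------------------------------------------

class Conv2d:
    """Stride-1 'same' conv layer with He-initialized weights."""

    def __init__(self, cin, cout, k, rng, dilation=1, bias=True):
        std = math.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, std, (cout, cin, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.dilation = dilation

    def __call__(self, x, dilation=None):
        return conv2d(x, self.w, self.b,
                      dilation=self.dilation if dilation is None else dilation)

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]


class Adam:
    """Adam with optional per-group learning rates.

    ``groups`` is a list of (params, lr) pairs.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps=1e-8):
        self.groups = [(list(ps), float(lr)) for ps, lr in groups]
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state = {}
        for ps, _ in self.groups:
            for p in ps:
                self.state[id(p)] = (np.zeros_like(p.data),
                                     np.zeros_like(p.data))

    def zero_grad(self):
        for ps, _ in self.groups:
            for p in ps:
                p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for ps, lr in self.groups:
            for p in ps:
                if p.grad is None:
                    continue
                m, v = self.state[id(p)]
                m *= self.b1
                m += (1 - self.b1) * p.grad
                v *= self.b2
                v += (1 - self.b2) * p.grad ** 2
                p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
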