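"""Minimal reverse-mode autodiff on numpy arrays for the map-generation GAN.

Implements exactly the operations the generator/discriminator need —
strided 2D convolution (im2col), nearest-neighbour upsampling, channel
concatenation, LeakyReLU/tanh, elementwise arithmetic and mean reduction —
with hand-written backward passes (gradient-checked against finite
differences in the test suite) and an Adam optimizer.  float32 throughout.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class Var:
    """A node in the computation graph: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_F32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(v):
            if id(v) in seen:
                return
            seen.add(id(v))
            for p in v._parents:
                visit(p)
            topo.append(v)

        visit(self)
        self.grad = np.ones_like(self.data)
        for v in reversed(topo):
            if v._backward is not None and v.grad is not None:
                v._backward(v.grad)

    # -- elementwise arithmetic (numpy broadcasting, gradients unbroadcast) --

    def __add__(self, other):
        other = _as_var(other)
        out = Var(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    def __sub__(self, other):
        other = _as_var(other)
        out = Var(self.data - other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = _as_var(other)
        out = Var(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return _as_var(other) - self

    def __neg__(self):
        return self * (-1.0)


def _as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(np.asarray(x, dtype=_F32))


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over dimensions that were broadcast in the forward op."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


def mean(x: Var) -> Var:
    out = Var(np.array(x.data.mean()), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.full_like(x.data, g / x.data.size))

    out._backward = bw
    return out


def absolute(x: Var) -> Var:
    out = Var(np.abs(x.data), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * np.sign(x.data))

    out._backward = bw
    return out


def tanh(x: Var) -> Var:
    y = np.tanh(x.data)
    out = Var(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - y * y))

    out._backward = bw
    return out


def leaky_relu(x: Var, slope: float = 0.2) -> Var:
    pos = x.data > 0
    out = Var(np.where(pos, x.data, slope * x.data), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * np.where(pos, 1.0, slope).astype(_F32))

    out._backward = bw
    return out


def concat(xs: list[Var], axis: int = 1) -> Var:
    out = Var(np.concatenate([x.data for x in xs], axis=axis), parents=tuple(xs))
    sizes = [x.data.shape[axis] for x in xs]

    def bw(g):
        start = 0
        for x, s in zip(xs, sizes):
            if x.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                x._accumulate(g[tuple(sl)])
            start += s

    out._backward = bw
    return out


def upsample_nearest(x: Var, factor: int = 2) -> Var:
    """Nearest-neighbour upsampling of (B, C, H, W) by an integer factor."""
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Var(out_data, parents=(x,))

    def bw(g):
        if x.requires_grad:
            b, c, h, w = x.data.shape
            gr = g.reshape(b, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accumulate(gr)

    out._backward = bw
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(B, C, Hp, Wp) -> columns (C*kh*kw, B*Ho*Wo)."""
    sw = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    sw = sw[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, kh, kw)
    b, c, ho, wo = sw.shape[:4]
    cols = sw.transpose(1, 4, 5, 0, 2, 3).reshape(c * kh * kw, b * ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Var, w: Var, b: Var, stride: int = 1, pad: int = 1) -> Var:
    """2D convolution (cross-correlation) of (B,C,H,W) with (Cout,C,kh,kw)."""
    bsz, cin, h, wdt = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError("channel mismatch")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wm = w.data.reshape(cout, -1)
    out_data = (wm @ cols).reshape(cout, bsz, ho, wo).transpose(1, 0, 2, 3)
    out_data = np.ascontiguousarray(out_data)
    out_data += b.data.reshape(1, cout, 1, 1)
    out = Var(out_data, parents=(x, w, b))

    def bw(g):
        gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, bsz * ho * wo)
        if b.requires_grad:
            b._accumulate(gm.sum(axis=1))
        if w.requires_grad:
            w._accumulate((gm @ cols.T).reshape(w.data.shape))
        if x.requires_grad:
            dcols = (wm.T @ gm).reshape(cin, kh, kw, bsz, ho, wo)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[
                        :, :, i : i + stride * ho : stride, j : j + stride * wo : stride
                    ] += dcols[:, i, j].transpose(1, 0, 2, 3)
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accumulate(dxp)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# layers


class Conv2d:
    """Convolution layer with He-initialized weights."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, pad=None, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        if pad is None:
            pad = k // 2
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Var(rng.standard_normal((cout, cin, k, k)) * scale, requires_grad=True)
        self.b = Var(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Var) -> Var:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def parameters(self):
        return [self.w, self.b]


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p.data -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(_F32)


def gradient_check(f, x: np.ndarray, eps: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Analytic vs central-difference gradient of a scalar function of x."""
    v = Var(x.astype(np.float32), requires_grad=True)
    out = f(v)
    out.backward()
    analytic = v.grad.copy()
    numeric = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        fp = f(Var(xp.astype(np.float32))).data.item()
        fm = f(Var(xm.astype(np.float32))).data.item()
        numeric[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return analytic, numeric
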