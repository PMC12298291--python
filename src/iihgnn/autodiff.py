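"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
``ndarray`` and records a backward closure. Only the operations the detector
needs are provided — elementwise arithmetic with broadcasting, matmul, 2-D
convolution (direct, per-kernel-offset slicing), bilinear resampling,
deformable convolution, pooling and the usual activations/losses. Everything
runs on the CPU in float32 by default.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "concat", "conv2d", "avg_pool2d", "resize_bilinear",
    "deform_conv2d", "bce_with_logits", "maximum", "minimum", "sigmoid",
    "silu", "relu", "exp", "log", "sqrt", "stack_rows", "Adam",
]


class no_grad:
    """Context manager that disables graph construction (inference mode)."""
    _active = 0

    def __enter__(self):
        no_grad._active += 1

    def __exit__(self, *exc):
        no_grad._active -= 1


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff machinery ---------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __neg__(self):
        return self * (-1.0)

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        a = self.data
        out = _make(a ** p, (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g * p * a ** (p - 1))
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._prev:
            shape = self.data.shape

            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, shape))

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.data.ndim))[::-1]
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._prev:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._prev:
            a, b = self.data, other.data

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

            out._backward = bw
        return out

    def clip(self, lo, hi):
        a = self.data
        out = _make(np.clip(a, lo, hi), (self,))
        if out._prev:
            mask = (a >= lo) & (a <= hi)
            out._backward = lambda g: self._accum(g * mask)
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data: np.ndarray, parents) -> Tensor:
    out = Tensor(data)
    if no_grad._active:
        return out
    parents = tuple(p for p in parents if isinstance(p, Tensor) and p.requires_grad)
    if parents:
        out.requires_grad = True
        out._prev = parents
    return out


def _binary(a: Tensor, b, fwd, dfa, dfb) -> Tensor:
    b = _as_tensor(b)
    out = _make(fwd(a.data, b.data), (a, b))
    if out._prev:
        ad, bd = a.data, b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(dfa(g, ad, bd), ad.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(dfb(g, ad, bd), bd.shape))

        out._backward = bw
    return out


# -- unary math ---------------------------------------------------------------

def _unary(x: Tensor, fwd, dfx) -> Tensor:
    out = _make(fwd(x.data), (x,))
    if out._prev:
        out._backward = lambda g: x._accum(dfx(g, x.data, out.data))
    return out


def exp(x):
    return _unary(_as_tensor(x), np.exp, lambda g, a, o: g * o)


def log(x):
    return _unary(_as_tensor(x), np.log, lambda g, a, o: g / a)


def sqrt(x):
    return _unary(_as_tensor(x), np.sqrt, lambda g, a, o: g * 0.5 / o)


def sigmoid(x):
    x = _as_tensor(x)

    def fwd(a):
        # clipping keeps exp finite; saturation error is below float32 eps
        return 1.0 / (1.0 + np.exp(-np.clip(a, -30.0, 30.0)))

    return _unary(x, fwd, lambda g, a, o: g * o * (1.0 - o))


def relu(x):
    return _unary(_as_tensor(x), lambda a: np.maximum(a, 0.0),
                  lambda g, a, o: g * (a > 0))


def silu(x):
    """x * sigmoid(x), the default activation of modern YOLO-style nets."""
    x = _as_tensor(x)
    s = sigmoid(x)
    return x * s


def maximum(a, b):
    return _binary(_as_tensor(a), b, np.maximum,
                   lambda g, x, y: g * (x >= y), lambda g, x, y: g * (x < y))


def minimum(a, b):
    return _binary(_as_tensor(a), b, np.minimum,
                   lambda g, x, y: g * (x <= y), lambda g, x, y: g * (x > y))


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._prev:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = bw
    return out


def stack_rows(tensors):
    """Stack 1-D tensors into a 2-D tensor (axis 0)."""
    return concat([t.reshape(1, -1) for t in tensors], axis=0)


# -- convolution --------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Direct 2-D convolution (cross-correlation), NCHW layout.

    Implemented as a sum over kernel offsets of strided views — fast enough
    for the small kernels (1x1/3x3) used here and exactly differentiable.
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, C2, kh, kw = wd.shape
    if C != C2:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {C2}")
    s, p = int(stride), int(padding)
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    out = np.zeros((N, O, Ho * Wo), dtype=xd.dtype)
    for ki in range(kh):
        for kj in range(kw):
            view = xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
            out += np.matmul(wd[:, :, ki, kj],
                             np.ascontiguousarray(view).reshape(N, C, -1))
    out = out.reshape(N, O, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    res = _make(out, parents)
    if res._prev:
        def bw(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            need_x = x.requires_grad
            need_w = w.requires_grad
            gf = np.ascontiguousarray(g).reshape(N, O, -1)
            dxp = np.zeros_like(xp) if need_x else None
            dw = np.zeros_like(wd) if need_w else None
            for ki in range(kh):
                for kj in range(kw):
                    view = xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
                    if need_w:
                        vf = np.ascontiguousarray(view).reshape(N, C, -1)
                        dw[:, :, ki, kj] = np.matmul(
                            gf, vf.transpose(0, 2, 1)).sum(axis=0)
                    if need_x:
                        dview = np.matmul(wd[:, :, ki, kj].T, gf)
                        dxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += \
                            dview.reshape(N, C, Ho, Wo)
            if need_w:
                w._accum(dw)
            if need_x:
                x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

        res._backward = bw
    return res


def avg_pool2d(x: Tensor, k: int = 2, stride: int | None = None) -> Tensor:
    s = stride or k
    xd = x.data
    N, C, H, W = xd.shape
    Ho, Wo = (H - k) // s + 1, (W - k) // s + 1
    out = np.zeros((N, C, Ho, Wo), dtype=xd.dtype)
    for ki in range(k):
        for kj in range(k):
            out += xd[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
    out /= k * k
    res = _make(out, (x,))
    if res._prev:
        def bw(g):
            dx = np.zeros_like(xd)
            gk = g / (k * k)
            for ki in range(k):
                for kj in range(k):
                    dx[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += gk
            x._accum(dx)

        res._backward = bw
    return res


# -- bilinear resampling ------------------------------------------------------

_RESIZE_CACHE: dict = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) bilinear interpolation matrix
    (half-pixel-center convention)."""
    key = (n_in, n_out)
    if key in _RESIZE_CACHE:
        return _RESIZE_CACHE[key]
    dst = np.arange(n_out, dtype=np.float64)
    src = np.clip((dst + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    A = np.zeros((n_out, n_in))
    A[np.arange(n_out), i0] += 1.0 - w1
    A[np.arange(n_out), i1] += w1
    _RESIZE_CACHE[key] = A
    return A


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Resize the last two axes of an NCHW (or CHW-like) tensor bilinearly.

    Separable: out = A_h @ x @ A_w^T. Rows of A sum to one, so constant maps
    are preserved exactly.
    """
    Ho, Wo = out_hw
    H, W = x.data.shape[-2], x.data.shape[-1]
    if (H, W) == (Ho, Wo):
        return x
    Ah = _interp_matrix(H, Ho).astype(x.data.dtype)
    Aw = _interp_matrix(W, Wo).astype(x.data.dtype)
    out = _make(Ah @ x.data @ Aw.T, (x,))
    if out._prev:
        out._backward = lambda g: x._accum(Ah.T @ g @ Aw)
    return out


# -- deformable convolution ---------------------------------------------------

def deform_conv2d(x: Tensor, offsets: Tensor, w: Tensor,
                  b: Tensor | None = None, padding: int = 1) -> Tensor:
    """Deformable 2-D convolution, stride 1.

    `offsets` has 2*kh*kw channels ordered (dy, dx) per kernel position;
    sampling positions are the regular kernel grid plus these offsets,
    evaluated by bilinear interpolation with zero padding. With all offsets
    zero this reduces exactly to `conv2d` with the same kernel.
    """
    xd, od, wd = x.data, offsets.data, w.data
    N, C, H, W = xd.shape
    O, _, kh, kw = wd.shape
    p = padding
    HW = H * W
    xflat = np.ascontiguousarray(xd.transpose(0, 2, 3, 1)).reshape(N * HW, C)
    base = (np.arange(N) * HW)[:, None, None]
    gi = np.arange(H)[None, :, None]
    gj = np.arange(W)[None, None, :]
    out = np.zeros((N, O, HW), dtype=xd.dtype)
    caches = []
    k = 0
    for ki in range(kh):
        for kj in range(kw):
            py = gi + (ki - p) + od[:, 2 * k]
            px = gj + (kj - p) + od[:, 2 * k + 1]
            y0 = np.floor(py).astype(np.int64)
            x0 = np.floor(px).astype(np.int64)
            fy = py - y0
            fx = px - x0
            sampled = np.zeros((N, H, W, C), dtype=xd.dtype)
            corners = []
            for dy in (0, 1):
                for dxo in (0, 1):
                    yc = y0 + dy
                    xc = x0 + dxo
                    valid = (yc >= 0) & (yc < H) & (xc >= 0) & (xc < W)
                    idx = (base + np.clip(yc, 0, H - 1) * W
                           + np.clip(xc, 0, W - 1))
                    v = xflat[idx.reshape(-1)].reshape(N, H, W, C)
                    v *= valid[..., None]
                    wy = fy if dy else 1.0 - fy
                    wx = fx if dxo else 1.0 - fx
                    sampled += v * (wy * wx)[..., None]
                    corners.append((idx, valid, v, wy, wx, dy, dxo))
            out += np.matmul(wd[:, :, ki, kj],
                             sampled.reshape(N, HW, C).transpose(0, 2, 1))
            caches.append((sampled, corners, ki, kj, k))
            k += 1
    out = out.reshape(N, O, H, W)
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)
    parents = [x, offsets, w] + ([b] if b is not None else [])
    res = _make(out, parents)
    if res._prev:
        def bw(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            need_x = x.requires_grad
            need_off = offsets.requires_grad
            gf = np.ascontiguousarray(g).reshape(N, O, HW)
            dof = np.zeros_like(od) if need_off else None
            dw = np.zeros_like(wd) if w.requires_grad else None
            sc_idx, sc_val = [], []
            for sampled, corners, ki, kj, k in caches:
                if dw is not None:
                    dw[:, :, ki, kj] = np.matmul(
                        gf, sampled.reshape(N, HW, C)).sum(axis=0)
                ds = np.matmul(wd[:, :, ki, kj].T, gf)     # (N,C,HW)
                dsT = np.ascontiguousarray(
                    ds.transpose(0, 2, 1)).reshape(N, H, W, C)
                dpy = dpx = None
                for idx, valid, v, wy, wx, dy, dxo in corners:
                    if need_x:
                        sc_idx.append(idx.reshape(-1))
                        sc_val.append(
                            (dsT * (wy * wx)[..., None]
                             * valid[..., None]).reshape(-1, C))
                    if need_off:
                        dot = (dsT * v).sum(axis=-1)       # v already masked
                        sy = 1.0 if dy else -1.0
                        sx = 1.0 if dxo else -1.0
                        ty = dot * sy * wx
                        tx = dot * sx * wy
                        dpy = ty if dpy is None else dpy + ty
                        dpx = tx if dpx is None else dpx + tx
                if need_off:
                    dof[:, 2 * k] = dpy
                    dof[:, 2 * k + 1] = dpx
            if need_x:
                all_idx = np.concatenate(sc_idx)
                all_val = np.concatenate(sc_val)
                dxflat = np.empty((N * HW, C), dtype=xd.dtype)
                for c in range(C):
                    dxflat[:, c] = np.bincount(
                        all_idx, weights=all_val[:, c], minlength=N * HW)
                x._accum(dxflat.reshape(N, H, W, C).transpose(0, 3, 1, 2))
            if need_off:
                offsets._accum(dof)
            if dw is not None:
                w._accum(dw)

        res._backward = bw
    return res


# -- losses -------------------------------------------------------------------

def bce_with_logits(z: Tensor, target: np.ndarray,
                    weight: np.ndarray | None = None) -> Tensor:
    """Numerically stable binary cross-entropy on logits; returns the sum."""
    zd = z.data
    t = np.asarray(target, dtype=zd.dtype)
    loss = np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    if weight is not None:
        loss = loss * weight
    out = _make(np.array(loss.sum(), dtype=zd.dtype), (z,))
    if out._prev:
        def bw(g):
            s = np.empty_like(zd)
            pos = zd >= 0
            s[pos] = 1.0 / (1.0 + np.exp(-zd[pos]))
            e = np.exp(zd[~pos])
            s[~pos] = e / (1.0 + e)
            dz = (s - t) * g
            if weight is not None:
                dz = dz * weight
            z._accum(dz)

        out._backward = bw
    return out


# -- optimizer ----------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
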