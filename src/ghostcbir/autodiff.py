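"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the primitives the backbone needs: elementwise arithmetic,
matmul, reductions, grouped 2-D convolution (im2col), deformable 2-D
convolution with bilinear sampling and learned offsets, average pooling and
separable bilinear resampling.  Everything is float64 and single-threaded, so
a forward/backward pass is bit-reproducible given fixed parameters.

Gradients flow through a tape of closures: each operation returns a
:class:`Tensor` whose ``_backward`` accumulates into its parents' ``grad``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "deform_conv2d",
    "avg_pool2d",
    "bilinear_resize",
    "relu",
    "sigmoid",
    "log_softmax",
]


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        count = _axis_count(self.shape, axis)
        return mul(tsum(self, axis=axis, keepdims=keepdims), 1.0 / count)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _axis_count(shape, axis) -> float:
    if axis is None:
        return float(np.prod(shape)) if shape else 1.0
    if isinstance(axis, int):
        axis = (axis,)
    return float(np.prod([shape[a] for a in axis]))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def power(a, exponent) -> Tensor:
    a = _wrap(a)
    exponent = float(exponent)
    out = Tensor(a.data ** exponent, parents=(a,))

    def backward(g):
        a._accum(g * exponent * a.data ** (exponent - 1.0))

    out._backward = backward if out.requires_grad else None
    return out


def texp(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.exp(a.data), parents=(a,))

    def backward(g):
        a._accum(g * out.data)

    out._backward = backward if out.requires_grad else None
    return out


def tlog(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def backward(g):
        a._accum(g / a.data)

    out._backward = backward if out.requires_grad else None
    return out


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), parents=(a,))

    def backward(g):
        a._accum(g * mask)

    out._backward = backward if out.requires_grad else None
    return out


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    # numerically stable logistic
    s = np.empty_like(a.data)
    pos = a.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    s[~pos] = ez / (1.0 + ez)
    out = Tensor(s, parents=(a,))

    def backward(g):
        a._accum(g * out.data * (1.0 - out.data))

    out._backward = backward if out.requires_grad else None
    return out


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            for ax in sorted(a.data.ndim + ax if ax < 0 else ax for ax in axes):
                g = np.expand_dims(g, ax)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    out._backward = backward if out.requires_grad else None
    return out


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        a._accum(g.reshape(a.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out._backward = backward if out.requires_grad else None
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = backward if out.requires_grad else None
    return out


def log_softmax(z: Tensor, axis: int = -1) -> Tensor:
    """Max-shifted log-softmax along ``axis``."""
    z = _wrap(z)
    shift = Tensor(z.data.max(axis=axis, keepdims=True))  # constant, no grad
    zs = z - shift
    return zs - tlog(tsum(texp(zs), axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# spatial operations (NCHW layout)
# ---------------------------------------------------------------------------

def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else (int(v[0]), int(v[1]))


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    N, C, Hp, Wp = xp.shape
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (N, C, kh, kw, Ho, Wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(view).reshape(N, C * kh * kw, Ho * Wo), Ho, Wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, ph: int, pw: int):
    N, C, H, W = xshape
    Hp, Wp = H + 2 * ph, W + 2 * pw
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    dxp = np.zeros((N, C, Hp, Wp))
    d6 = dcols.reshape(N, C, kh, kw, Ho, Wo)
    for ky in range(kh):
        for kx in range(kw):
            dxp[:, :, ky:ky + Ho * stride:stride, kx:kx + Wo * stride:stride] += d6[:, :, ky, kx]
    if ph or pw:
        dxp = dxp[:, :, ph:ph + H, pw:pw + W]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding=0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution, NCHW, kernel (Cout, Cin/groups, kh, kw)."""
    x, w = _wrap(x), _wrap(w)
    N, C, H, W = x.data.shape
    Cout, Cin_g, kh, kw = w.data.shape
    ph, pw = _pair(padding)
    if C != Cin_g * groups or Cout % groups:
        raise ValueError(
            f"channel mismatch: x has {C} channels, kernel expects {Cin_g * groups} "
            f"({groups} groups)"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols, Ho, Wo = _im2col(xp, kh, kw, stride)
    colsg = cols.reshape(N, groups, Cin_g * kh * kw, Ho * Wo)
    wg = w.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
    y = np.einsum("goc,ngcl->ngol", wg, colsg, optimize=True).reshape(N, Cout, Ho, Wo)
    parents = (x, w) if b is None else (x, w, _wrap(b))
    if b is not None:
        bt = parents[2]
        y = y + bt.data.reshape(1, Cout, 1, 1)
    out = Tensor(y, parents=parents)

    def backward(g):
        gg = g.reshape(N, groups, Cout // groups, Ho * Wo)
        if w.requires_grad:
            dw = np.einsum("ngol,ngcl->goc", gg, colsg, optimize=True)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and parents[2].requires_grad:
            parents[2]._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("goc,ngol->ngcl", wg, gg, optimize=True)
            x._accum(_col2im(dcols.reshape(N, C * kh * kw, Ho * Wo),
                             x.data.shape, kh, kw, stride, ph, pw))

    out._backward = backward if out.requires_grad else None
    return out


def _bilinear_gather(xg: np.ndarray, py: np.ndarray, px: np.ndarray, H: int, W: int):
    """Sample ``xg`` (..., Cpg, H*W) at fractional (py, px); zero outside.

    Returns the sampled values plus the per-corner pieces needed for the
    backward pass: integer corner indices, validity masks and fractions.
    """
    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    fy = py - y0
    fx = px - x0
    corners = []
    vals = 0.0
    for dy, dx, wy, wx in ((0, 0, 1 - fy, 1 - fx), (0, 1, 1 - fy, fx),
                           (1, 0, fy, 1 - fx), (1, 1, fy, fx)):
        yc = y0 + dy
        xc = x0 + dx
        valid = (yc >= 0) & (yc < H) & (xc >= 0) & (xc < W)
        idx = np.clip(yc, 0, H - 1) * W + np.clip(xc, 0, W - 1)
        v = np.take_along_axis(xg, idx[:, :, None, :], axis=3)
        v = v * valid[:, :, None, :]
        weight = (wy * wx) * valid
        vals = vals + weight[:, :, None, :] * v
        corners.append((idx, valid, v, dy, dx))
    return vals, corners, fy, fx


def deform_conv2d(x: Tensor, w: Tensor, b: Tensor | None, offsets: Tensor,
                  stride: int = 1, padding: int = 1, groups: int = 1,
                  offset_groups: int = 1) -> Tensor:
    """Deformable 2-D convolution.

    The sampling grid of each kernel tap is displaced by a learned offset and
    the input is read at the fractional position by bilinear interpolation
    (zero outside the borders).  ``offsets`` has ``2*K*K*offset_groups``
    channels laid out as [group, tap, (dy, dx)] over the output locations;
    channels within an offset group share the same displacement field.
    """
    x, w, offsets = _wrap(x), _wrap(w), _wrap(offsets)
    if not np.all(np.isfinite(offsets.data)):
        raise FloatingPointError("non-finite offsets passed to deform_conv2d")
    N, C, H, W = x.data.shape
    Cout, Cin_g, K, _ = w.data.shape
    OG = offset_groups
    if C % OG:
        raise ValueError("input channels must divide evenly into offset groups")
    if C != Cin_g * groups or Cout % groups:
        raise ValueError("channel mismatch between input and kernel/groups")
    KK = K * K
    if offsets.data.shape[1] != 2 * KK * OG:
        raise ValueError(
            f"offset field must have {2 * KK * OG} channels, got {offsets.data.shape[1]}"
        )
    Ho, Wo = offsets.data.shape[2], offsets.data.shape[3]
    Cpg = C // OG

    off = offsets.data.reshape(N, OG, KK, 2, Ho, Wo)
    ky, kx = np.divmod(np.arange(KK), K)
    oy = np.arange(Ho) * stride - padding
    ox = np.arange(Wo) * stride - padding
    py = (off[:, :, :, 0] + oy[None, None, None, :, None] + ky[None, None, :, None, None])
    px = (off[:, :, :, 1] + ox[None, None, None, None, :] + kx[None, None, :, None, None])
    py = py.reshape(N, OG, KK * Ho * Wo)
    px = px.reshape(N, OG, KK * Ho * Wo)

    xg = x.data.reshape(N, OG, Cpg, H * W)
    S, corners, fy, fx = _bilinear_gather(xg, py, px, H, W)
    # S: (N, OG, Cpg, KK*Ho*Wo) -> (N, groups, Cin_g*KK, Ho*Wo)
    S5 = S.reshape(N, C, KK, Ho * Wo)
    Sg = S5.reshape(N, groups, Cin_g, KK, Ho * Wo).reshape(N, groups, Cin_g * KK, Ho * Wo)
    wg = w.data.reshape(groups, Cout // groups, Cin_g * KK)
    y = np.einsum("goc,ngcl->ngol", wg, Sg, optimize=True).reshape(N, Cout, Ho, Wo)
    parents = (x, w, offsets) if b is None else (x, w, offsets, _wrap(b))
    if b is not None:
        y = y + parents[3].data.reshape(1, Cout, 1, 1)
    out = Tensor(y, parents=parents)

    def backward(g):
        gg = g.reshape(N, groups, Cout // groups, Ho * Wo)
        if w.requires_grad:
            w._accum(np.einsum("ngol,ngcl->goc", gg, Sg, optimize=True).reshape(w.data.shape))
        if b is not None and parents[3].requires_grad:
            parents[3]._accum(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_off = offsets.requires_grad
        if not (need_x or need_off):
            return
        dSg = np.einsum("goc,ngol->ngcl", wg, gg, optimize=True)
        dS = dSg.reshape(N, groups, Cin_g, KK, Ho * Wo).reshape(N, C, KK, Ho * Wo)
        dS = dS.reshape(N, OG, Cpg, KK * Ho * Wo)
        if need_x:
            dxg = np.zeros((N, OG, Cpg, H * W))
        dpy = np.zeros((N, OG, KK * Ho * Wo)) if need_off else None
        dpx = np.zeros((N, OG, KK * Ho * Wo)) if need_off else None
        for idx, valid, v, dy, dx in corners:
            wy = fy if dy else (1.0 - fy)
            wx = fx if dx else (1.0 - fx)
            if need_x:
                contrib = dS * ((wy * wx) * valid)[:, :, None, :]
                # scatter-add into flat (N*OG*Cpg, H*W)
                flat_idx = (idx[:, :, None, :] +
                            (np.arange(N * OG * Cpg).reshape(N, OG, Cpg, 1) * (H * W)))
                np.add.at(dxg.reshape(-1), flat_idx.ravel(), contrib.ravel())
            if need_off:
                dv = (dS * v).sum(axis=2)  # sum over channels in the offset group
                sy = 1.0 if dy else -1.0
                sx = 1.0 if dx else -1.0
                dpy += dv * (sy * wx) * valid
                dpx += dv * (wy * sx) * valid
        if need_x:
            x._accum(dxg.reshape(x.data.shape))
        if need_off:
            doff = np.stack(
                [dpy.reshape(N, OG, KK, Ho, Wo), dpx.reshape(N, OG, KK, Ho, Wo)], axis=3
            )
            offsets._accum(doff.reshape(offsets.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k average pooling (trailing remainder cropped)."""
    x = _wrap(x)
    N, C, H, W = x.data.shape
    Ho, Wo = H // k, W // k
    if Ho < 1 or Wo < 1:
        raise ValueError("feature map smaller than the pooling window")
    xc = x.data[:, :, :Ho * k, :Wo * k]
    y = xc.reshape(N, C, Ho, k, Wo, k).mean(axis=(3, 5))
    out = Tensor(y, parents=(x,))

    def backward(g):
        dx = np.zeros_like(x.data)
        dx[:, :, :Ho * k, :Wo * k] = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(dx)

    out._backward = backward if out.requires_grad else None
    return out


def _resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    M = np.zeros((n_out, n_in))
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    M[np.arange(n_out), i0] += 1.0 - f
    M[np.arange(n_out), i1] += f
    return M


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resampling to (out_h, out_w)."""
    x = _wrap(x)
    N, C, H, W = x.data.shape
    Ry = _resize_matrix(out_h, H)
    Rx = _resize_matrix(out_w, W)
    y = np.einsum("oh,nchw,pw->ncop", Ry, x.data, Rx, optimize=True)
    out = Tensor(y, parents=(x,))

    def backward(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", Ry, g, Rx, optimize=True))

    out._backward = backward if out.requires_grad else None
    return out
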