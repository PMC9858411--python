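"""Differentiable array operations (NCHW layout, float32).

Convolutions use im2col + BLAS sgemm, the throughput-optimal route for a
CPU-only NumPy stack. Backward passes recompute the column matrix instead of
caching it, trading a cheap re-materialisation for a flat memory profile.
Padding follows the TensorFlow 'SAME' convention (extra pixel on the
bottom/right for odd totals) so stride-2 layers halve even inputs exactly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "add", "mul", "concat", "relu", "relu6", "sigmoid", "silu",
    "conv2d", "conv_transpose2d", "batchnorm2d", "maxpool2d", "avgpool2d",
    "global_avg_pool", "upsample_nearest", "upsample_bilinear",
    "bce_mean", "same_padding",
]


class ShapeError(ValueError):
    """Spatial/channel dimensions incompatible with the requested operation."""


# ---------------------------------------------------------------------------
# padding helpers
# ---------------------------------------------------------------------------

def same_padding(size: int, k: int, s: int) -> tuple[int, int]:
    """TF-style 'SAME' padding (begin, end) for one spatial dimension."""
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    beg = total // 2
    return beg, total - beg


def _resolve_padding(h, w, kh, kw, sh, sw, padding):
    if padding == "same":
        return (*same_padding(h, kh, sh), *same_padding(w, kw, sw))
    if padding == "valid":
        return (0, 0, 0, 0)
    raise ValueError(f"unknown padding {padding!r}")


def _pad_nchw(x, pt, pb, pl, pr):
    if pt or pb or pl or pr:
        return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    return x


def _im2col(x, kh, kw, sh, sw):
    """(B,C,H,W) -> columns (B, C*kh*kw, OH*OW); x must be pre-padded.

    Built with kh*kw strided slice copies (fast memcpy-like paths) rather
    than one large 6-D transpose, which NumPy executes far slower.
    """
    b, c, h, w = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    cols = np.empty((b, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        hi = i + sh * oh
        for j in range(kw):
            wj = j + sw * ow
            cols[:, :, i, j] = x[:, :, i:hi:sh, j:wj:sw]
    return cols.reshape(b, c * kh * kw, oh * ow), oh, ow


def _col2im(cols, x_shape, kh, kw, sh, sw):
    """Scatter-add columns (B, C*kh*kw, OH*OW) back onto the padded image."""
    b, c, h, w = x_shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    out = np.zeros(x_shape, dtype=np.float32)
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        hi = i + sh * oh
        for j in range(kw):
            wj = j + sw * ow
            out[:, :, i:hi:sh, j:wj:sw] += cols[:, :, i, j]
    return out


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ShapeError(f"add: shape mismatch {a.shape} vs {b.shape}")
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor._result(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Broadcasting elementwise product (used by squeeze-excite gating)."""
    out_data = a.data * b.data

    def _reduce(g, shape):
        extra = g.ndim - len(shape)
        if extra:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] > 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g

    def backward(g):
        if a.requires_grad:
            a._accumulate(_reduce(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_reduce(g * a.data, b.shape))

    return Tensor._result(out_data, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    shapes = [t.shape for t in tensors]
    ref = list(shapes[0])
    for s in shapes[1:]:
        chk = list(s)
        chk[axis] = ref[axis]
        if chk != ref:
            raise ShapeError(f"concat: incompatible shapes {shapes}")
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [s[axis] for s in shapes]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._result(out_data, tuple(tensors), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, np.float32(0.0))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._result(out_data, (x,), backward)


def relu6(x: Tensor) -> Tensor:
    out_data = np.clip(x.data, 0.0, 6.0)
    mask = (x.data > 0) & (x.data < 6)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._result(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = _sigmoid(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (x,), backward)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x) — the 'Swish' activation used by EfficientNet."""
    s = _sigmoid(x.data)
    out_data = x.data * s

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (s + x.data * s * (1.0 - s)))

    return Tensor._result(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1,
           padding: str = "same", groups: int = 1) -> Tensor:
    """2-D cross-correlation; w has shape (Cout, Cin/groups, kh, kw)."""
    sh, sw = (stride, stride) if np.isscalar(stride) else stride
    cout, cin_g, kh, kw = w.shape
    bsz, cin, h, wd = x.shape
    if cin != cin_g * groups:
        raise ShapeError(f"conv2d: {cin} input channels, weight expects {cin_g * groups}")
    pt, pb, pl, pr = _resolve_padding(h, wd, kh, kw, sh, sw, padding)
    xp = _pad_nchw(x.data, pt, pb, pl, pr)

    if groups == 1:
        cols, oh, ow = _im2col(xp, kh, kw, sh, sw)
        w2 = w.data.reshape(cout, cin * kh * kw)
        y = np.matmul(w2, cols).reshape(bsz, cout, oh, ow)
        del cols  # backward re-materialises columns: flat memory profile
    elif groups == cin and cin_g == 1:
        # depthwise: per-channel patch reduction, no gemm needed
        v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        oh, ow = v.shape[2], v.shape[3]
        y = np.einsum("bchwij,cij->bchw", v, w.data.reshape(cout, kh, kw),
                      optimize=True).astype(np.float32)
    else:
        raise NotImplementedError("only groups=1 or full depthwise supported")
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)

    def backward(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        goh, gow = g.shape[2], g.shape[3]
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            gflat = g.reshape(bsz, cout, goh * gow)
            if w.requires_grad:
                cols2, _, _ = _im2col(xp, kh, kw, sh, sw)
                gw = np.matmul(gflat, cols2.swapaxes(1, 2)).sum(axis=0)
                del cols2
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                w2 = w.data.reshape(cout, cin * kh * kw)
                dcols = np.matmul(w2.T, gflat)
                dxp = _col2im(dcols, xp.shape, kh, kw, sh, sw)
                x._accumulate(dxp[:, :, pt:pt + h, pl:pl + wd])
        else:
            v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
            if w.requires_grad:
                gw = np.einsum("bchw,bchwij->cij", g, v, optimize=True)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                wk = w.data.reshape(cin, kh, kw)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + sh * goh:sh, j:j + sw * gow:sw] += (
                            g * wk[None, :, i:i + 1, j:j + 1])
                x._accumulate(dxp[:, :, pt:pt + h, pl:pl + wd])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: str = "same") -> Tensor:
    """Transposed convolution; w has shape (Cin, Cout, kh, kw).

    'same' yields output exactly stride x input size (the Table-2 decoder
    contract: 4x4 kernels, stride 2, output doubled).
    """
    s = stride
    cin, cout, kh, kw = w.shape
    bsz, cx, h, wd = x.shape
    if cx != cin:
        raise ShapeError(f"conv_transpose2d: {cx} input channels, weight expects {cin}")
    if padding != "same":
        raise NotImplementedError("only 'same' transposed convolution is used")
    # input pixel (p,q) scatters w[:, o] onto out[p*s - pad + a, q*s - pad + c];
    # realised as one gemm + a col2im scatter onto a padded canvas
    pt, _ = same_padding(h * s, kh, s)
    pl, _ = same_padding(wd * s, kw, s)
    pad_shape = (bsz, cout, (h - 1) * s + kh, (wd - 1) * s + kw)
    xflat = x.data.reshape(bsz, cin, h * wd)
    w2 = w.data.reshape(cin, cout * kh * kw)
    cols = np.matmul(w2.T, xflat)  # (B, cout*kh*kw, h*wd)
    y = _col2im(cols, pad_shape, kh, kw, s, s)[
        :, :, pt:pt + h * s, pl:pl + wd * s]
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)

    def backward(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if not (w.requires_grad or x.requires_grad):
            return
        gpad = _pad_nchw(g, pt, pad_shape[2] - h * s - pt,
                         pl, pad_shape[3] - wd * s - pl)
        dcols, _, _ = _im2col(gpad, kh, kw, s, s)  # (B, cout*kh*kw, h*wd)
        if w.requires_grad:
            gw = np.matmul(xflat, dcols.swapaxes(1, 2)).sum(axis=0)
            w._accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            dx = np.matmul(w2, dcols).reshape(bsz, cin, h, wd)
            x._accumulate(dx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(y, parents, backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
                training: bool, momentum: float = 0.99, eps: float = 1e-3) -> Tensor:
    c = x.shape[1]
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mean
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    y = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(np.einsum("bchw,bchw->c", g, xhat, optimize=True))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            ginv = (gamma.data * inv).reshape(1, c, 1, 1)
            if training:
                n = g.shape[0] * g.shape[2] * g.shape[3]
                gsum = g.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                gx = np.einsum("bchw,bchw->c", g, xhat, optimize=True).reshape(1, c, 1, 1)
                dx = ginv * (g - gsum / n - xhat * gx / n)
            else:
                dx = ginv * g
            x._accumulate(np.asarray(dx, dtype=np.float32))

    return Tensor._result(np.asarray(y, dtype=np.float32), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def maxpool2d(x: Tensor, kernel: int = 2, stride: int | None = None,
              padding: str = "valid") -> Tensor:
    k, s = kernel, stride or kernel
    bsz, c, h, w = x.shape
    pt, pb, pl, pr = _resolve_padding(h, w, k, k, s, s, padding)
    xp = _pad_nchw(x.data, pt, pb, pl, pr)
    if padding == "same" and (pt or pb or pl or pr):
        # pad with -inf so padding never wins the max
        xp = xp.copy()
        if pt:
            xp[:, :, :pt] = -np.inf
        if pb:
            xp[:, :, -pb:] = -np.inf
        if pl:
            xp[:, :, :, :pl] = -np.inf
        if pr:
            xp[:, :, :, -pr:] = -np.inf
    v = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    oh, ow = v.shape[2], v.shape[3]
    vflat = v.reshape(bsz, c, oh, ow, k * k)
    arg = vflat.argmax(axis=-1)
    y = np.take_along_axis(vflat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros(xp.shape, dtype=np.float32)
        ki, kj = np.unravel_index(arg, (k, k))
        bi, ci, oi, oj = np.indices(arg.shape, sparse=False)
        rows = oi * s + ki
        cols_ = oj * s + kj
        np.add.at(dxp, (bi, ci, rows, cols_), g)
        x._accumulate(dxp[:, :, pt:pt + h, pl:pl + w])

    return Tensor._result(np.ascontiguousarray(y), (x,), backward)


def avgpool2d(x: Tensor, kernel: int = 3, stride: int = 1,
              padding: str = "same") -> Tensor:
    """Uniform average pooling as a fixed depthwise convolution.

    Zero padding is included in the average (deviates from Keras at borders
    only; documented).
    """
    c = x.shape[1]
    w = Tensor(np.full((c, 1, kernel, kernel), 1.0 / (kernel * kernel), dtype=np.float32))
    return conv2d(x, w, stride=stride, padding=padding, groups=c)


def global_avg_pool(x: Tensor) -> Tensor:
    bsz, c, h, w = x.shape
    y = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / (h * w), x.shape).astype(np.float32))

    return Tensor._result(y, (x,), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    f = int(factor)
    y = x.data.repeat(f, axis=2).repeat(f, axis=3)

    def backward(g):
        if x.requires_grad:
            bsz, c, oh, ow = g.shape
            gr = g.reshape(bsz, c, oh // f, f, ow // f, f).sum(axis=(3, 5))
            x._accumulate(gr)

    return Tensor._result(y, (x,), backward)


def _bilinear_matrix(n_in: int, factor: int) -> np.ndarray:
    """Half-pixel bilinear interpolation weights, (n_in*factor, n_in)."""
    n_out = n_in * factor
    m = np.zeros((n_out, n_in), dtype=np.float32)
    for j in range(n_out):
        src = (j + 0.5) / factor - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[j, i0c] += 1.0 - t
        m[j, i1c] += t
    return m


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    bsz, c, h, w = x.shape
    mh = _bilinear_matrix(h, factor)
    mw = _bilinear_matrix(w, factor)
    y = np.einsum("oh,bchw,pw->bcop", mh, x.data, mw, optimize=True).astype(np.float32)

    def backward(g):
        if x.requires_grad:
            dx = np.einsum("oh,bcop,pw->bchw", mh, g, mw, optimize=True)
            x._accumulate(dx.astype(np.float32))

    return Tensor._result(y, (x,), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_mean(p: Tensor, y: np.ndarray, eps: float = 1e-7,
             reduction: str = "mean") -> Tensor:
    """Binary cross-entropy of probabilities p against binary targets y.

    p is clipped to [eps, 1-eps] before the logs; gradients are zero where
    the clip is active.
    """
    y = np.asarray(y, dtype=np.float32)
    if y.shape != p.shape:
        raise ShapeError(f"bce: target shape {y.shape} != prediction shape {p.shape}")
    pc = np.clip(p.data, eps, 1.0 - eps)
    ll = -(y * np.log(pc) + (1.0 - y) * np.log1p(-pc))
    n = ll.size if reduction == "mean" else 1
    val = ll.sum(dtype=np.float64) / n

    def backward(g):
        if p.requires_grad:
            inside = (p.data > eps) & (p.data < 1.0 - eps)
            dp = (pc - y) / (pc * (1.0 - pc)) / n
            p._accumulate((g * dp * inside).astype(np.float32))

    return Tensor._result(np.float32(val), (p,), backward)
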