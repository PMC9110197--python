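"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape-based engine sized for small encoder-decoder CNNs on CPU:
tensors wrap float32/float64 numpy arrays, every primitive op records a
closure that accumulates gradients into its parents, and ``backward`` runs
the tape in reverse topological order. Only the primitives the segmentation
networks need are implemented; each one carries a hand-written backward
(checked against finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "sigmoid",
    "relu",
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "global_avg_pool2d",
    "global_max_pool2d",
    "channel_mean",
    "channel_max",
    "bilinear_resize",
    "batch_norm2d",
    "linear",
    "dropout",
    "cross_entropy_with_logits",
]


class Tensor:
    """A numpy array plus gradient bookkeeping.

    Parameters
    ----------
    data : array_like
        Values; converted to a numpy array (float preserved, not copied
        when already an ndarray).
    requires_grad : bool
        Whether gradients should be accumulated into ``grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- autograd -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this tensor.

        ``grad`` defaults to ones (scalar losses pass nothing).
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        return _add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x))


def _make(data, parents, backward) -> Tensor:
    """Build a result tensor; drop the tape when no parent needs grads."""
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (channel axis by default)."""
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tensors, backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    # stable logistic: exp of a non-positive argument never overflows
    e = np.exp(-np.abs(x.data))
    s = np.where(x.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e)).astype(x.data.dtype)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


# -----------------------------------------------------------------------------
# Convolution via im2col / col2im
# -----------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    """(N,C,H,W) -> (N, Ho*Wo, C*kh*kw) patch matrix."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return cols, ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, padding: int):
    """Scatter-add patches back; adjoint of :func:`_im2col`."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    if padding:
        out = out[:, :, padding:hp - padding, padding:wp - padding]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation, weight shape (C_out, C_in, kh, kw)."""
    x = _as_tensor(x)
    co, ci, kh, kw = weight.data.shape
    n, _, h, w = x.data.shape
    wmat = weight.data.reshape(co, ci * kh * kw)

    if kh == kw == 1 and stride == 1 and padding == 0:
        # pointwise fast path: a single matmul over flattened pixels
        xflat = x.data.reshape(n, ci, h * w)
        out = np.matmul(wmat[None], xflat)  # (N, Cout, HW)
        if bias is not None:
            out += bias.data[None, :, None]
        out_data = out.reshape(n, co, h, w)

        def backward(g):
            gflat = g.reshape(n, co, h * w)
            if weight.requires_grad:
                gw = np.tensordot(gflat, xflat, axes=([0, 2], [0, 2]))
                weight._accumulate(gw.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(gflat.sum(axis=(0, 2)))
            if x.requires_grad:
                x._accumulate(np.matmul(wmat.T[None], gflat).reshape(x.data.shape))

        parents = (x, weight) if bias is None else (x, weight, bias)
        return _make(out_data, parents, backward)

    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    out = cols @ wmat.T  # (N, Ho*Wo, Cout)
    if bias is not None:
        out = out + bias.data
    out_data = out.transpose(0, 2, 1).reshape(n, co, ho, wo)

    def backward(g):
        gmat = np.ascontiguousarray(
            g.reshape(n, co, ho * wo).transpose(0, 2, 1))  # (N, HoWo, Cout)
        if weight.requires_grad:
            gw = np.tensordot(gmat, cols, axes=([0, 1], [0, 1]))  # (Cout, Ckhkw)
            weight._accumulate(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = gmat @ wmat  # (N, HoWo, C*kh*kw)
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, padding))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out_data, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 2, output_padding: int = 0) -> Tensor:
    """Transpose convolution, weight shape (C_in, C_out, kh, kw).

    Output spatial size is ``(H-1)*stride + kh + output_padding``; the
    trailing ``output_padding`` rows/columns receive only the bias (used to
    hit odd decoder sizes such as 12 -> 25).
    """
    x = _as_tensor(x)
    ci, co, kh, kw = weight.data.shape
    n, _, h, w = x.data.shape
    ho = (h - 1) * stride + kh + output_padding
    wo = (w - 1) * stride + kw + output_padding
    xmat = x.data.reshape(n, ci, h * w).transpose(0, 2, 1)  # (N, HW, Cin)
    wmat = weight.data.reshape(ci, co * kh * kw)
    cols = xmat @ wmat  # (N, HW, Cout*kh*kw)
    base = _col2im(cols, (n, co, ho, wo), kh, kw, stride, 0) if output_padding == 0 else None
    if base is None:
        # scatter into the un-padded grid, then zero-pad the trailing edge
        core_h = (h - 1) * stride + kh
        core_w = (w - 1) * stride + kw
        core = _col2im(cols, (n, co, core_h, core_w), kh, kw, stride, 0)
        base = np.zeros((n, co, ho, wo), dtype=core.dtype)
        base[:, :, :core_h, :core_w] = core
    out_data = base
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, co, 1, 1)

    def backward(g):
        core_h = (h - 1) * stride + kh
        core_w = (w - 1) * stride + kw
        gcore = g[:, :, :core_h, :core_w]
        gcols, _, _ = _im2col(gcore, kh, kw, stride, 0)  # (N, HW, Cout*kh*kw)
        if weight.requires_grad:
            gw = np.tensordot(xmat, gcols, axes=([0, 1], [0, 1]))  # (Cin, Coutkhkw)
            weight._accumulate(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = gcols @ wmat.T  # (N, HW, Cin)
            x._accumulate(gx.transpose(0, 2, 1).reshape(x.data.shape))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out_data, parents, backward)


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling with floor semantics (50 -> 25 -> 12 ...)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    ho, wo = h // size, w // size
    xc = x.data[:, :, :ho * size, :wo * size]
    patches = xc.reshape(n, c, ho, size, wo, size).transpose(0, 1, 2, 4, 3, 5)
    flat = patches.reshape(n, c, ho, wo, size * size)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gflat = np.zeros((n, c, ho, wo, size * size), dtype=g.dtype)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gp = gflat.reshape(n, c, ho, wo, size, size).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(x.data)
        gx[:, :, :ho * size, :wo * size] = gp.reshape(n, c, ho * size, wo * size)
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def global_avg_pool2d(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1) spatial mean."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).copy())

    return _make(out_data, (x,), backward)


def global_max_pool2d(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1) spatial max."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1).reshape(n, c, 1, 1)

    def backward(g):
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g.reshape(n, c, 1), axis=-1)
        x._accumulate(gflat.reshape(x.data.shape))

    return _make(out_data, (x,), backward)


def channel_mean(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,1,H,W) mean across channels."""
    x = _as_tensor(x)
    c = x.data.shape[1]
    out_data = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / c, x.data.shape).copy())

    return _make(out_data, (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,1,H,W) max across channels."""
    x = _as_tensor(x)
    idx = x.data.argmax(axis=1, keepdims=True)
    out_data = np.take_along_axis(x.data, idx, axis=1)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=1)
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x: Tensor, out_size: int) -> Tensor:
    """Separable bilinear resampling to ``out_size`` x ``out_size``."""
    x = _as_tensor(x)
    h, w = x.data.shape[2], x.data.shape[3]
    rm = _interp_matrix(h, out_size, x.data.dtype)
    cm = _interp_matrix(w, out_size, x.data.dtype)
    out_data = np.matmul(np.matmul(rm, x.data), cm.T)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.matmul(np.matmul(rm.T, g), cm))

    return _make(out_data, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    Updates ``running_mean``/``running_var`` in place when training.
    """
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = n * h * w
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased estimate feeds the running variance, biased feeds the norm
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gs = gamma.data.reshape(1, c, 1, 1)
        if training:
            m = n * h * w
            gxhat = g * gs
            sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (inv_std.reshape(1, c, 1, 1) / m) * (m * gxhat - sum_g - xhat * sum_gx)
        else:
            gx = g * gs * inv_std.reshape(1, c, 1, 1)
        x._accumulate(gx)

    return _make(out_data, (x, gamma, beta), backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Affine map, x (N, F_in), weight (F_out, F_in)."""
    x = _as_tensor(x)
    out = x.data @ weight.data.T
    if bias is not None:
        out = out + bias.data

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(g.T @ x.data)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=0))
        if x.requires_grad:
            x._accumulate(g @ weight.data)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    x = _as_tensor(x)
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out_data = x.data * keep

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return _make(out_data, (x,), backward)


def cross_entropy_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy.

    logits: (N, K, H, W); target: (N, H, W) integer class labels.
    """
    logits = _as_tensor(logits)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp  # (N, K, H, W)
    tgt = np.asarray(target, dtype=np.int64)
    picked = np.take_along_axis(logp, tgt[:, None, :, :], axis=1)[:, 0]
    npix = picked.size
    loss = -picked.sum() / npix

    def backward(g):
        if not logits.requires_grad:
            return
        prob = np.exp(logp)
        onehot = np.zeros_like(prob)
        np.put_along_axis(onehot, tgt[:, None, :, :], 1.0, axis=1)
        logits._accumulate(g * (prob - onehot) / npix)

    return _make(np.asarray(loss), (logits,), backward)
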