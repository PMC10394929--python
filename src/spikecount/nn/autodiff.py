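"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the segmentation
network needs: broadcast arithmetic, activations, 2-D convolution (im2col),
batch normalization, axis reductions, concatenation, bilinear upsampling and
the softmax cross-entropy loss.  Gradients are accumulated on :class:`Tensor`
objects by walking the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "linear",
    "conv2d",
    "batch_norm2d",
    "reduce_mean",
    "reduce_max",
    "reduce_sum",
    "concat",
    "upsample_bilinear",
    "softmax_cross_entropy",
    "reshape",
]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Backpropagate from this node through the whole tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        order = _topo_order(self)
        self.accumulate(grad)
        for node in order:
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators (constants auto-wrapped)
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _topo_order(root):
    """Reverse topological order of the tape rooted at *root* (iterative DFS)."""
    order, visited = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in visited and (p.requires_grad or p._parents):
                stack.append((p, False))
    return order[::-1]


def _unbroadcast(g, shape):
    """Sum *g* down to *shape* (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad or b._parents:
            b.accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad or b._parents:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x.accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x.accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        x.accumulate(g.reshape(old))

    return Tensor(out_data, parents=(x,), backward=backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (N, Cin) @ w.T with w: (Cout, Cin), optional bias (Cout,)."""
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        x.accumulate(g @ w.data)
        w.accumulate(g.T @ x.data)
        if b is not None:
            b.accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    x: (N, Cin, H, W); w: (Cout, Cin, KH, KW); b: (Cout,) or None.
    """
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, kernel expects {cin_w}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho, wo = (hp - kh) // s + 1, (wp - kw) // s + 1
    # windows: (N, Cin, Ho, Wo, KH, KW)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]
    out_data = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data[None, :, None, None]

    def backward(g):
        # g: (N, Cout, Ho, Wo)
        gt = g.transpose(0, 2, 3, 1)  # (N, Ho, Wo, Cout)
        gw = np.tensordot(gt, win, axes=([0, 1, 2], [0, 2, 3]))  # (Cout,Cin,KH,KW)
        w.accumulate(gw)
        if b is not None:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gcol = np.tensordot(gt, w.data, axes=([3], [0]))  # (N,Ho,Wo,Cin,KH,KW)
            gxp = np.zeros((n, cin, hp, wp), dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += (
                        gcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            x.accumulate(gxp[:, :, p : hp - p, p : wp - p] if p else gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics normalize the activations and the
    running buffers are updated in place (unbiased variance, as is
    conventional); in evaluation mode the buffers are used.
    """
    n, c, h, w = x.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))  # biased, used for normalization
        m = n * h * w
        unbiased = var * m / max(m - 1, 1)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta.accumulate(g.sum(axis=(0, 2, 3)))
        if not (x.requires_grad or x._parents):
            return
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            m = n * h * w
            gsum = gxhat.sum(axis=(0, 2, 3))
            gxsum = (gxhat * xhat).sum(axis=(0, 2, 3))
            gx = (
                gxhat
                - gsum[None, :, None, None] / m
                - xhat * gxsum[None, :, None, None] / m
            ) * inv_std[None, :, None, None]
        else:
            gx = gxhat * inv_std[None, :, None, None]
        x.accumulate(gx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def reduce_mean(x: Tensor, axes, keepdims=False) -> Tensor:
    axes = tuple(axes) if not isinstance(axes, int) else (axes,)
    out_data = x.data.mean(axis=axes, keepdims=keepdims)
    count = int(np.prod([x.shape[a] for a in axes]))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        x.accumulate(np.broadcast_to(g / count, x.shape).copy())

    return Tensor(out_data, parents=(x,), backward=backward)


def reduce_sum(x: Tensor, axes=None, keepdims=False) -> Tensor:
    if axes is None:
        axes = tuple(range(x.ndim))
    axes = tuple(axes) if not isinstance(axes, int) else (axes,)
    out_data = x.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        x.accumulate(np.broadcast_to(g, x.shape).copy())

    return Tensor(out_data, parents=(x,), backward=backward)


def reduce_max(x: Tensor, axes, keepdims=False) -> Tensor:
    """Max over *axes*; ties send the full gradient to the first maximum."""
    axes = tuple(axes) if not isinstance(axes, int) else (axes,)
    # collapse the reduced axes into one trailing axis for a clean argmax
    keep = tuple(a for a in range(x.ndim) if a not in axes)
    perm = keep + axes
    xt = x.data.transpose(perm)
    lead = xt.shape[: len(keep)]
    xt2 = xt.reshape(lead + (-1,))
    idx = xt2.argmax(axis=-1)
    out_flat = np.take_along_axis(xt2, idx[..., None], axis=-1)[..., 0]
    out_data = out_flat
    if keepdims:
        out_data = np.expand_dims(out_flat, axes)

    def backward(g):
        if keepdims:
            g = g.reshape(lead)
        gt2 = np.zeros_like(xt2)
        np.put_along_axis(gt2, idx[..., None], g[..., None], axis=-1)
        gt = gt2.reshape(xt.shape)
        x.accumulate(gt.transpose(np.argsort(perm)))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors, axis=1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t.accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def _bilinear_coeffs(size_in: int, size_out: int, align_corners: bool):
    if align_corners and size_out > 1:
        src = np.arange(size_out) * (size_in - 1) / (size_out - 1)
    else:
        src = (np.arange(size_out) + 0.5) * (size_in / size_out) - 0.5
    src = np.clip(src, 0, size_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, size_in - 1)
    w1 = src - i0
    return i0, i1, 1.0 - w1, w1


def upsample_bilinear(x: Tensor, out_h: int, out_w: int, align_corners: bool = False) -> Tensor:
    """Bilinear resampling of an NCHW tensor to (out_h, out_w)."""
    n, c, h, w = x.shape
    r0, r1, wr0, wr1 = _bilinear_coeffs(h, out_h, align_corners)
    c0, c1, wc0, wc1 = _bilinear_coeffs(w, out_w, align_corners)
    top = x.data[:, :, r0, :][:, :, :, c0] * (wr0[:, None] * wc0[None, :]) + \
        x.data[:, :, r0, :][:, :, :, c1] * (wr0[:, None] * wc1[None, :])
    bot = x.data[:, :, r1, :][:, :, :, c0] * (wr1[:, None] * wc0[None, :]) + \
        x.data[:, :, r1, :][:, :, :, c1] * (wr1[:, None] * wc1[None, :])
    out_data = top + bot

    def backward(g):
        if not (x.requires_grad or x._parents):
            return
        gx = np.zeros((h, w, n, c), dtype=x.data.dtype)
        gt = g.transpose(2, 3, 0, 1)  # (Ho, Wo, N, C)
        R0 = np.broadcast_to(r0[:, None], (out_h, out_w))
        R1 = np.broadcast_to(r1[:, None], (out_h, out_w))
        C0 = np.broadcast_to(c0[None, :], (out_h, out_w))
        C1 = np.broadcast_to(c1[None, :], (out_h, out_w))
        for R, C, wgt in (
            (R0, C0, wr0[:, None] * wc0[None, :]),
            (R0, C1, wr0[:, None] * wc1[None, :]),
            (R1, C0, wr1[:, None] * wc0[None, :]),
            (R1, C1, wr1[:, None] * wc1[None, :]),
        ):
            np.add.at(gx, (R, C), gt * wgt[:, :, None, None])
        x.accumulate(gx.transpose(2, 3, 0, 1))

    return Tensor(out_data, parents=(x,), backward=backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy.

    logits: (N, C, H, W); labels: (N, H, W) integer class ids.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sm = ez / ez.sum(axis=1, keepdims=True)
    n, c, h, w = z.shape
    labels = np.asarray(labels)
    onehot_idx = (
        np.arange(n)[:, None, None],
        labels,
        np.arange(h)[None, :, None],
        np.arange(w)[None, None, :],
    )
    logp = np.log(np.maximum(sm, 1e-30))
    picked = logp[np.arange(n)[:, None, None], labels,
                  np.arange(h)[None, :, None], np.arange(w)[None, None, :]]
    count = n * h * w
    loss = -picked.sum() / count

    def backward(g):
        gx = sm.copy()
        gx[onehot_idx] -= 1.0
        logits.accumulate(gx * (g / count))

    return Tensor(np.asarray(loss), parents=(logits,), backward=backward)
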