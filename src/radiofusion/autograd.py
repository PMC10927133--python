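"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small convolutional networks on a single CPU, so the
engine implements exactly the operator set those networks need: broadcasted
arithmetic, matmul, stride-1 2-D convolution (with groups and dilation),
2x2 max pooling, bilinear 2x upsampling, reductions, softmax, sigmoid/ReLU/
softplus, concatenation, slicing and axis shifts.  Every operator's backward
pass is verified against central finite differences in the test suite.

Design notes
------------
* A :class:`Tensor` wraps an ``ndarray`` and records its parents plus a
  closure that accumulates gradients into them.  ``backward()`` runs a
  topological sort and applies the closures in reverse order.
* Broadcasting is supported in elementwise ops; gradients are summed back
  over broadcast axes (:func:`_unbroadcast`).
* Convolutions are stride-1 only (downsampling is done by pooling), which
  lets the input gradient be expressed as another convolution with the
  channel-swapped, spatially flipped kernel.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nextra = grad.ndim - len(shape)
    if nextra:
        grad = grad.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _NoGrad:
    _active = False

    def __enter__(self):
        self.prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self.prev
        return False


def no_grad() -> _NoGrad:
    """Context manager disabling graph construction."""
    return _NoGrad()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _from_op(data: np.ndarray, parents: Sequence["Tensor"], backward):
        req = (not _NoGrad._active) and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad = self.grad + np.asarray(g, dtype=self.data.dtype)

    # -- autodiff --------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._from_op(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return Tensor._from_op(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(out_data, (self,), bwd)

    # -- matmul ---------------------------------------------------------------
    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._from_op(out_data, (self, other), bwd)

    # -- nonlinearities --------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g):
            self._accum(g * mask)

        return Tensor._from_op(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), bwd)

    def softplus(self):
        # max(x,0) + log1p(exp(-|x|)) : overflow-safe
        x = self.data
        out_data = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def bwd(g):
            self._accum(g * sig)

        return Tensor._from_op(out_data, (self,), bwd)

    def softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._from_op(out_data, (self,), bwd)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._from_op(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        # split ties evenly so the gradient check is well-defined
        mask = mask / mask.sum(axis=axis, keepdims=True)
        res = out_data if keepdims else np.squeeze(out_data, axis=axis)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * mask)

        return Tensor._from_op(res, (self,), bwd)

    # -- shape ops -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor._from_op(out_data, (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._from_op(out_data, (self,), bwd)

    def shift(self, axis: int, offset: int):
        """Shift along ``axis`` by ``offset`` with zero fill (for 3-tap convs)."""
        out_data = np.zeros_like(self.data)
        src = [slice(None)] * self.ndim
        dst = [slice(None)] * self.ndim
        if offset > 0:
            dst[axis] = slice(offset, None)
            src[axis] = slice(None, -offset)
        elif offset < 0:
            dst[axis] = slice(None, offset)
            src[axis] = slice(-offset, None)
        out_data[tuple(dst)] = self.data[tuple(src)]
        src_t, dst_t = tuple(src), tuple(dst)

        def bwd(g):
            full = np.zeros_like(self.data)
            full[src_t] = g[dst_t]
            self._accum(full)

        return Tensor._from_op(out_data, (self,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(out_data, tensors, bwd)


# ---------------------------------------------------------------------------
# Spatial operators (NCHW layout, stride 1)
# ---------------------------------------------------------------------------

def _cols_view(xp: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """Sliding-window view of padded input: (B, C, Ho, Wo, k, k)."""
    kd = dilation * (k - 1) + 1
    v = np.lib.stride_tricks.sliding_window_view(xp, (kd, kd), axis=(2, 3))
    if dilation > 1:
        v = v[..., ::dilation, ::dilation]
    return v


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0,
           dilation: int = 1, groups: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW.

    ``w`` has shape (C_out, C_in // groups, k, k); output spatial size is
    H + 2*padding - dilation*(k-1).
    """
    B, C, H, W = x.shape
    Cout, cig, kh, kw = w.shape
    assert kh == kw, "square kernels only"
    assert C == cig * groups, f"channel mismatch: input {C}, weight expects {cig * groups}"
    k = kh
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    v = _cols_view(xp, k, dilation)  # (B,C,Ho,Wo,k,k)
    og = Cout // groups
    outs = []
    for gi in range(groups):
        vg = v[:, gi * cig:(gi + 1) * cig]
        wg = w.data[gi * og:(gi + 1) * og]
        outs.append(np.einsum("bchwij,ocij->bohw", vg, wg, optimize=True))
    out_data = outs[0] if groups == 1 else np.concatenate(outs, axis=1)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    def bwd(g):
        if w.requires_grad:
            gws = []
            for gi in range(groups):
                vg = v[:, gi * cig:(gi + 1) * cig]
                gg = g[:, gi * og:(gi + 1) * og]
                gws.append(np.einsum("bchwij,bohw->ocij", vg, gg, optimize=True))
            w._accum(np.concatenate(gws, axis=0) if groups > 1 else gws[0])
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # input gradient = conv of g with channel-swapped, flipped kernel
            w2 = w.data.reshape(groups, og, cig, k, k)
            w2 = w2.transpose(0, 2, 1, 3, 4)[..., ::-1, ::-1]
            w2 = np.ascontiguousarray(w2.reshape(groups * cig, og, k, k))
            pad_back = dilation * (k - 1) - padding
            gp = np.pad(g, ((0, 0), (0, 0), (pad_back, pad_back), (pad_back, pad_back))) \
                if pad_back else g
            gv = _cols_view(gp, k, dilation)
            gxs = []
            for gi in range(groups):
                gvg = gv[:, gi * og:(gi + 1) * og]
                wg = w2[gi * cig:(gi + 1) * cig]
                gxs.append(np.einsum("bchwij,ocij->bohw", gvg, wg, optimize=True))
            gx = gxs[0] if groups == 1 else np.concatenate(gxs, axis=1)
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out_data, parents, bwd)


def maxpool2x(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2.  Requires even spatial sizes."""
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x needs even spatial size, got {H}x{W}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(B, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gf = np.zeros((B, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = gf.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(B, C, H, W))

    return Tensor._from_op(out_data, (x,), bwd)


_UP_CACHE: dict[int, np.ndarray] = {}


def _up_matrix(n: int) -> np.ndarray:
    """(2n, n) bilinear interpolation matrix (half-pixel convention)."""
    A = _UP_CACHE.get(n)
    if A is None:
        A = np.zeros((2 * n, n))
        for o in range(2 * n):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            t = src - i0
            i0c = min(max(i0, 0), n - 1)
            i1c = min(max(i0 + 1, 0), n - 1)
            A[o, i0c] += 1.0 - t
            A[o, i1c] += t
        _UP_CACHE[n] = A
    return A


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear 2x upsampling (separable matrix form, exact adjoint backward)."""
    B, C, H, W = x.shape
    Ah = _up_matrix(H).astype(x.data.dtype)
    Aw = _up_matrix(W).astype(x.data.dtype)
    out_data = np.einsum("hi,bcij,wj->bchw", Ah, x.data, Aw, optimize=True)

    def bwd(g):
        x._accum(np.einsum("hi,bchw,wj->bcij", Ah, g, Aw, optimize=True))

    return Tensor._from_op(out_data, (x,), bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits: softplus(z) - y*z (overflow-safe)."""
    t = Tensor(np.asarray(targets, dtype=logits.data.dtype))
    per = logits.softplus() - logits * t
    return per.mean()
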