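"""Reverse-mode automatic differentiation over NumPy arrays.

This is the numeric substrate for the segmentation network: a small
tape-based autograd engine exposing exactly the operations the
architecture needs — broadcast arithmetic, 2-D (dilated) convolution via
im2col, 2x2 max pooling, nearest-neighbour upsampling, channel
concatenation, reductions and the ReLU/sigmoid/log/exp nonlinearities.
Gradients are accumulated by topological traversal of the recorded
graph; correctness is checked against central finite differences in the
test suite.

All tensors are float32 by default (float64 is accepted and preserved,
which the gradient-check tests rely on).
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "maxpool2x2",
    "upsample_nearest",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient tape entry.

    Parameters
    ----------
    data : array-like
        Values; cast to float32 unless already a float64 array.
    requires_grad : bool
        Whether gradients should flow to this tensor.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype != np.float64:
            arr = arr.astype(DEFAULT_DTYPE, copy=False)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------
    # bookkeeping
    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    # arithmetic
    # ------------------------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out = Tensor(fwd(self.data, other.data))
        if self.requires_grad or other.requires_grad:
            out.requires_grad = True
            out._parents = (self, other)
            a, b = self, other

            def _backward(grad):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(bwd_self(grad, a.data, b.data), a.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(bwd_other(grad, a.data, b.data), b.shape))

            out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda x, y: x + y,
                            lambda g, x, y: g, lambda g, x, y: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda x, y: x - y,
                            lambda g, x, y: g, lambda g, x, y: -g)

    def __rsub__(self, other):
        return Tensor(np.asarray(other, dtype=self.data.dtype)).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda x, y: x * y,
                            lambda g, x, y: g * y, lambda g, x, y: g * x)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda x, y: x / y,
                            lambda g, x, y: g / y,
                            lambda g, x, y: -g * x / (y * y))

    def __rtruediv__(self, other):
        return Tensor(np.asarray(other, dtype=self.data.dtype)).__truediv__(self)

    def __neg__(self):
        return self * -1.0

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent)
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src = self

            def _backward(grad):
                src._accumulate(grad * exponent * src.data ** (exponent - 1.0))

            out._backward = _backward
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # ------------------------------------------------------------------
    # nonlinearities
    # ------------------------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src, mask = self, self.data > 0

            def _backward(grad):
                src._accumulate(grad * mask)

            out._backward = _backward
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        x = self.data
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        s[~pos] = ex / (1.0 + ex)
        out = Tensor(s)
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src = self

            def _backward(grad):
                src._accumulate(grad * s * (1.0 - s))

            out._backward = _backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e)
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src = self

            def _backward(grad):
                src._accumulate(grad * e)

            out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src = self

            def _backward(grad):
                src._accumulate(grad / src.data)

            out._backward = _backward
        return out

    def clip_min(self, floor: float) -> "Tensor":
        """max(x, floor); gradient passes where x > floor."""
        out = Tensor(np.maximum(self.data, floor))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src, mask = self, self.data > floor

            def _backward(grad):
                src._accumulate(grad * mask)

            out._backward = _backward
        return out

    # ------------------------------------------------------------------
    # shape ops and reductions
    # ------------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src, orig = self, self.data.shape

            def _backward(grad):
                src._accumulate(grad.reshape(orig))

            out._backward = _backward
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src = self

            def _backward(grad):
                g = grad
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % src.ndim for a in axes):
                        g = np.expand_dims(g, ax)
                src._accumulate(np.broadcast_to(g, src.shape).astype(src.dtype))

            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis``; gradient is split back to the parts."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def _backward(grad):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * grad.ndim
                    idx[axis] = slice(lo, hi)
                    t._accumulate(grad[tuple(idx)])

        out._backward = _backward
    return out


# ----------------------------------------------------------------------
# convolution (stride 1, optional dilation) via im2col
# ----------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, dil: int,
            h_out: int, w_out: int) -> np.ndarray:
    n, c, hp, wp = xp.shape
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, h_out, w_out),
        strides=(s[0], s[1], s[2] * dil, s[3] * dil, s[2], s[3]),
    )
    return np.ascontiguousarray(view).reshape(n, c * kh * kw, h_out * w_out)


def _col2im(gcols: np.ndarray, n: int, c: int, hp: int, wp: int,
            kh: int, kw: int, dil: int, h_out: int, w_out: int,
            dtype) -> np.ndarray:
    gx = np.zeros((n, c, hp, wp), dtype=dtype)
    g6 = gcols.reshape(n, c, kh, kw, h_out, w_out)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i * dil:i * dil + h_out, j * dil:j * dil + w_out] += g6[:, :, i, j]
    return gx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, stride 1, zero padding, optional dilation.

    ``x``: (N, C, H, W); ``weight``: (F, C, kh, kw); ``bias``: (F,).
    Output spatial size is H + 2·padding − dilation·(kh−1).
    """
    n, c, h, w = x.shape
    f, c_w, kh, kw = weight.shape
    if c != c_w:
        raise ValueError(
            f"conv2d channel mismatch: input has {c} channels, kernel expects {c_w}"
        )
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    h_out = hp - dilation * (kh - 1)
    w_out = wp - dilation * (kw - 1)
    if h_out < 1 or w_out < 1:
        raise ValueError(
            f"conv2d: input {h}x{w} too small for kernel {kh}x{kw} "
            f"with dilation {dilation} and padding {padding}"
        )
    cols = _im2col(xp, kh, kw, dilation, h_out, w_out)  # (N, CK, L)
    wmat = weight.data.reshape(f, -1)                    # (F, CK)
    out_data = np.matmul(wmat, cols)                     # (N, F, L)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, f, 1)
    out = Tensor(out_data.reshape(n, f, h_out, w_out))

    needs = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad)
    if needs:
        out.requires_grad = True
        out._parents = (x, weight) if bias is None else (x, weight, bias)

        def _backward(grad):
            g = grad.reshape(n, f, h_out * w_out)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2)))
            if weight.requires_grad:
                gw = np.einsum("nfl,nkl->fk", g, cols, optimize=True)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                gcols = np.matmul(wmat.T, g)  # (N, CK, L)
                gx = _col2im(gcols, n, c, hp, wp, kh, kw, dilation,
                             h_out, w_out, x.dtype)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                x._accumulate(gx)

        out._backward = _backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; requires even spatial dims."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(
            f"max pooling requires even spatial dimensions, got {h}x{w}; "
            "pad inputs to a multiple of 16"
        )
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    windows = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = windows.argmax(axis=-1)
    out = Tensor(np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0])
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        src = x

        def _backward(grad):
            gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=src.dtype)
            np.put_along_axis(gwin, idx[..., None], grad[..., None], axis=-1)
            gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            src._accumulate(gx)

        out._backward = _backward
    return out


def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor.

    Output pixel (X, Y) copies source pixel (floor(X/scale), floor(Y/scale)),
    the floor-index map of integer-factor nearest interpolation.
    """
    if scale < 1 or int(scale) != scale:
        raise ValueError(f"upsampling scale must be a positive integer, got {scale}")
    scale = int(scale)
    if scale == 1:
        return x
    n, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3))
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        src = x

        def _backward(grad):
            g = grad.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
            src._accumulate(g)

        out._backward = _backward
    return out
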