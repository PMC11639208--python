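"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and
a closure that propagates gradients to its parents.  The operator set is the
small one this package actually needs: broadcast arithmetic, matmul, shape
ops, reductions, pointwise nonlinearities, and an ``unfold`` (im2col)
primitive out of which all convolutions are composed.  Everything is float64
and single-threaded; determinism is part of the contract.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._grad_owned = False
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        # copy-on-write: adopt the first gradient by reference and only
        # materialize a private copy if a second contribution arrives
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    def zero_grad(self):
        self.grad = None
        self._grad_owned = False

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            a._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bw)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g, a=self):
            a._accum(g.reshape(old))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g, a=self):
            a._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bw(g, a=self):
            od, gg = out_data, g
            if axis is not None and not keepdims:
                od = np.expand_dims(od, axis)
                gg = np.expand_dims(gg, axis)
            mask = (a.data == od).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            a._accum(mask * gg)

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- pointwise -----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self):
            a._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, a=self):
            a._accum(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g, a=self):
            a._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g, a=self):
            a._accum(g * sig)

        return Tensor(out_data, parents=(self,), backward=bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g, a=self):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- structured ops ------------------------------------------------------
    def unfold(self, kh: int, kw: int):
        """im2col with zero 'same' padding.

        Input ``(C, H, W)`` -> output ``(H*W, C*kh*kw)`` where row ``i*W+j``
        holds the kh x kw patch centred at ``(i, j)``, channel-major.
        Kernel sides must be odd (centring is undefined otherwise).
        """
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError(f"unfold requires odd kernel sides, got {kh}x{kw}")
        C, H, W = self.shape
        ph, pw = kh // 2, kw // 2
        padded = np.pad(self.data, ((0, 0), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(1, 2))
        out_data = np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(
            H * W, C * kh * kw
        )

        def bw(g, a=self):
            gg = g.reshape(H, W, C, kh, kw).transpose(2, 0, 1, 3, 4)
            gpad = np.zeros((C, H + 2 * ph, W + 2 * pw))
            for di in range(kh):
                for dj in range(kw):
                    gpad[:, di : di + H, dj : dj + W] += gg[:, :, :, di, dj]
            a._accum(gpad[:, ph : ph + H, pw : pw + W])

        return Tensor(out_data, parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def Parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


# ---------------------------------------------------------------------------
# layers built from the primitives above
# ---------------------------------------------------------------------------

def concat_channels(tensors):
    """Concatenate (C_i, H, W) tensors along the channel axis."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=0)
    offsets = np.cumsum([0] + [d.shape[0] for d in datas])

    def bw(g, parts=tuple(tensors), offs=offsets):
        for t, o0, o1 in zip(parts, offs[:-1], offs[1:]):
            if t.requires_grad:
                t._accum(g[o0:o1])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def stack0(tensors):
    """Stack equal-shape tensors along a new leading axis."""
    out_data = np.stack([t.data for t in tensors], axis=0)

    def bw(g, parts=tuple(tensors)):
        for i, t in enumerate(parts):
            if t.requires_grad:
                t._accum(g[i])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """'Same' zero-padded cross-correlation.

    x: (Cin, H, W); weight: (Cout, Cin, kh, kw); bias: (Cout,) or None.
    """
    Cout, Cin, kh, kw = weight.shape
    C, H, W = x.shape
    if C != Cin:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel expects {Cin}")
    cols = x.unfold(kh, kw)                       # (H*W, Cin*kh*kw)
    wmat = weight.reshape(Cout, Cin * kh * kw)    # (Cout, K)
    out = (cols @ wmat.transpose((1, 0))).transpose((1, 0)).reshape(Cout, H, W)
    if bias is not None:
        out = out + bias.reshape(Cout, 1, 1)
    return out


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Per-channel 'same' cross-correlation; weight: (C, kh, kw).

    Implemented as a shift-and-accumulate primitive (kh*kw vectorized adds)
    rather than im2col, which would materialize an H*W x C*kh*kw buffer.
    """
    C, H, W = x.shape
    Cw, kh, kw = weight.shape
    if C != Cw:
        raise ValueError(f"depthwise channel mismatch: input {C}, kernel {Cw}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError(f"depthwise kernel sides must be odd, got {kh}x{kw}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    out_data = np.zeros((C, H, W))
    wd = weight.data
    for di in range(kh):
        for dj in range(kw):
            out_data += wd[:, di, dj, None, None] * xp[:, di : di + H, dj : dj + W]

    def bw(g, a=x, w=weight):
        if a.requires_grad:
            gpad = np.zeros((C, H + 2 * ph, W + 2 * pw))
            for di in range(kh):
                for dj in range(kw):
                    gpad[:, di : di + H, dj : dj + W] += wd[:, di, dj, None, None] * g
            a._accum(gpad[:, ph : ph + H, pw : pw + W])
        if w.requires_grad:
            gw = np.empty((C, kh, kw))
            for di in range(kh):
                for dj in range(kw):
                    gw[:, di, dj] = (g * xp[:, di : di + H, dj : dj + W]).sum(axis=(1, 2))
            w._accum(gw)

    out = Tensor(out_data, parents=(x, weight), backward=bw)
    if bias is not None:
        out = out + bias.reshape(C, 1, 1)
    return out


def layer_norm(x: Tensor, gain: Tensor, shift: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize across the channel axis at every spatial position.

    x: (C, H, W); gain, shift: (C,).
    """
    C = x.shape[0]
    mu = x.mean(axis=0, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=0, keepdims=True)
    y = xc / (var + eps).sqrt()
    return gain.reshape(C, 1, 1) * y + shift.reshape(C, 1, 1)


def softmax0(x: Tensor) -> Tensor:
    """Numerically stable softmax along axis 0."""
    z = x - x.max(axis=0, keepdims=True).detach()
    e = z.exp()
    return e / e.sum(axis=0, keepdims=True)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix (align_corners=False convention)."""
    B = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        B[i, lo_c] += 1.0 - frac
        B[i, hi_c] += frac
    return B


def upsample_bilinear(x: Tensor, factor: int = 2) -> Tensor:
    """Bilinear upsampling of (C, H, W) by an integer factor."""
    C, H, W = x.shape
    By = Tensor(_interp_matrix(H * factor, H))
    Bx = Tensor(_interp_matrix(W * factor, W))
    # rows: (C,H,W) -> (H, C*W) -> (fH, C*W) -> (C, fH, W)
    t = x.transpose((1, 0, 2)).reshape(H, C * W)
    t = (By @ t).reshape(H * factor, C, W).transpose((1, 0, 2))
    # cols: (C,fH,W) -> (C*fH, W) -> matmul Bx^T -> (C, fH, fW)
    t = t.reshape(C * H * factor, W) @ Bx.transpose((1, 0))
    return t.reshape(C, H * factor, W * factor)
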