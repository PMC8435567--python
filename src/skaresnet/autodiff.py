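"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the attention networks in this package
need: broadcast arithmetic, matmul, (grouped/depthwise) 2-d convolution,
max pooling, reductions, softmax and elementwise nonlinearities.  Gradients
are accumulated by a topological backward sweep over the recorded tape.

All math runs in float64: the package targets desk-scale models where
numerical transparency (gradient checks against central differences to
~1e-7) matters more than throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` back to ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Run the reverse sweep from this tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if p.requires_grad and id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g, self.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(tuple(inv)))
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the (first) argmax."""
        arg = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(arg, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_data, _parents=(self,))

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(arg, axis), g, axis=axis)
            self._accumulate(full)

        out._backward = bw
        return out

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500.0, 500.0)))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / r)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        out._backward = bw
        return out

    # -- gather -----------------------------------------------------------
    def take_rows(self, idx):
        """out[i] = self[i, idx[i]] for a 2-d tensor."""
        idx = np.asarray(idx)
        rows = np.arange(self.shape[0])
        out = Tensor(self.data[rows, idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (rows, idx), g)
            self._accumulate(full)

        out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# Spatial ops (NCHW)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int):
    """Sliding windows of a padded NCHW array: (N, C, Ho, Wo, k, k)."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped cross-correlation of NCHW input with (Cout, Cin/g, k, k) weights."""
    n, cin, h, wd_ = x.shape
    cout, cin_g, k, k2 = w.shape
    if k != k2:
        raise ValueError("only square kernels are supported")
    if cin % groups or cout % groups:
        raise ValueError(f"groups={groups} must divide Cin={cin} and Cout={cout}")
    if cin_g != cin // groups:
        raise ValueError(
            f"weight expects {cin_g * groups} input channels, got {cin}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _im2col(xp, k, stride)                       # (N, Cin, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    depthwise = groups == cin == cout

    if depthwise:
        out_data = np.einsum("nchwij,cij->nchw", win, w.data[:, 0], optimize=True)
    elif groups == 1:
        out_data = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    else:
        wing = win.reshape(n, groups, cin // groups, ho, wo, k, k)
        wg = w.data.reshape(groups, cout // groups, cin // groups, k, k)
        out_data = np.einsum("ngchwij,gocij->ngohw", wing, wg,
                             optimize=True).reshape(n, cout, ho, wo)
    out = Tensor(out_data, _parents=(x, w))

    def _scatter(gwin):
        """col2im: accumulate window grads back onto the padded input."""
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += gwin[
                    :, :, :, :, i, j
                ]
        if padding:
            gxp = gxp[:, :, padding : padding + h, padding : padding + wd_]
        return gxp

    def bw(g):
        if depthwise:
            if w.requires_grad:
                gw = np.einsum("nchw,nchwij->cij", g, win, optimize=True)
                w._accumulate(gw[:, None])
            if x.requires_grad:
                gwin = np.einsum("nchw,cij->nchwij", g, w.data[:, 0], optimize=True)
                x._accumulate(_scatter(gwin))
        elif groups == 1:
            if w.requires_grad:
                w._accumulate(np.einsum("nohw,nchwij->ocij", g, win, optimize=True))
            if x.requires_grad:
                gwin = np.einsum("nohw,ocij->nchwij", g, w.data, optimize=True)
                x._accumulate(_scatter(gwin))
        else:
            gg = g.reshape(n, groups, cout // groups, ho, wo)
            wing = win.reshape(n, groups, cin // groups, ho, wo, k, k)
            wg = w.data.reshape(groups, cout // groups, cin // groups, k, k)
            if w.requires_grad:
                gw = np.einsum("ngohw,ngchwij->gocij", gg, wing, optimize=True)
                w._accumulate(gw.reshape(cout, cin // groups, k, k))
            if x.requires_grad:
                gwin = np.einsum("ngohw,gocij->ngchwij", gg, wg, optimize=True)
                x._accumulate(_scatter(gwin.reshape(n, cin, ho, wo, k, k)))

    out._backward = bw
    return out


def max_pool2d(x: Tensor, k: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    win = _im2col(xp, k, stride)
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], _parents=(x,))

    def bw(g):
        gxp = np.zeros(xp.shape)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            mask = arg == idx
            gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += g * mask
        if padding:
            gxp = gxp[:, :, padding : padding + h, padding : padding + w]
        x._accumulate(gxp)

    out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bw
    return out
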