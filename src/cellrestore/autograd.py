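"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the restoration/segmentation networks and
their losses need: broadcasting arithmetic, (batched) matrix products,
3x3/1x1 convolution via im2col GEMM, 2x2 average pooling, nearest-neighbour
2x upsampling, reductions with axes, relu/sigmoid and a numerically stable
binary cross-entropy on logits.

All tensors hold float32 or float64 numpy data.  The graph is a tape of
``Tensor`` nodes; ``Tensor.backward()`` runs a topological sweep and
accumulates gradients into every node with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "pow_",
    "matmul",
    "bmm",
    "relu",
    "sigmoid",
    "conv2d",
    "avg_pool2",
    "upsample2",
    "reshape",
    "transpose_last2",
    "mean",
    "sum_",
    "bce_with_logits",
]


class Tensor:
    """A node in the autodiff tape wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g) -> None:
        if not self.requires_grad and self._backward is None:
            return
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, pow_(as_tensor(other), -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in ts)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _node(data, parents, backward) -> Tensor:
    if _needs_grad(*parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# -- arithmetic ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def bw(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(-g, b.data.shape))

    return _node(out_data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bw)


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def bw(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), bw)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def bw(g):
        a._accum(g @ b.data.swapaxes(-1, -2))
        b._accum(a.data.swapaxes(-1, -2) @ g)

    return _node(out_data, (a, b), bw)


def bmm(a, b) -> Tensor:
    """Batched matmul for stacks of matrices (..., n, k) @ (..., k, m)."""
    return matmul(a, b)


def transpose_last2(a) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.swapaxes(-1, -2)

    def bw(g):
        a._accum(g.swapaxes(-1, -2))

    return _node(out_data, (a,), bw)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def bw(g):
        a._accum(g.reshape(a.data.shape))

    return _node(out_data, (a,), bw)


# -- reductions ------------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _node(out_data, (a,), bw)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# -- nonlinearities --------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0)

    def bw(g):
        a._accum(g * (a.data > 0))

    return _node(out_data, (a,), bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), bw)


def bce_with_logits(logits, targets) -> Tensor:
    """Mean binary cross-entropy on raw logits; stable log-sum-exp form."""
    logits = as_tensor(logits)
    t = np.asarray(targets.data if isinstance(targets, Tensor) else targets)
    z = logits.data
    out_data = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accum(g * (s - t) / z.size)

    return _node(out_data, (logits,), bw)


# -- spatial ops (NCHW) ----------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix, zero padding, stride 1."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, h, w), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(view.transpose(0, 4, 5, 1, 2, 3)).reshape(n * h * w, c * k * k)


def conv2d(x, weight, bias=None) -> Tensor:
    """Same-size 2D convolution, odd kernel, stride 1, zero padding.

    x: (N, Cin, H, W); weight: (Cout, Cin, k, k); bias: (Cout,) or None.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, h, w = x.data.shape
    cout, cin_w, k, _ = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    pad = k // 2
    col = _im2col(x.data, k, pad)  # (N*H*W, Cin*k*k)
    wmat = weight.data.reshape(cout, cin * k * k)
    out = col @ wmat.T
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data
    out_data = out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, cout)
        weight._accum((gflat.T @ col).reshape(weight.data.shape))
        if bias is not None:
            bias._accum(gflat.sum(axis=0))
        if x.requires_grad or x._backward is not None:
            # grad wrt input = correlation of g with the 180-degree-rotated,
            # in/out-swapped kernel
            gx_col = _im2col(g, k, pad)
            wrot = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
                cin, cout * k * k
            )
            gx = (gx_col @ wrot.T).reshape(n, h, w, cin).transpose(0, 3, 1, 2)
            x._accum(gx)

    return _node(out_data, parents, bw)


def avg_pool2(x) -> Tensor:
    """2x2 average pooling, stride 2; spatial dims must be even."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def bw(g):
        x._accum(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25)

    return _node(out_data, (x,), bw)


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    x = as_tensor(x)
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bw(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _node(out_data, (x,), bw)
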