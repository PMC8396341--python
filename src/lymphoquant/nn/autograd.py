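"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations needed by the density-regression network are
implemented: broadcast arithmetic, matmul, 3x3 same-padding convolution,
2x2 average pooling, 2x bilinear/nearest upsampling, ReLU, sigmoid,
elementwise max, channel concatenation, reductions and reshapes.

Gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "avg_pool2", "upsample2x", "maximum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = _make(np.add(self.data, other.data), (self, other))

        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = _make(self.data * other.data, (self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __pow__(self, p: float):
        out = _make(self.data**p, (self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = _make(self.data @ other.data, (self, other))

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- nonlinearities --------------------------------------------------
    def relu(self) -> "Tensor":
        out = _make(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        out = _make(self.data.reshape(*shape), (self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    # -- backprop driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; subgradient routes to the larger input (ties -> a)."""
    out = _make(np.maximum(a.data, b.data), (a, b))

    def backward(g):
        take_a = a.data >= b.data
        return (
            _unbroadcast(g * take_a, a.data.shape),
            _unbroadcast(g * (~take_a), b.data.shape),
        )

    out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, same padding.

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin, kh, kw) with odd kh, kw;
    ``b``: (Cout,) or None.
    """
    kh, kw = w.data.shape[2], w.data.shape[3]
    ph, pw = kh // 2, kw // 2
    B, Cin, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    y = np.zeros((B, w.data.shape[0], H, W))
    for di in range(kh):
        for dj in range(kw):
            y += np.einsum(
                "oc,bchw->bohw",
                w.data[:, :, di, dj],
                xp[:, :, di : di + H, dj : dj + W],
                optimize=True,
            )
    if b is not None:
        y += b.data[None, :, None, None]
        parents: tuple[Tensor, ...] = (x, w, b)
    else:
        parents = (x, w)
    out = _make(y, parents)

    def backward(g):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, :, di : di + H, dj : dj + W]
                gw[:, :, di, dj] = np.einsum("bohw,bchw->oc", g, patch, optimize=True)
                gxp[:, :, di : di + H, dj : dj + W] += np.einsum(
                    "oc,bohw->bchw", w.data[:, :, di, dj], g, optimize=True
                )
        gx = gxp[:, :, ph : ph + H, pw : pw + W]
        if b is not None:
            return gx, gw, g.sum(axis=(0, 2, 3))
        return gx, gw

    out._backward = backward
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2; spatial dims must be even."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    y = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    out = _make(y, (x,))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        return (gx,)

    out._backward = backward
    return out


def _lin_up_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """1-D 2x linear upsampling (align_corners=False) along ``axis``."""
    n = a.shape[axis]
    lo = np.clip(np.arange(n) - 1, 0, n - 1)
    hi = np.clip(np.arange(n) + 1, 0, n - 1)
    a_lo = np.take(a, lo, axis=axis)
    a_hi = np.take(a, hi, axis=axis)
    even = 0.25 * a_lo + 0.75 * a  # output index 2i  <- src i - 0.25
    odd = 0.75 * a + 0.25 * a_hi  # output index 2i+1 <- src i + 0.25
    out = np.stack([even, odd], axis=axis + 1)
    shape = list(a.shape)
    shape[axis] = 2 * n
    return out.reshape(shape)


def upsample2x(x: Tensor, mode: str = "bilinear") -> Tensor:
    """Upsample (B, C, H, W) by 2 in both spatial dimensions."""
    if mode == "nearest":
        y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
        out = _make(y, (x,))

        def backward_nearest(g):
            B, C, H2, W2 = g.shape
            gx = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            return (gx,)

        out._backward = backward_nearest
        return out
    if mode != "bilinear":
        raise ValueError(f"unknown upsampling mode: {mode}")
    h = x.data.shape[2]
    w = x.data.shape[3]
    y = _lin_up_axis(_lin_up_axis(x.data, 2), 3)
    out = _make(y, (x,))

    def backward(g):
        g = _lin_up_T(g, 3, w)
        g = _lin_up_T(g, 2, h)
        return (g,)

    out._backward = backward
    return out


def _lin_up_T(g: np.ndarray, axis: int, n: int) -> np.ndarray:
    """Adjoint of the 1-D 2x linear upsampling along ``axis``."""
    shape = list(g.shape)
    shape[axis] = n
    shape.insert(axis + 1, 2)
    g2 = g.reshape(shape)
    even = np.take(g2, 0, axis=axis + 1)
    odd = np.take(g2, 1, axis=axis + 1)
    ga = 0.75 * even + 0.75 * odd
    # scatter the 0.25-weighted neighbor contributions with edge clamping
    ev = np.moveaxis(0.25 * even, axis, 0)
    od = np.moveaxis(0.25 * odd, axis, 0)
    gm = np.moveaxis(ga, axis, 0)
    gm[0] += ev[0]
    gm[:-1] += ev[1:]
    gm[1:] += od[:-1]
    gm[-1] += od[-1]
    return np.moveaxis(gm, 0, axis)
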