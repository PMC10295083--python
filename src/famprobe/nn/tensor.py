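"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 numpy array and records the operations
that produced it.  Calling :meth:`Tensor.backward` on a scalar (or with an
explicit cotangent) walks the tape in reverse topological order and
accumulates gradients into every reachable leaf with ``requires_grad``.

The operation set is deliberately small: exactly what feed-forward
convolutional and transformer-encoder models need (broadcasted arithmetic,
matmul, conv1d, softmax, layer statistics, gather, slicing).  Everything is
float32; gradient correctness is enforced by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, cotangent: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if cotangent is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without cotangent needs a scalar")
            cotangent = np.ones_like(self.data)
        # reverse topological order over the tape
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(_as_array(cotangent))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            self._accumulate(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape))
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = bw
        return out

    # ------------------------------------------------------------ elementwise
    def relu(self):
        out = Tensor(np.maximum(self.data, 0), parents=(self,))

        def bw(g):
            self._accumulate(g * (self.data > 0))
        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def bw(g):
            self._accumulate(g * s * (1.0 - s))
        out._backward = bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))

        def bw(g):
            self._accumulate(g * (1.0 - t * t))
        out._backward = bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))

        def bw(g):
            self._accumulate(g * e)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            self._accumulate(g / self.data)
        out._backward = bw
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, parents=(self,))

        def bw(g):
            self._accumulate(g * 0.5 / r)
        out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(DTYPE))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, parents=(self,))
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, argmax, g, axis)
            self._accumulate(full)
        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))
        out._backward = bw
        return out

    # --------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            self._accumulate(g.reshape(self.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))
        out._backward = bw
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))

        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))
        out._backward = bw
        return out


# ---------------------------------------------------------------- free functions
def gather_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Embedding lookup: ``table[indices]`` with scatter-add backward."""
    idx = np.asarray(indices)
    out = Tensor(table.data[idx], parents=(table,))

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        table._accumulate(full)
    out._backward = bw
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1) -> Tensor:
    """Same-padded, optionally strided 1-D convolution.

    x: (B, L, Cin); weight: (K, Cin, Cout) with K odd; bias: (Cout,).
    Returns (B, ceil(L / stride), Cout).  Implemented by im2col + one BLAS
    matmul; the backward pass scatters window gradients back by shifted adds.
    """
    B, L, Cin = x.shape
    K, Cin_w, Cout = weight.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    if K % 2 != 1:
        raise ValueError("kernel size must be odd for same padding")
    pad = K // 2
    Lout = (L + stride - 1) // stride
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B,L,Cin,K)
    cols = cols[:, ::stride]
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B * Lout, K * Cin)
    w2 = weight.data.reshape(K * Cin, Cout)
    y = (cols @ w2).reshape(B, Lout, Cout)
    if bias is not None:
        y = y + bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents=parents)

    def bw(g):
        g2 = g.reshape(B * Lout, Cout)
        if weight.requires_grad:
            gw = cols.T @ g2
            weight._accumulate(gw.reshape(K, Cin, Cout))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ w2.T).reshape(B, Lout, K, Cin)
            gxp = np.zeros((B, L + 2 * pad, Cin), dtype=DTYPE)
            for k in range(K):  # K is small; col2im by shifted adds
                gxp[:, k:k + stride * Lout:stride, :] += gcols[:, :, k, :]
            x._accumulate(gxp[:, pad:pad + L, :])
    out._backward = bw
    return out
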