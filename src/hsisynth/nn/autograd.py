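"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tensor engine sized for the desk-scale convolutional networks in this
package (KL-VAE, diffusion U-Net, segmentation U-Net). Float32 throughout.
Only the primitives those models need are implemented; convolution has a
hand-written backward pass (per-kernel-offset tensordots) instead of im2col to
keep memory flat.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample2x"]


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep U-Nets overflow the recursion limit
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            self._accumulate(
                _unbroadcast(g * e * self.data ** (e - 1.0), self.shape)
            )

        return self._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accumulate(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accumulate(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = _stable_sigmoid(self.data)

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def silu(self):
        s = _stable_sigmoid(self.data)

        def backward(g):
            self._accumulate(g * (s + self.data * s * (1.0 - s)))

        return self._make(self.data * s, (self,), backward)

    # -- reductions & shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, self.shape)
            else:
                g_exp = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(g_exp, self.shape)
            self._accumulate(np.ascontiguousarray(grad))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            self._accumulate(g.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            grad = np.zeros(self.shape, dtype=np.float32)
            grad[idx] = g
            self._accumulate(grad)

        return self._make(self.data[idx], (self,), backward)

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    live = [t for t in tensors if t.requires_grad]
    if live:
        out.requires_grad = True
        out._parents = tuple(live)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution, NCHW input, OIHW weights.

    Forward and backward are expressed as one tensordot per kernel offset,
    which is fast for the 3x3 kernels used here and allocates no im2col
    buffer.
    """
    n, c_in, h, w_in = x.shape
    c_out, c_in_w, kh, kw = w.shape
    if c_in != c_in_w:
        raise ValueError(f"conv2d channel mismatch: input {c_in}, weight {c_in_w}")
    s = stride
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    y = np.zeros((n, c_out, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
            # (n, ci, ho, wo) x (co, ci) -> (n, ho, wo, co)
            y += np.tensordot(patch, w.data[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
    if b is not None:
        y += b.data.reshape(1, c_out, 1, 1)

    parents = [x, w] + ([b] if b is not None else [])

    def backward(g):
        if x.requires_grad:
            gx_p = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    # (n, co, ho, wo) x (co, ci) -> (n, ho, wo, ci)
                    contrib = np.tensordot(g, w.data[:, :, i, j], axes=([1], [0]))
                    gx_p[:, :, i : i + s * ho : s, j : j + s * wo : s] += contrib.transpose(0, 3, 1, 2)
            if padding:
                gx = gx_p[:, :, padding : padding + h, padding : padding + w_in]
            else:
                gx = gx_p
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                    # sum_n,ho,wo g[n,co,ho,wo] * patch[n,ci,ho,wo]
                    gw[:, :, i, j] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out = Tensor(y)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling (NCHW)."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        x._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    out = Tensor(y)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out
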