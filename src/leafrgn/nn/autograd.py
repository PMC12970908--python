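"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations needed by the network blocks in
this package are implemented (dense/conv/pool/upsample layers, batch norm,
the usual pointwise nonlinearities and a fused softmax cross-entropy).

All data is float32 unless a caller supplies float64; convolution uses an
im2col lowering so the heavy lifting is a BLAS matmul.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _node(self, data, prev, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in prev), _prev=prev)
        if out.requires_grad:
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.requires_grad:
            if self.grad is None:
                self.grad = grad.astype(self.data.dtype, copy=True)
            else:
                self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, p: float):
        def backward(g):
            self._accum(g * p * np.power(self.data, p - 1))

        return self._node(np.power(self.data, p), (self,), backward)

    __pow__ = pow

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._node(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._node(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._node(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return self._node(np.abs(self.data), (self,), backward)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._node(self.data.transpose(axes), (self,), backward)

    def concat(self, other: "Tensor", axis: int = 0):
        other = self._wrap(other)
        n = self.shape[axis]

        def backward(g):
            ga, gb = np.split(g, [n], axis=axis)
            self._accum(ga)
            other._accum(gb)

        return self._node(np.concatenate([self.data, other.data], axis=axis), (self, other), backward)

    # -- spatial ops (NCHW) ------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1,
               padding: int = 0, groups: int = 1):
        """2-D convolution, NCHW layout, square kernel, optional grouping."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        Cout, Cin_g, kh, kw = w.shape
        if C % groups or Cout % groups or Cin_g != C // groups:
            raise ValueError(
                f"channel/group mismatch: C={C}, Cout={Cout}, groups={groups}")
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        Hp, Wp = xp.shape[2], xp.shape[3]
        OH = (Hp - kh) // stride + 1
        OW = (Wp - kw) // stride + 1
        cols = np.empty((N, C, kh, kw, OH, OW), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i:i + stride * OH:stride,
                                      j:j + stride * OW:stride]
        cols = cols.reshape(N, C, kh * kw, OH * OW)

        cg = C // groups
        og = Cout // groups
        out = np.empty((N, Cout, OH * OW), dtype=x.dtype)
        w2 = w.reshape(groups, og, cg * kh * kw)
        cols_g = cols.reshape(N, groups, cg * kh * kw, OH * OW)
        for g in range(groups):
            out[:, g * og:(g + 1) * og] = np.matmul(w2[g], cols_g[:, g])
        out = out.reshape(N, Cout, OH, OW)
        if bias is not None:
            out = out + bias.data.reshape(1, Cout, 1, 1)

        prev = (self, weight) + ((bias,) if bias is not None else ())

        def backward(gout):
            go = gout.reshape(N, Cout, OH * OW)
            if bias is not None:
                bias._accum(gout.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                gw = np.empty_like(w2)
                K = cg * kh * kw
                for g in range(groups):
                    # (og, K) = [og, N*L] @ [N*L, K]
                    go_g = np.ascontiguousarray(
                        go[:, g * og:(g + 1) * og].transpose(1, 0, 2)).reshape(og, -1)
                    cols_flat = np.ascontiguousarray(
                        cols_g[:, g].transpose(1, 0, 2)).reshape(K, -1)
                    gw[g] = go_g @ cols_flat.T
                weight._accum(gw.reshape(w.shape))
            if self.requires_grad:
                gcols = np.empty_like(cols_g)
                for g in range(groups):
                    gcols[:, g] = np.matmul(w2[g].T, go[:, g * og:(g + 1) * og])
                gcols = gcols.reshape(N, C, kh, kw, OH, OW)
                gx = np.zeros((N, C, Hp, Wp), dtype=x.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + stride * OH:stride,
                           j:j + stride * OW:stride] += gcols[:, :, i, j]
                if padding:
                    gx = gx[:, :, padding:Hp - padding, padding:Wp - padding]
                self._accum(gx)

        return self._node(out, prev, backward)

    def avg_pool2d(self, k: int = 2):
        """Non-overlapping k x k average pooling (stride = k)."""
        N, C, H, W = self.shape
        if H % k or W % k:
            raise ValueError(f"spatial side ({H}x{W}) not divisible by pool size {k}")
        out = self.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

        def backward(g):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            self._accum(gx)

        return self._node(out, (self,), backward)

    def upsample2x(self):
        """Nearest-neighbour x2 spatial upsampling."""
        out = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        N, C, H, W = self.shape

        def backward(g):
            self._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

        return self._node(out, (self,), backward)

    # -- losses ------------------------------------------------------------
    def softmax(self, axis: int = -1) -> np.ndarray:
        """Numerically stable softmax of the *values* (no graph)."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=axis, keepdims=True)

    def cross_entropy(self, labels: np.ndarray):
        """Mean softmax cross-entropy against integer labels; fused op."""
        logits = self.data
        n = logits.shape[0]
        z = logits - logits.max(axis=1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=1))
        nll = lse - z[np.arange(n), labels]
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)

        def backward(g):
            gz = probs.copy()
            gz[np.arange(n), labels] -= 1.0
            self._accum(gz * (g / n))

        return self._node(np.float32(nll.mean()), (self,), backward)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
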