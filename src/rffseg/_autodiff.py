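"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the package's
segmentation networks need: stride-1 'same' 2-D convolution, 2x2 max
pooling, block transposed convolution (kernel == stride), channel
concatenation, elementwise arithmetic, ReLU/sigmoid/cos, and reductions.
Tensors are NHWC. Gradients accumulate into ``Tensor.grad`` after calling
``backward()`` on a scalar node, including gradients of intermediate
(non-leaf) tensors, which the class-activation-mapping code reads.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    """Zero-pad the two spatial axes of an NHWC array (faster than np.pad)."""
    n, h, w, c = x.shape
    out = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
    out[:, p:p + h, p:p + w, :] = x
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy scalars/arrays defer to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        t = Tensor(data)
        t.requires_grad = any(p.requires_grad for p in parents)
        if t.requires_grad:
            t._parents = parents
            t._backward = backward
        return t

    @property
    def shape(self):
        return self.data.shape

    # -- elementwise ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(self.data + other.data, (self, other), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            return _unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)

        return Tensor._make(self.data - other.data, (self, other), bwd)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def relu(self):
        mask = self.data > 0
        return Tensor._make(np.where(mask, self.data, 0.0), (self,),
                            lambda g: (g * mask,))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def cos(self):
        return Tensor._make(np.cos(self.data), (self,),
                            lambda g: (-g * np.sin(self.data),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None):
        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis), (self,), bwd)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * np.asarray(1.0 / n, dtype=self.data.dtype)

    # -- structural -----------------------------------------------------------
    @staticmethod
    def concat(tensors, axis=-1):
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            return tuple(np.split(g, splits, axis=axis))

        return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                            tuple(tensors), bwd)

    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: (g.reshape(old),))

    # -- dense / tensordot (used by the per-position RFF mapping) -------------
    def dot_last(self, w: "Tensor"):
        """Contract the last axis with a (D, Q) matrix: NHWD @ DQ -> NHWQ."""
        def bwd(g):
            gx = np.tensordot(g, w.data.T, axes=1)
            gw = np.tensordot(self.data.reshape(-1, self.shape[-1]).T,
                              g.reshape(-1, g.shape[-1]), axes=1)
            return gx, gw

        return Tensor._make(np.tensordot(self.data, w.data, axes=1),
                            (self, w), bwd)

    # -- convolutional ops ----------------------------------------------------
    def conv2d(self, w: "Tensor", b: "Tensor"):
        """Stride-1 'same' convolution; x NHWC, w (k,k,Cin,Cout), odd k.

        Evaluated as a sum of k*k spatially shifted 1x1 matmuls so BLAS does
        each contraction without materializing an im2col patch matrix.
        """
        k, _, cin, cout = w.data.shape
        assert k % 2 == 1, "odd kernels only"
        n, h, wd, _ = self.shape
        p = k // 2
        xp = _pad_hw(self.data, p)
        out = np.zeros((n, h, wd, cout), dtype=self.data.dtype)
        for di in range(k):
            for dj in range(k):
                out += xp[:, di:di + h, dj:dj + wd, :] @ w.data[di, dj]
        out = out + b.data

        def bwd(g):
            gb = g.sum(axis=(0, 1, 2))
            gw = np.empty_like(w.data)
            for di in range(k):
                for dj in range(k):
                    gw[di, dj] = np.tensordot(
                        xp[:, di:di + h, dj:dj + wd, :], g,
                        axes=([0, 1, 2], [0, 1, 2]))
            # dx: 'same' correlation of g with the flipped, transposed kernel
            gp = _pad_hw(g, p)
            wf = w.data[::-1, ::-1].transpose(0, 1, 3, 2)
            gx = np.zeros((n, h, wd, cin), dtype=g.dtype)
            for di in range(k):
                for dj in range(k):
                    gx += gp[:, di:di + h, dj:dj + wd, :] @ wf[di, dj]
            return gx, gw, gb

        return Tensor._make(out, (self, w, b), bwd)

    def maxpool2(self):
        n, h, wd, c = self.shape
        assert h % 2 == 0 and wd % 2 == 0
        xw = (self.data.reshape(n, h // 2, 2, wd // 2, 2, c)
              .transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, wd // 2, c, 4))
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            gw = np.zeros_like(xw)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = (gw.reshape(n, h // 2, wd // 2, c, 2, 2)
                  .transpose(0, 1, 4, 2, 5, 3).reshape(n, h, wd, c))
            return (gx,)

        return Tensor._make(out, (self,), bwd)

    def conv_transpose_block(self, w: "Tensor", b: "Tensor"):
        """Transposed convolution with kernel == stride == k (no overlap).

        x (N,h,w,Cin), w (k,k,Cin,Cout) -> (N, h*k, w*k, Cout); each input
        pixel paints one disjoint k x k output block.
        """
        k = w.data.shape[0]
        n, h, wd, cin = self.shape
        cout = w.data.shape[3]
        x2d = self.data.reshape(n * h * wd, cin)
        # (NHW, Cin) @ (Cin, k*k*Cout) -> blocks, then interleave spatially
        blk = (x2d @ w.data.transpose(2, 0, 1, 3).reshape(cin, -1)).reshape(
            n, h, wd, k, k, cout)
        out = blk.transpose(0, 1, 3, 2, 4, 5).reshape(
            n, h * k, wd * k, cout) + b.data

        def bwd(g):
            gb = g.sum(axis=(0, 1, 2))
            gblk = np.ascontiguousarray(
                g.reshape(n, h, k, wd, k, cout).transpose(0, 1, 3, 2, 4, 5)
            ).reshape(n * h * wd, k * k * cout)
            wk = w.data.transpose(2, 0, 1, 3).reshape(cin, -1)
            gx = (gblk @ wk.T).reshape(n, h, wd, cin)
            gw = (x2d.T @ gblk).reshape(cin, k, k, cout).transpose(1, 2, 0, 3)
            return gx, gw, gb

        return Tensor._make(out, (self, w, b), bwd)

    # -- backward pass --------------------------------------------------------
    def backward(self):
        assert self.data.size == 1, "backward() requires a scalar"
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if p.requires_grad:
                    p.grad = p.grad + g if p.grad is not None else g
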