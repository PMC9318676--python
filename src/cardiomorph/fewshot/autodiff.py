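"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a small convolutional encoder and a subspace
classifier head: elementwise arithmetic with broadcasting, matmul, reductions,
reshape/indexing/concatenation, ReLU, exp/log, 3×3 same-convolution, 2×2 max
pooling, batch normalization, dropout, a linear solve (for Gram-matrix
projections, so gradients flow through the subspace construction), and a
fused softmax cross-entropy. Gradients for every primitive are covered by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d", "batchnorm2d",
           "dropout", "solve", "cross_entropy_mean"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion depth
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    def _binary(self, other, forward, back_self, back_other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(back_self(g), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(back_other(g), other.data.shape))

        return Tensor._make(forward(self.data, other.data), (self, other), backward)

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(other, np.multiply,
                            lambda g: g * other.data, lambda g: g * self.data)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("divide by a Tensor via explicit ops")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g):
            self._accum(g.T)
        return Tensor._make(self.data.T, (self,), backward)

    # -- reductions and shaping -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def astype(self, dtype):
        """Cast with a gradient pass-through (cast back on the way down)."""
        def backward(g):
            self._accum(g.astype(self.data.dtype))
        return Tensor._make(self.data.astype(dtype), (self,), backward)

    def reshape(self, *shape):
        def backward(g):
            self._accum(g.reshape(self.data.shape))
        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def rows(self, index) -> "Tensor":
        """Select rows (first-axis indexing) with gradient scatter-add."""
        index = np.asarray(index)

        def backward(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, index, g)

        return Tensor._make(self.data[index], (self,), backward)

    # -- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: int = 1) -> Tensor:
    """Same-size 2D convolution (cross-correlation), NCHW input, FCHW weights.

    Implemented as one materialized im2col plus BLAS matmuls; the input
    gradient is scattered back with one slice-add per kernel offset.
    """
    f, c, kh, kw = w.data.shape
    bsz, _, h, wd = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,H,W,kh,kw
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                               ).reshape(bsz * h * wd, c * kh * kw)
    wmat = w.data.reshape(f, c * kh * kw)
    out = (col @ wmat.T).reshape(bsz, h, wd, f).transpose(0, 3, 1, 2)
    out = out + b.data[None, :, None, None]

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)
                                    ).reshape(bsz * h * wd, f)
        if w.requires_grad:
            w._accum((gmat.T @ col).reshape(f, c, kh, kw))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = (gmat @ wmat).reshape(bsz, h, wd, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + h, j:j + wd] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._accum(dxp[:, :, padding:padding + h, padding:padding + wd])

    return Tensor._make(out, (x, w, b), backward)


def maxpool2d(x: Tensor) -> Tensor:
    """2×2 max pooling, stride 2; spatial dims must be even."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2d needs even spatial dimensions")
    xr = (x.data.reshape(B, C, H // 2, 2, W // 2, 2)
          .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4))
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        x._accum(gr.reshape(B, C, H // 2, W // 2, 2, 2)
                 .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W))

    return Tensor._make(out, (x,), backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running: dict | None = None, training: bool = True,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (batch, H, W).

    ``running`` is a dict with "mean"/"var" arrays updated in training mode
    and used verbatim in evaluation mode.
    """
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        if running is not None:
            running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
            running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        if running is None:
            raise ValueError("evaluation mode requires running statistics")
        mean, var = running["mean"], running["var"]
    m = mean[None, :, None, None]
    ivstd = 1.0 / np.sqrt(var + eps)[None, :, None, None]
    xhat = (x.data - m) * ivstd
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gxh = g * gamma.data[None, :, None, None]
            if training:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gxh.sum(axis=axes, keepdims=True)
                s2 = (gxh * xhat).sum(axis=axes, keepdims=True)
                x._accum(ivstd * (gxh - s1 / n - xhat * s2 / n))
            else:
                x._accum(gxh * ivstd)

    return Tensor._make(out, (x, gamma, beta), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted dropout: identity in evaluation mode."""
    if not training or rate == 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)

    def backward(g):
        x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def solve(a: Tensor, b: Tensor) -> Tensor:
    """X = A⁻¹ B for square A. Backward: dB = A⁻ᵀ Ḡ, dA = −dB Xᵀ."""
    x_data = np.linalg.solve(a.data, b.data)

    def backward(g):
        gb = np.linalg.solve(a.data.T, g)
        if b.requires_grad:
            b._accum(gb)
        if a.requires_grad:
            a._accum(-gb @ x_data.T)

    return Tensor._make(x_data, (a, b), backward)


def cross_entropy_mean(scores: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-softmax-probability of the true class.

    ``scores`` is (n_items, n_classes); ``labels`` integer class indices.
    """
    labels = np.asarray(labels)
    n = scores.data.shape[0]
    shifted = scores.data - scores.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        scores._accum(g * p / n)

    return Tensor._make(loss, (scores,), backward)
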