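"""A small reverse-mode automatic differentiation engine on numpy arrays.

This powers the 1-D CNN-BiLSTM-attention regressor.  It implements exactly
the operations that network needs — broadcast arithmetic, (batched) matmul,
pointwise nonlinearities, reductions, shape ops, softmax, 1-D convolution
and a Smooth-L1 loss — each with an analytic backward rule.  Gradients are
accumulated by a topologically ordered sweep over the recorded tape; the
whole engine is verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce *grad* back to *shape* after numpy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- construction helpers ---------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            _accum(self, _unbroadcast(g, self.shape))
            _accum(other, _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            _accum(self, _unbroadcast(g * other.data, self.shape))
            _accum(other, _unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            _accum(self, _unbroadcast(g / other.data, self.shape))
            _accum(other, _unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: _accum(self, g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            _accum(self, _unbroadcast(ga, self.shape))
            _accum(other, _unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- pointwise ---------------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: _accum(self, g * (1.0 - y**2))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: _accum(self, g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: _accum(self, g * y)
        return out

    def leaky_relu(self, alpha: float = 0.01):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, alpha * self.data), parents=(self,))
        out._backward = lambda g: _accum(self, g * np.where(mask, 1.0, alpha))
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: _accum(self, g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward = lambda g: _accum(self, g.transpose(*inverse))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            _accum(self, full)

        out._backward = backward
        return out

    # -- backprop driver ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def _accum(tensor: Tensor, grad: np.ndarray) -> None:
    if not tensor.requires_grad:
        return
    if tensor.grad is None:
        tensor.grad = np.array(grad, dtype=np.float64, copy=True)
    else:
        tensor.grad += grad


# ---------------------------------------------------------------------------
# composite / custom operations
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            _accum(t, np.take(g, i, axis=axis))

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(x, y * (g - dot))

    out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: _accum(x, g * mask)
    return out


def _im2col(data: np.ndarray, kernel: int, stride: int, pad: int):
    """(B, C, T) -> (B, C, T_out, K) sliding windows of the padded signal."""
    padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)))
    t_out = (padded.shape[2] - kernel) // stride + 1
    idx = stride * np.arange(t_out)[:, None] + np.arange(kernel)[None, :]
    return padded[:, :, idx], idx, padded.shape[2], t_out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation along the last axis: x (B,Cin,T), weight (Cout,Cin,K)."""
    kernel = weight.shape[2]
    cols, idx, t_padded, _ = _im2col(x.data, kernel, stride, pad)
    y = np.einsum("bctk,ock->bot", cols, weight.data, optimize=True)
    y += bias.data[None, :, None]
    out = Tensor(y, parents=(x, weight, bias))

    def backward(g):
        _accum(bias, g.sum(axis=(0, 2)))
        _accum(weight, np.einsum("bot,bctk->ock", g, cols, optimize=True))
        if x.requires_grad:
            dcols = np.einsum("bot,ock->bctk", g, weight.data, optimize=True)
            dpad = np.zeros((x.shape[0], x.shape[1], t_padded))
            np.add.at(dpad, (slice(None), slice(None), idx), dcols)
            _accum(x, dpad[:, :, pad: pad + x.shape[2]] if pad else dpad)

    out._backward = backward
    return out


def smooth_l1(pred: Tensor, observed: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean Smooth-L1 (Huber-like) loss against a constant target array."""
    d = pred.data - np.asarray(observed, float)
    absd = np.abs(d)
    small = absd < beta
    loss = np.where(small, 0.5 * d**2 / beta, absd - 0.5 * beta)
    out = Tensor(loss.mean(), parents=(pred,))

    def backward(g):
        grad = np.where(small, d / beta, np.sign(d)) / d.size
        _accum(pred, g * grad)

    out._backward = backward
    return out
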