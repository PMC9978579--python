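"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the encoder/decoder/classifier networks and
their loss terms are implemented.  Tensors form a DAG; ``backward()`` runs a
topological sweep accumulating gradients into ``grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=np.float64)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)

        def _bw():
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._make(self.data**exponent, (self,), None)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = _bw
        return out

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out = Tensor._make(np.exp(self.data), (self,), None)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _bw
        return out

    def sqrt(self):
        out = Tensor._make(np.sqrt(self.data), (self,), None)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * 0.5 / np.maximum(out.data, 1e-300))

        out._backward = _bw
        return out

    def abs(self):
        out = Tensor._make(np.abs(self.data), (self,), None)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data))

        out._backward = _bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through inside [lo, hi] only."""
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)

        def _bw():
            if self.requires_grad:
                mask = (self.data >= lo) & (self.data <= hi)
                self._accum(out.grad * mask)

        out._backward = _bw
        return out

    def leaky_relu(self, slope: float = 0.01):
        out = Tensor._make(
            np.where(self.data > 0, self.data, slope * self.data), (self,), None
        )

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, slope))

        out._backward = _bw
        return out

    # -- reductions / indexing -------------------------------------------
    def sum(self, axis=None):
        out = Tensor._make(self.data.sum(axis=axis), (self,), None)

        def _bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / n

    def take_rows(self, idx):
        idx = np.asarray(idx)
        out = Tensor._make(self.data[idx], (self,), None)

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = _bw
        return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean multiclass cross-entropy from raw logits (numerically stable)."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = z.shape[0]
    value = -logp[np.arange(n), labels].mean()
    out = Tensor._make(np.asarray(value), (logits,), None)

    def _bw():
        if logits.requires_grad:
            softmax = np.exp(logp)
            softmax[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * softmax / n)

    out._backward = _bw
    return out


class Adam:
    """Standard Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self._m[i] = b1 * self._m[i] + (1 - b1) * p.grad
            self._v[i] = b2 * self._v[i] + (1 - b2) * p.grad**2
            m_hat = self._m[i] / (1 - b1**self.t)
            v_hat = self._v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
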