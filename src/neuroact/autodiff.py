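"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the ZINB bottleneck autoencoder needs:
dense layers, batch normalization, ELU/sigmoid/softplus activations, the
log-gamma function for the negative-binomial likelihood, and reductions.
Gradients are exact (verified against central finite differences in the
test suite), which also makes the engine the source of the input-to-bottleneck
gradients used for feature attribution.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln

__all__ = ["Tensor", "as_tensor", "concat", "Dense", "BatchNorm", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the computation graph. `data` is always float64."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    # make numpy defer to Tensor's reflected operators (ndarray op Tensor)
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = bool(
            requires_grad or any(p.requires_grad for p in parents)
        )

    @property
    def shape(self):
        return self.data.shape

    # ---- graph traversal -------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or pgrad is None:
                    continue
                pgrad = _unbroadcast(pgrad, parent.data.shape)
                parent.grad = pgrad if parent.grad is None else parent.grad + pgrad

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            (self, other),
            lambda g: (g, g),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            (self, other),
            lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            (self, other),
            lambda g: (g / other.data, -g * self.data / other.data**2),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    # ---- elementwise functions -------------------------------------------

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, (self,), lambda g: (g * 0.5 / out,))

    def square(self):
        return Tensor(self.data**2, (self,), lambda g: (g * 2.0 * self.data,))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, (self,), lambda g: (g * out * (1.0 - out),))

    def elu(self, alpha: float = 1.0):
        neg = self.data < 0
        out = np.where(neg, alpha * np.expm1(self.data), self.data)
        deriv = np.where(neg, alpha * np.exp(self.data), 1.0)
        return Tensor(out, (self,), lambda g: (g * deriv,))

    def softplus(self):
        out = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, (self,), lambda g: (g * sig,))

    def lgamma(self):
        return Tensor(
            gammaln(self.data), (self,), lambda g: (g * digamma(self.data),)
        )

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)
        return Tensor(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * inside,)
        )

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor(out, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- structural ------------------------------------------------------

    def stop_gradient(self):
        return Tensor(self.data.copy())


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back
    )


# ---------------------------------------------------------------------------
# Neural-network building blocks
# ---------------------------------------------------------------------------


class Dense:
    """Fully connected layer, Glorot-uniform initialised."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class BatchNorm:
    """Batch normalization with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = Tensor(np.ones(n), requires_grad=True)
        self.beta = Tensor(np.zeros(n), requires_grad=True)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = (x - mu).square().mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta

    @property
    def params(self):
        return [self.gamma, self.beta]


class Adam:
    """ADAM optimizer (Kingma & Ba) over a flat parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7,
                 lr_scales=None):
        self.params = list(params)
        self.lr = lr
        self.lr_scales = (
            np.ones(len(self.params)) if lr_scales is None else np.asarray(lr_scales)
        )
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * self.lr_scales[i] * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
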