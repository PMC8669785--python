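"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the conv/GRU/attention models:
broadcasting arithmetic, 2-D matmul, pointwise nonlinearities, reductions,
concatenation, a 3x3 same-padded convolution and a 2x2 max-pool. Gradients
are accumulated by an iterative topological-order sweep, so deep unrolled
recurrences (hundreds of time steps) do not hit the recursion limit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3x3", "maxpool2x2", "time_slice", "Adam", "set_dtype"]

# Compute dtype. float32 halves memory traffic, which dominates the runtime
# of the per-window convolutions; gradient-check tests switch to float64.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = dtype


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
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
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        out._backward = backward
        return out

    # -- pointwise nonlinearities ----------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * (1.0 - y**2),)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -80, 80))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    # -- reductions & shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    # -- autodiff driver --------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological sort
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pg in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or pg is None:
                    continue  # None: accumulated in place by the op itself
                # first contribution keeps the reference; later ones allocate
                parent.grad = pg if parent.grad is None else parent.grad + pg


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = backward
    return out


def conv3x3(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 3x3 convolution.

    x: (N, H, W, Cin); weight: (3, 3, Cin, Cout); bias: (Cout,).
    Implemented as 9 shifted batched matmuls (no im2col materialization,
    which would dominate memory traffic at N = batch x windows).
    """
    n, h, w, cin = x.data.shape
    cout = weight.data.shape[-1]
    dtype = x.data.dtype
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    # explicit im2col with contiguous writes, then a single 2-D GEMM
    cols = np.empty((n, h, w, 9 * cin), dtype=dtype)
    offsets = [(di, dj) for di in range(3) for dj in range(3)]
    for k, (di, dj) in enumerate(offsets):
        cols[..., k * cin : (k + 1) * cin] = xp[:, di : di + h, dj : dj + w, :]
    cols2 = cols.reshape(n * h * w, 9 * cin)
    wmat = weight.data.reshape(9 * cin, cout)
    out_data = (cols2 @ wmat + bias.data).reshape(n, h, w, cout)
    out = Tensor(out_data, parents=(x, weight, bias))

    def backward(g):
        g2 = g.reshape(n * h * w, cout)
        db = g2.sum(axis=0)
        dw = (cols2.T @ g2).reshape(3, 3, cin, cout)
        dcols = (g2 @ wmat.T).reshape(n, h, w, 9 * cin)
        dxp = np.zeros_like(xp)
        for k, (di, dj) in enumerate(offsets):
            dxp[:, di : di + h, dj : dj + w, :] += dcols[..., k * cin : (k + 1) * cin]
        return (dxp[:, 1 : 1 + h, 1 : 1 + w, :], dw, db)

    out._backward = backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped.

    The gradient routes to the first maximal element of each 2x2 block
    (row-major), matching an argmax tie-break.
    """
    n, h, w, c = x.data.shape
    h2, w2 = h // 2, w // 2
    positions = [(0, 0), (0, 1), (1, 0), (1, 1)]
    views = [x.data[:, i : 2 * h2 : 2, j : 2 * w2 : 2, :] for i, j in positions]
    out_data = np.maximum.reduce(views)
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        dx = np.zeros_like(x.data)
        alive = np.ones(out_data.shape, dtype=bool)
        for (i, j), xv in zip(positions, views):
            take = alive & (xv == out_data)
            dx[:, i : 2 * h2 : 2, j : 2 * w2 : 2, :] = np.where(take, g, 0)
            alive &= ~take
        return (dx,)

    out._backward = backward
    return out


def time_slice(x: Tensor, t: int) -> Tensor:
    """(B, T, D) -> (B, D) at step t; gradient scattered in place."""
    out = Tensor(x.data[:, t, :], parents=(x,))

    def backward(g):
        if x.grad is None:
            x.grad = np.zeros_like(x.data)
        x.grad[:, t, :] += g
        return (None,)

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
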