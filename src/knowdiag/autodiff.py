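"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's recurrent encoder and classifier head are trained by gradient
descent, so every tensor operation used on the training path is implemented
here as a differentiable node.  The engine is deliberately small: float64
arrays, a static tape built eagerly, and exactly the operators the model
needs (broadcast arithmetic, matmul, tanh/sigmoid/exp/log, reductions,
reshape/transpose/concatenate/slicing, an embedding gather and a clip).

Gradient correctness is established by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "embedding", "masked_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float64 array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # defer mixed ndarray/Tensor arithmetic to Tensor's reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # ---- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _const(x) -> np.ndarray:
        return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)

    def _node(self, data, parents, backward) -> "Tensor":
        if any(p.requires_grad for p in parents):
            return Tensor(data, _parents=parents, _backward=backward)
        return Tensor(data)

    # ---- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Tensor):
            out_data = self.data + other.data

            def backward(g):
                return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

            return self._node(out_data, (self, other), backward)
        od = self._const(other)
        out_data = self.data + od

        def backward(g):
            return (_unbroadcast(g, self.shape),)

        return self._node(out_data, (self,), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return (-g,)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, Tensor):
            out_data = self.data - other.data

            def backward(g):
                return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

            return self._node(out_data, (self, other), backward)
        od = self._const(other)

        def backward(g):
            return (_unbroadcast(g, self.shape),)

        return self._node(self.data - od, (self,), backward)

    def __rsub__(self, other):
        od = self._const(other)

        def backward(g):
            return (_unbroadcast(-g, self.shape),)

        return self._node(od - self.data, (self,), backward)

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out_data = self.data * other.data
            a, b = self, other

            def backward(g):
                return (
                    _unbroadcast(g * b.data, a.shape) if a.requires_grad else None,
                    _unbroadcast(g * a.data, b.shape) if b.requires_grad else None,
                )

            return self._node(out_data, (self, other), backward)
        od = self._const(other)

        def backward(g):
            return (_unbroadcast(g * od, self.shape),)

        return self._node(self.data * od, (self,), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            a, b = self, other
            out_data = a.data / b.data

            def backward(g):
                return (
                    _unbroadcast(g / b.data, a.shape) if a.requires_grad else None,
                    _unbroadcast(-g * a.data / (b.data ** 2), b.shape)
                    if b.requires_grad else None,
                )

            return self._node(out_data, (self, other), backward)
        od = self._const(other)

        def backward(g):
            return (_unbroadcast(g / od, self.shape),)

        return self._node(self.data / od, (self,), backward)

    def __matmul__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other_t
        out_data = a.data @ b.data

        def backward(g):
            ga = gb = None
            if a.requires_grad:
                ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
            if b.requires_grad:
                if a.data.ndim > 2 and b.data.ndim == 2:
                    # stacked @ matrix: one flat gemm instead of a batched
                    # gemm followed by a reduction over the stack axes
                    k = a.data.shape[-1]
                    gb = a.data.reshape(-1, k).T @ g.reshape(-1, g.shape[-1])
                else:
                    gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
            return (ga, gb)

        return self._node(out_data, (a, b), backward)

    # ---- nonlinearities -------------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data ** 2),)

        return self._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return self._node(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return self._node(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through strictly inside [lo, hi]."""
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            return (g * inside,)

        return self._node(np.clip(self.data, lo, hi), (self,), backward)

    # ---- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, shape).copy(),)

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return self._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return self._node(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape, dtype=np.float64)
            full[idx] = g
            return (full,)

        return self._node(out_data, (self,), backward)

    # ---- backward pass --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep for long sequences)
        topo, seen, stack_ = [], set(), [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack_.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


# ---- free functions -----------------------------------------------------------

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    if any(t.requires_grad for t in tensors):
        return Tensor(out_data, _parents=tuple(tensors), _backward=backward)
    return Tensor(out_data)


def stack(tensors, axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = t if isinstance(t, Tensor) else Tensor(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else len(shape) + 1 + axis, 1)
        expanded.append(t.reshape(shape))
    return concat(expanded, axis=axis)


def scatter_rows(src: Tensor, rows: np.ndarray, n_rows: int) -> Tensor:
    """Place the rows of ``src`` at positions ``rows`` of an otherwise-zero
    (n_rows, ...) tensor.  Inverse of row selection; used to skip all-padding
    rows in batched passes."""
    rows = np.asarray(rows)
    out_data = np.zeros((n_rows,) + src.shape[1:], dtype=np.float64)
    out_data[rows] = src.data

    def backward(g):
        return (g[rows],)

    if src.requires_grad:
        return Tensor(out_data, _parents=(src,), _backward=backward)
    return Tensor(out_data)


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup `weight[indices]` with scatter-add gradient into `weight`."""
    indices = np.asarray(indices)
    out_data = weight.data[indices]

    def backward(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, indices.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        return (full,)

    if weight.requires_grad:
        return Tensor(out_data, _parents=(weight,), _backward=backward)
    return Tensor(out_data)


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax restricted to positions where mask == 1.

    Masked positions receive exactly zero weight.  Rows with no unmasked
    position come back as all-zero rather than raising, which is what the
    batched encoder wants for padding-only sentences.
    """
    mask = np.asarray(mask, dtype=np.float64)
    shifted = scores - (1.0 - mask) * 1e9
    # subtracting the (constant) row max is a numerical shift only
    row_max = np.max(shifted.data, axis=axis, keepdims=True)
    expd = (shifted - row_max).exp() * mask
    denom = expd.sum(axis=axis, keepdims=True) + 1e-30
    return expd / denom


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
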