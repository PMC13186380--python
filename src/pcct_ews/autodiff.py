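"""Compact reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model family needs: broadcasting
arithmetic, matmul, reductions, slicing/concatenation, softmax, layer norm,
GELU/ReLU/sigmoid, and an Adam optimiser. Gradients flow to any leaf marked
``requires_grad`` — parameters during training, inputs for Integrated
Gradients.

Arrays are kept in float32 unless constructed from float64 (gradient-check
tests use float64 end to end); accumulation avoids allocation where it can.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        a = np.asarray(data)
        if a.dtype not in (np.float32, np.float64):
            a = a.astype(np.float32)
        self.data = a
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    def _wants_grad(self) -> bool:
        return self.requires_grad or bool(self._parents)

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray):
        if not self._wants_grad():
            return
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        seed = (
            np.ones_like(self.data)
            if grad is None
            else np.asarray(grad, dtype=self.data.dtype)
        )
        self.grad = seed if self.grad is None else self.grad + seed
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                t.grad = None  # free intermediate gradients as we go

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        needs = any(p.requires_grad or p._parents for p in parents)
        if needs:
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            # scalar fast path: python scalars promote weakly (dtype kept)
            c = float(other)

            def bw_s(g):
                self._accumulate(g)

            return self._node(self.data + c, (self,), bw_s)
        other = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            c = float(other)

            def bw_s(g):
                self._accumulate(g * c)

            return self._node(self.data * c, (self,), bw_s)
        other = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            return self + (-float(other))
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return (-self) + other if isinstance(
            other, (int, float, np.floating, np.integer)
        ) else self._wrap(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            return self * (1.0 / float(other))
        return self * other ** -1.0

    def __rtruediv__(self, other):
        inv = self ** -1.0
        if isinstance(other, (int, float, np.floating, np.integer)):
            return inv * float(other)
        return self._wrap(other) * inv

    def __pow__(self, p: float):
        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return self._node(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        return self._node(self.data @ other.data, (self, other), bw)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return self._node(self.data.reshape(*shape), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))

        return self._node(np.swapaxes(self.data, a, b), (self,), bw)

    def __getitem__(self, key):
        basic = all(
            isinstance(k, (int, slice, type(Ellipsis), type(None)))
            for k in (key if isinstance(key, tuple) else (key,))
        )

        def bw(g):
            full = np.zeros_like(self.data)
            if basic:
                full[key] += g  # basic indexing: no duplicate positions
            else:
                np.add.at(full, key, g)
            self._accumulate(full)

        return self._node(self.data[key], (self,), bw)

    # -- reductions & nonlinearities ----------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return self._node(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return self._node(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1 - out_data**2))

        return self._node(out_data, (self,), bw)

    def relu(self):
        def bw(g):
            self._accumulate(g * (self.data > 0))

        return self._node(np.maximum(self.data, 0), (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accumulate(g * out_data * (1 - out_data))

        return self._node(out_data, (self,), bw)

    def gelu(self):
        # tanh approximation, fused forward/backward
        c = float(np.sqrt(2.0 / np.pi))
        xd = self.data
        t = np.tanh(c * (xd + 0.044715 * xd**3))

        def bw(g):
            du = c * (1.0 + 3 * 0.044715 * xd * xd)
            self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * xd * (1.0 - t * t) * du))

        return self._node(0.5 * xd * (1.0 + t), (self,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            t._accumulate(p)

    return Tensor._node(np.concatenate(datas, axis=axis), tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accumulate(out_data * (g - dot))

    return Tensor._node(out_data, (x,), bw)


def causal_attention(q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray) -> Tensor:
    """Fused scaled-dot-product attention with an additive causal mask.

    ``q``, ``k``, ``v`` are (B, H, T, dh); ``mask`` is broadcastable to
    (B, H, T, T) with -inf-like entries above the diagonal. Forward and
    backward are hand-fused to keep the (T, T) intermediates to a minimum —
    the attention matrices dominate memory traffic at these sizes.
    """
    dh = q.shape[-1]
    scale = float(1.0 / np.sqrt(dh))
    s = q.data @ np.swapaxes(k.data, -1, -2)
    s *= scale
    s += mask
    s -= s.max(axis=-1, keepdims=True)
    np.exp(s, out=s)
    s /= s.sum(axis=-1, keepdims=True)
    p = s  # attention weights, retained for backward
    out_data = p @ v.data

    def bw(g):
        dv = np.swapaxes(p, -1, -2) @ g
        dp = g @ np.swapaxes(v.data, -1, -2)
        dp *= p
        dp -= p * dp.sum(axis=-1, keepdims=True)  # softmax jacobian
        dq = (dp @ k.data) * scale
        dk = np.swapaxes(dp, -1, -2) @ q.data
        dk *= scale
        q._accumulate(dq)
        k._accumulate(dk)
        v._accumulate(dv)

    return Tensor._node(out_data, (q, k, v), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis (fused forward/backward)."""
    xd = x.data
    n = xd.shape[-1]
    mu = xd.mean(axis=-1, keepdims=True)
    xc = xd - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def bw(g):
        reduce_axes = tuple(range(g.ndim - 1))
        gamma._accumulate((g * xhat).sum(axis=reduce_axes))
        beta._accumulate(g.sum(axis=reduce_axes))
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return Tensor._node(out_data, (x, gamma, beta), bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (inference) or p == 0."""
    if rng is None or p <= 0:
        return x
    mask = (rng.random(x.shape, dtype=np.float32) >= p) / np.float32(1.0 - p)
    return x * Tensor(mask.astype(x.data.dtype, copy=False))


class Adam:
    """Adam optimiser with optional L2 weight decay and max-norm constraint."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        max_norm: float | None = None,
    ):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.max_norm = max_norm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.max_norm is not None and p.data.ndim >= 2:
                norms = np.linalg.norm(p.data, axis=-1, keepdims=True)
                factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
                p.data *= factor

    def zero_grad(self):
        for p in self.params:
            p.grad = None
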