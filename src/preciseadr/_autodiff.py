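"""Minimal reverse-mode automatic differentiation on numpy arrays.

The neural components of this package (heterogeneous graph encoder,
augmentation branch, predictor, losses) are expressed as compositions of
the primitives below. Gradients are exact (reverse-mode on the recorded
graph) and are validated against central finite differences in the test
suite. Arrays are kept in float64 throughout; the models here are desk
scale (thousands of nodes), so numerical robustness is worth more than
memory.

Only the primitives this package needs are provided: broadcasting
arithmetic, matmul, reductions, the usual pointwise nonlinearities, row
gather / segment scatter-sum (the message-passing primitives), and a
per-head batched linear map.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "tensor", "segment_sum", "take_rows", "head_linear",
           "concat", "segment_softmax", "layer_norm", "Adam",
           "numerical_gradient"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape machinery for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = tensor(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        return Tensor(self.data + other.data, parents=(self, other), backward=back)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def back(g):
            self._accumulate(-g)
        return Tensor(-self.data, parents=(self,), backward=back)

    def __sub__(self, other) -> "Tensor":
        return self + (-tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = tensor(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        return Tensor(self.data * other.data, parents=(self, other), backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = tensor(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                               other.shape))
        return Tensor(self.data / other.data, parents=(self, other), backward=back)

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def back(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))
        return Tensor(self.data ** exponent, parents=(self,), backward=back)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = tensor(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        return Tensor(self.data @ other.data, parents=(self, other), backward=back)

    # -- reductions / shape -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        def back(g):
            self._accumulate(g.reshape(self.shape))
        return Tensor(self.data.reshape(*shape), parents=(self,), backward=back)

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def back(g):
            self._accumulate(g * out_data)
        return Tensor(out_data, parents=(self,), backward=back)

    def log(self) -> "Tensor":
        def back(g):
            self._accumulate(g / self.data)
        return Tensor(np.log(self.data), parents=(self,), backward=back)

    def sigmoid(self) -> "Tensor":
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def back(g):
            self._accumulate(g * out_data * (1.0 - out_data))
        return Tensor(out_data, parents=(self,), backward=back)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def back(g):
            self._accumulate(g * (1.0 - out_data ** 2))
        return Tensor(out_data, parents=(self,), backward=back)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def back(g):
            self._accumulate(g * mask)
        return Tensor(self.data * mask, parents=(self,), backward=back)

    def gelu(self) -> "Tensor":
        """Exact GELU x·Φ(x) with the Gaussian CDF Φ."""
        phi = 0.5 * (1.0 + erf(self.data / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * self.data ** 2) / math.sqrt(2.0 * math.pi)

        def back(g):
            self._accumulate(g * (phi + self.data * pdf))
        return Tensor(self.data * phi, parents=(self,), backward=back)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only where unclamped."""
        mask = (self.data > lo) & (self.data < hi)

        def back(g):
            self._accumulate(g * mask)
        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=back)


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows x[idx] along axis 0 (scatter-add on the way back)."""
    idx = np.asarray(idx, dtype=np.intp)

    def back(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accumulate(acc)
    return Tensor(x.data[idx], parents=(x,), backward=back)


def segment_sum(x: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """out[s] = Σ_{i: seg[i]=s} x[i]; the transpose of take_rows."""
    seg = np.asarray(seg, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out_data, seg, x.data)

    def back(g):
        x._accumulate(g[seg])
    return Tensor(out_data, parents=(x,), backward=back)


def head_linear(x: Tensor, w: Tensor) -> Tensor:
    """Per-head batched linear map: (E,h,d) x (h,d,f) -> (E,h,f)."""
    out_data = np.einsum("ehd,hdf->ehf", x.data, w.data)

    def back(g):
        if x.requires_grad:
            x._accumulate(np.einsum("ehf,hdf->ehd", g, w.data))
        if w.requires_grad:
            w._accumulate(np.einsum("ehd,ehf->hdf", x.data, g))
    return Tensor(out_data, parents=(x, w), backward=back)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    parts = list(tensors)
    sizes = [t.data.shape[axis] for t in parts]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(parts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])
    return Tensor(np.concatenate([t.data for t in parts], axis=axis),
                  parents=tuple(parts), backward=back)


def segment_softmax(scores: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of `scores` within each segment along axis 0.

    Segments with no members simply produce no output rows. The per-segment
    max is subtracted as a constant for numerical stability; the gradient
    of a softmax is invariant to that shift.
    """
    seg = np.asarray(seg, dtype=np.intp)
    m = np.full((num_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(m, seg, scores.data)
    shifted = scores - Tensor(m[seg])
    e = shifted.exp()
    denom = segment_sum(e, seg, num_segments)
    return e / take_rows(denom, seg)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """LayerNorm over the last axis with learnable affine (gamma, beta)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * gamma + beta


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            if self.weight_decay and p.data.ndim >= 2:
                # decoupled decay on weight matrices only (not biases/LN)
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def numerical_gradient(f: Callable[[], Tensor], param: Tensor,
                       eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f() w.r.t. `param` (test utility)."""
    g = np.zeros_like(param.data)
    flat = param.data.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = float(f().data)
        flat[i] = orig - eps
        lo = float(f().data)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return g
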