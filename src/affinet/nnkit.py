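"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model sizes used here (a few dense layers of width <= 64 over a few
thousand graph edges) are small enough that a hand-rolled tape plus numpy
BLAS is fast on one CPU and keeps the package free of heavyweight deep
learning dependencies.  All tensors are float64; gradients are exact to
machine precision, which the equivariance test suite relies on.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "Dense",
    "MLP",
    "Adam",
    "flatten_params",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape machinery for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -----------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: callers may hand us views or reused buffers
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
        # free the tape eagerly: the closure <-> tensor reference cycles
        # otherwise linger until the cyclic GC runs, which is both slow and
        # memory-hungry at our allocation rate. Leaf (parameter) gradients
        # are kept; intermediate gradients die with the graph.
        for node in topo:
            if node._parents:
                node._backward = None
                node._parents = ()
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bwd
        return out

    def sqrt(self) -> "Tensor":
        out = Tensor(np.sqrt(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out.data)

        out._backward = bwd
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data**2))

        out._backward = bwd
        return out

    def silu(self) -> "Tensor":
        sig = expit(self.data)
        out = Tensor(self.data * sig, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * sig * (1.0 + self.data * (1.0 - sig)))

        out._backward = bwd
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bwd
    return out


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows (axis 0) of `t` by integer index."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], _parents=(t,))

    def bwd(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accumulate(acc)

    out._backward = bwd
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given per-row bucket ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    shape = (num_segments,) + t.data.shape[1:]
    acc = np.zeros(shape, dtype=np.float64)
    np.add.at(acc, segment_ids, t.data)
    out = Tensor(acc, _parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g[segment_ids])

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# layers


class Dense:
    """Affine layer y = x @ W + b."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        zero_init: bool = False,
    ):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self) -> dict[str, Tensor]:
        return {"W": self.W, "b": self.b}


class MLP:
    """Dense feed-forward network with SiLU hidden activations.

    `dropout` (rate in [0, 1)) is applied to hidden activations only when a
    training-mode rng is passed to the call; inference is always exact.
    """

    def __init__(
        self,
        sizes: Sequence[int],
        rng: np.random.Generator,
        zero_init_last: bool = False,
        dropout: float = 0.0,
    ):
        self.layers = [
            Dense(a, b, rng, zero_init=(zero_init_last and i == len(sizes) - 2))
            for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:]))
        ]
        self.dropout = float(dropout)

    def __call__(self, x: Tensor, train_rng: np.random.Generator | None = None) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.silu()
                if self.dropout > 0.0 and train_rng is not None:
                    mask = (train_rng.random(x.shape) >= self.dropout) / (1.0 - self.dropout)
                    x = x * Tensor(mask)
        return x

    def params(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"layer{i}.{k}"] = v
        return out


def flatten_params(tree, prefix: str = "") -> dict[str, Tensor]:
    """Flatten a nested dict / object tree of Tensors into {name: Tensor}."""
    out: dict[str, Tensor] = {}
    if isinstance(tree, Tensor):
        out[prefix.rstrip(".")] = tree
    elif isinstance(tree, dict):
        for k, v in tree.items():
            out.update(flatten_params(v, f"{prefix}{k}."))
    elif hasattr(tree, "params"):
        out.update(flatten_params(tree.params(), prefix))
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot flatten {type(tree)!r}")
    return out


class Adam:
    """Adam with linear learning-rate warm-up.

    Moment buffers start at zero; `reset()` zeroes them again (used when a
    pretrained model is re-trained on a new dataset, where stale momenta are
    deliberately discarded).
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        warmup_steps: int = 0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decay_exclude: tuple[str, ...] = (),
    ):
        self.params = params
        self.lr = lr
        self.warmup_steps = int(warmup_steps)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_exclude = tuple(decay_exclude)
        self.reset()

    def reset(self) -> None:
        self.step_count = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def current_lr(self) -> float:
        if self.warmup_steps > 0 and self.step_count < self.warmup_steps:
            return self.lr * (self.step_count + 1) / self.warmup_steps
        return self.lr

    def step(self) -> None:
        lr = self.current_lr()
        self.step_count += 1
        t = self.step_count
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**t)
            vhat = self.v[k] / (1 - self.beta2**t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and not any(s in k for s in self.decay_exclude):
                p.data -= lr * self.weight_decay * p.data  # decoupled decay

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
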