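"""Minimal reverse-mode automatic differentiation over numpy arrays.

The hybrid training loop needs gradients that flow from a segmentation loss,
through classical convolution layers, into the rotation angles of variational
quantum circuits.  This module provides the small tensor/op set that the rest
of the package builds on: elementwise arithmetic with broadcasting, reductions,
shape ops, the activations used by the models, and a hook (`Tensor.from_op`)
for custom operations (convolution, pooling, the circuit simulator) that
supply their own backward functions.

Everything is float64 and eager; graphs are built per forward pass and freed
after `backward()`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Module", "Adam", "cat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward: Callable | None = None

    # -- graph construction -------------------------------------------------

    @classmethod
    def from_op(cls, data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], tuple]) -> "Tensor":
        """Create a tensor produced by an op.

        `backward(out_grad)` must return one gradient array (or None) per
        parent, aligned with `parents`.
        """
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- elementwise arithmetic ---------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out = self.data + other.data
        a, b = self, other

        def backward(g):
            return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

        return Tensor.from_op(out, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor.from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return Tensor.from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = a.data / b.data

        def backward(g):
            return (_unbroadcast(g / b.data, a.data.shape),
                    _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor.from_op(out, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        if not isinstance(p, (int, float)):
            raise TypeError("only scalar exponents are supported")
        a = self
        out = a.data ** p

        def backward(g):
            return (g * p * a.data ** (p - 1),)

        return Tensor.from_op(out, (a,), backward)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for d in sorted(a_norm_axes(ax, a.data.ndim)):
                    g = np.expand_dims(g, d)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor.from_op(out, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[d] for d in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor.from_op(a.data.reshape(shape), (a,),
                              lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor.from_op(a.data.transpose(axes), (a,),
                              lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        a = self

        def backward(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor.from_op(a.data[idx], (a,), backward)

    # -- activations / pointwise functions ------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor.from_op(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor.from_op(s, (a,), lambda g: (g * s * (1.0 - s),))

    def log(self):
        a = self
        return Tensor.from_op(np.log(a.data), (a,), lambda g: (g / a.data,))

    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor.from_op(out, (a,), lambda g: (g * out,))


def a_norm_axes(axes: Iterable[int], ndim: int) -> tuple:
    return tuple(ax % ndim for ax in axes)


def cat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor.from_op(data, tensors, backward)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: recursive parameter discovery, no registration API."""

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
            elif isinstance(value, dict):
                for key, item in value.items():
                    if isinstance(item, Parameter):
                        yield f"{prefix}{name}.{key}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{key}.")

    def parameters(self):
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self, trainable_only: bool = True) -> int:
        return sum(p.size for p in self.parameters()
                   if p.requires_grad or not trainable_only)


class Adam:
    """Adam optimizer with (L2-coupled) weight decay, as in the classic recipe."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
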