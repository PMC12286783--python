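"""Tape-based reverse-mode autodiff on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` plus an optional backward closure and
parent references; calling :meth:`Tensor.backward` on a scalar output walks
the tape in reverse topological order.  Gradients are accumulated on every
tensor that ``requires_grad`` (including intermediates, which the tests use
to check connectivity).  A global :class:`no_grad` context disables taping
for inference.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad) if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar (delegates to ops to avoid import cycles) ------------
    def __add__(self, other):
        from . import ops
        return ops.add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        from . import ops
        return ops.mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        from . import ops
        return ops.sub(self, other)

    def __rsub__(self, other):
        from . import ops
        return ops.sub(other, self)

    def __neg__(self):
        from . import ops
        return ops.mul(self, -1.0)

    def __matmul__(self, other):
        from . import ops
        return ops.matmul(self, other)

    def __truediv__(self, other):
        from . import ops
        return ops.div(self, other)

    def reshape(self, *shape):
        from . import ops
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return ops.reshape(self, shape)

    def transpose(self, axes):
        from . import ops
        return ops.transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        from . import ops
        return ops.sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        from . import ops
        return ops.mean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64)
                                                  if np.isscalar(x) else x)


def make_op(out_data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    """Create an output tensor, recording the tape entry if grad is enabled."""
    out = Tensor(out_data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents)
        out._backward = backward
    return out


def accumulate(t: Tensor, g: np.ndarray) -> None:
    """Add ``g`` into ``t.grad`` if ``t`` participates in the tape."""
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, copy=True)
    else:
        t.grad = t.grad + g
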