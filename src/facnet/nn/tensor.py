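"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every operation that
produced it, a closure that propagates the upstream gradient to its parents.
``Tensor.backward()`` runs the closures in reverse topological order.  The
engine is define-by-run: any composition of the ops in
:mod:`facnet.nn.functional` is differentiable, which is what lets the
feedback-fusion and attention blocks have arbitrary branching topologies
without per-block backward code.

Gradients accumulate (+=) so shared subexpressions are handled correctly.
A global switch (:func:`no_grad`) disables graph construction for inference.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction used by ops ------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward_fn):
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward_fn
        return out

    def _accumulate(self, grad):
        grad = np.asarray(grad)
        if grad.shape != self.data.shape:  # defensive: ops must unbroadcast
            raise ValueError(
                f"gradient shape {grad.shape} != tensor shape {self.data.shape}"
            )
        if self.grad is None:
            self.grad = grad.copy() if not grad.flags.owndata else grad
        else:
            self.grad = self.grad + grad

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar; implementations live in functional.py (set at import)
    def __add__(self, other):
        from . import functional as F

        return F.add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        from . import functional as F

        return F.mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        from . import functional as F

        return F.mul(self, -1.0)

    def __sub__(self, other):
        from . import functional as F

        return F.add(self, F.mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        from . import functional as F

        return F.add(as_tensor(other), F.mul(self, -1.0))

    def __truediv__(self, other):
        from . import functional as F

        return F.div(self, other)

    def __rtruediv__(self, other):
        from . import functional as F

        return F.div(as_tensor(other), self)

    def sum(self, axis=None, keepdims=False):
        from . import functional as F

        return F.sum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        from . import functional as F

        return F.reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))
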