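"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports higher-order derivatives: every vector-Jacobian product is itself
built from :class:`Tensor` operations, so gradients can be differentiated
again (needed for the parameter gradient of the R1 penalty, which involves
the derivative of an input-gradient norm with respect to the network
weights).

Only the operations required by small fully-connected networks are
implemented; this is deliberately not a general tensor library.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "grad", "concat_cols", "clip"]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "requires_grad", "parents", "vjps")

    def __init__(self, data, requires_grad=False, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.parents = parents
        self.vjps = vjps

    @property
    def shape(self):
        return self.data.shape

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __truediv__(self, other):
        return mul(self, pow_const(_as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), pow_const(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __pow__(self, c):
        return pow_const(self, float(c))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _op(data, parents, vjps):
    req = any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=tuple(parents), vjps=tuple(vjps))


def _sum_to(g: Tensor, shape) -> Tensor:
    """Reverse numpy broadcasting: reduce ``g`` down to ``shape``."""
    if g.shape == tuple(shape):
        return g
    ndiff = len(g.shape) - len(shape)
    out = g
    if ndiff > 0:
        out = tsum(out, axis=tuple(range(ndiff)), keepdims=False)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and out.shape[i] != 1)
    if axes:
        out = tsum(out, axis=axes, keepdims=True)
    if out.shape != tuple(shape):
        out = reshape(out, shape)
    return out


# -- primitives ---------------------------------------------------------

def add(x: Tensor, y: Tensor) -> Tensor:
    return _op(
        x.data + y.data,
        (x, y),
        (lambda g: _sum_to(g, x.shape), lambda g: _sum_to(g, y.shape)),
    )


def mul(x: Tensor, y: Tensor) -> Tensor:
    return _op(
        x.data * y.data,
        (x, y),
        (lambda g: _sum_to(mul(g, y), x.shape), lambda g: _sum_to(mul(g, x), y.shape)),
    )


def neg(x: Tensor) -> Tensor:
    return _op(-x.data, (x,), (lambda g: neg(g),))


def pow_const(x: Tensor, c: float) -> Tensor:
    return _op(
        x.data ** c,
        (x,),
        (lambda g: mul(g, mul(Tensor(np.float64(c)), pow_const(x, c - 1.0))),),
    )


def affine(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused x @ w + b (b broadcasts over rows)."""
    return _op(
        x.data @ w.data + b.data,
        (x, w, b),
        (
            lambda g: matmul(g, transpose(w)),
            lambda g: matmul(transpose(x), g),
            lambda g: tsum(g, axis=0, keepdims=True),
        ),
    )


def matmul(x: Tensor, y: Tensor) -> Tensor:
    return _op(
        x.data @ y.data,
        (x, y),
        (lambda g: matmul(g, transpose(y)), lambda g: matmul(transpose(x), g)),
    )


def transpose(x: Tensor) -> Tensor:
    return _op(x.data.T, (x,), (lambda g: transpose(g),))


def texp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)
    return _op(out_data, (x,), (lambda g: mul(g, texp(x)),))


def tlog(x: Tensor) -> Tensor:
    return _op(np.log(x.data), (x,), (lambda g: mul(g, pow_const(x, -1.0)),))


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    return _op(t, (x,), (lambda g: mul(g, 1.0 - pow_const(tanh_ref(x, t), 2.0)),))


def tanh_ref(x: Tensor, t: np.ndarray) -> Tensor:
    # re-expresses the cached forward value as a graph node so that the
    # vjp of tanh stays differentiable
    return _op(t, (x,), (lambda g: mul(g, 1.0 - pow_const(tanh_ref(x, t), 2.0)),))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _op(s, (x,), ())
    if out.requires_grad:
        out.parents = (x,)
        out.vjps = (lambda g: mul(g, mul(out, 1.0 - out)),)
    return out


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)
    return _op(x.data * mask, (x,), (lambda g: mul(g, Tensor(mask)),))


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0))

    def vjp(g):
        # derivative: 1 on the positive branch, alpha*exp(x) on the negative
        neg_exp = texp(mul(x, Tensor((~mask).astype(np.float64))))
        factor = add(
            Tensor(mask.astype(np.float64)),
            mul(Tensor(alpha * (~mask).astype(np.float64)), neg_exp),
        )
        return mul(g, factor)

    return _op(out, (x,), (vjp,))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    mask = ((x.data >= lo) & (x.data <= hi)).astype(np.float64)
    return _op(np.clip(x.data, lo, hi), (x,), (lambda g: mul(g, Tensor(mask)),))


def tsum(x: Tensor, axis=None, keepdims=False) -> Tensor:
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * x.data.ndim), x.shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(a % x.data.ndim for a in axes)
        if not keepdims:
            kshape = tuple(
                1 if i in axes else s for i, s in enumerate(x.shape)
            )
            g = reshape(g, kshape)
        return broadcast_to(g, x.shape)

    return _op(out, (x,), (vjp,))


def tmean(x: Tensor, axis=None, keepdims=False) -> Tensor:
    n = x.data.size if axis is None else np.prod(
        [x.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), Tensor(1.0 / float(n)))


def reshape(x: Tensor, shape) -> Tensor:
    shape = tuple(int(s) for s in shape)
    return _op(x.data.reshape(shape), (x,), (lambda g: reshape(g, x.shape),))


def broadcast_to(x: Tensor, shape) -> Tensor:
    shape = tuple(int(s) for s in shape)
    return _op(
        np.broadcast_to(x.data, shape).copy(), (x,), (lambda g: _sum_to(g, x.shape),)
    )


def concat_cols(tensors) -> Tensor:
    """Concatenate 2-D tensors along the column axis."""
    tensors = [_as_tensor(t) for t in tensors]
    widths = [t.shape[1] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(widths)])

    vjps = []
    for i, t in enumerate(tensors):
        a, b = int(offsets[i]), int(offsets[i + 1])
        vjps.append(lambda g, a=a, b=b: slice_cols(g, a, b))
    return _op(np.concatenate([t.data for t in tensors], axis=1), tensors, vjps)


def slice_cols(x: Tensor, a: int, b: int) -> Tensor:
    return _op(x.data[:, a:b], (x,), (lambda g: pad_cols(g, a, x.shape[1]),))


def pad_cols(x: Tensor, a: int, total: int) -> Tensor:
    out = np.zeros((x.shape[0], total))
    out[:, a : a + x.shape[1]] = x.data
    return _op(out, (x,), (lambda g: slice_cols(g, a, a + x.shape[1]),))


def slice_rows(x: Tensor, a: int, b: int) -> Tensor:
    return _op(x.data[a:b, :], (x,), (lambda g: pad_rows(g, a, x.shape[0]),))


def pad_rows(x: Tensor, a: int, total: int) -> Tensor:
    out = np.zeros((total, x.shape[1]))
    out[a : a + x.shape[0], :] = x.data
    return _op(out, (x,), (lambda g: slice_rows(g, a, a + x.shape[0]),))


# -- reverse pass -------------------------------------------------------

def _topo(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs, grad_output=None):
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``inputs``.

    The returned tensors carry their own graphs, so the result can be
    differentiated again (double backprop).
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")
    seed = Tensor(np.ones_like(output.data)) if grad_output is None else grad_output

    grads: dict[int, Tensor] = {id(output): seed}
    keep = {id(t) for t in inputs}
    for node in reversed(_topo(output)):
        g = grads.get(id(node))
        if g is None:
            continue
        for parent, vjp in zip(node.parents, node.vjps):
            if not parent.requires_grad:
                continue
            contrib = vjp(g)
            prev = grads.get(id(parent))
            grads[id(parent)] = contrib if prev is None else add(prev, contrib)
        if id(node) not in keep:
            del grads[id(node)]

    out = [grads.get(id(t), Tensor(np.zeros(t.shape))) for t in inputs]
    return out[0] if single else out
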