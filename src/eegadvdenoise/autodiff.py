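"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The adversarial training in this package needs gradients of losses with
respect to network weights, and — for the WGAN gradient penalty — gradients
of a *gradient norm* with respect to those weights (double backprop). To
support that, every operation's vector-Jacobian product is itself written
in terms of the same differentiable ops, so the tensors produced by
:func:`grad` are ordinary graph nodes that can be differentiated again.

Only what the models require is implemented: elementwise arithmetic,
matmul, reductions, shaping/slicing, the sigmoid/tanh/ReLU family, and 1-D
(transposed) convolution built from pad + strided slice + matmul. All data
is float64; there is no GPU path and no in-place mutation of graph nodes.

Example
-------
>>> x = Tensor([2.0], requires_grad=True)
>>> y = x * x * x
>>> (g,) = grad(y.sum(), [x])        # dy/dx = 3 x^2 = 12
>>> (h,) = grad(g.sum(), [x])        # d2y/dx2 = 6 x = 12
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "grad", "conv1d", "conv_transpose1d", "concat", "where_positive"]


class Tensor:
    """A float64 array plus the links needed for reverse-mode differentiation."""

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents: Tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self._parents = tuple((p, fn) for p, fn in _parents if p.requires_grad)
        self.requires_grad = bool(requires_grad) or bool(self._parents)

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        """A constant copy cut off from the graph."""
        return Tensor(self.data.copy())

    # ---- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, _ensure(other))

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_ensure(other)))

    def __rsub__(self, other):
        return add(_ensure(other), neg(self))

    def __mul__(self, other):
        return mul(self, _ensure(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, power(_ensure(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_ensure(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, float(p))

    def __matmul__(self, other):
        return matmul(self, _ensure(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    # ---- convenience ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# gradient driver
# ---------------------------------------------------------------------------


def grad(output: Tensor, wrt: Sequence[Tensor], grad_output: Optional[Tensor] = None):
    """Gradients of ``output`` w.r.t. each tensor in ``wrt``.

    The returned tensors are themselves differentiable graph nodes, so
    calling :func:`grad` on (functions of) them yields higher-order
    derivatives. Tensors in ``wrt`` that ``output`` does not depend on get
    zero gradients.
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))

    topo: list = []
    visited = set()

    def build(t: Tensor):
        stack = [(t, iter(t._parents))]
        seen_on_stack = {id(t)}
        visited.add(id(t))
        while stack:
            node, it = stack[-1]
            advanced = False
            for p, _ in it:
                if id(p) not in visited:
                    visited.add(id(p))
                    stack.append((p, iter(p._parents)))
                    seen_on_stack.add(id(p))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack.pop()

    build(output)

    grads = {id(output): grad_output}
    keep = {id(output): output}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None:
            continue
        for parent, vjp in node._parents:
            pg = vjp(g)
            if id(parent) in grads:
                grads[id(parent)] = add(grads[id(parent)], pg)
            else:
                grads[id(parent)] = pg
            keep[id(parent)] = parent

    out = []
    for w in wrt:
        g = grads.get(id(w))
        out.append(g if g is not None else Tensor(np.zeros_like(w.data)))
    return out


# ---------------------------------------------------------------------------
# primitive ops (each VJP is written with these same ops)
# ---------------------------------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return g if g.shape == shape else reshape(g, shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    return Tensor(
        a.data + b.data,
        _parents=(
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ),
    )


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, _parents=((a, lambda g: neg(g)),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    return Tensor(
        a.data * b.data,
        _parents=(
            (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
        ),
    )


def power(a: Tensor, p: float) -> Tensor:
    """Elementwise ``a ** p`` for a Python scalar exponent."""
    a = _ensure(a)
    return Tensor(
        a.data**p,
        _parents=((a, lambda g: mul(g, mul(Tensor(p), power(a, p - 1.0)))),),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _ensure(a), _ensure(b)

    def _swap(t: Tensor) -> Tensor:
        axes = list(range(t.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return transpose(t, tuple(axes))

    return Tensor(
        a.data @ b.data,
        _parents=(
            (a, lambda g: _unbroadcast(matmul(g, _swap(b)), a.shape)),
            (b, lambda g: _unbroadcast(matmul(_swap(a), g), b.shape)),
        ),
    )


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _ensure(a)
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)
    kd_shape = tuple(1 if i in axes else s for i, s in enumerate(a.shape))

    def vjp(g: Tensor) -> Tensor:
        if not keepdims:
            g = reshape(g, kd_shape)
        return broadcast_to(g, a.shape)

    return Tensor(a.data.sum(axis=axes, keepdims=keepdims), _parents=((a, vjp),))


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _ensure(a)
    if axis is None:
        n = a.size
    elif isinstance(axis, int):
        n = a.shape[axis % a.ndim]
    else:
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axis]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    a = _ensure(a)
    return Tensor(
        np.broadcast_to(a.data, shape).copy(),
        _parents=((a, lambda g: _unbroadcast(g, a.shape)),),
    )


def reshape(a: Tensor, shape: tuple) -> Tensor:
    a = _ensure(a)
    return Tensor(a.data.reshape(shape), _parents=((a, lambda g: reshape(g, a.shape)),))


def transpose(a: Tensor, axes: tuple) -> Tensor:
    a = _ensure(a)
    inv = tuple(np.argsort(axes))
    return Tensor(
        a.data.transpose(axes), _parents=((a, lambda g: transpose(g, inv)),)
    )


def getitem(a: Tensor, idx) -> Tensor:
    a = _ensure(a)
    return Tensor(a.data[idx], _parents=((a, lambda g: put(g, a.shape, idx)),))


def put(a: Tensor, shape: tuple, idx) -> Tensor:
    """Scatter ``a`` into zeros of ``shape`` at basic-slice index ``idx``."""
    a = _ensure(a)
    out = np.zeros(shape, dtype=np.float64)
    out[idx] = a.data
    return Tensor(out, _parents=((a, lambda g: getitem(g, idx)),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + [t.shape[axis] for t in tensors])
    parents = []
    for i, t in enumerate(tensors):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        parents.append((t, lambda g, sl=sl: getitem(g, sl)))
    return Tensor(data, _parents=tuple(parents))


def sigmoid(a: Tensor) -> Tensor:
    a = _ensure(a)
    out_data = np.where(
        a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
        np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))),
    )
    out = Tensor(out_data)
    if a.requires_grad:
        out._parents = ((a, lambda g: mul(g, mul(out, add(Tensor(1.0), neg(out))))),)
        out.requires_grad = True
    return out


def tanh(a: Tensor) -> Tensor:
    a = _ensure(a)
    out = Tensor(np.tanh(a.data))
    if a.requires_grad:
        out._parents = ((a, lambda g: mul(g, add(Tensor(1.0), neg(mul(out, out))))),)
        out.requires_grad = True
    return out


def relu(a: Tensor) -> Tensor:
    a = _ensure(a)
    mask = Tensor((a.data > 0).astype(np.float64))
    return Tensor(np.maximum(a.data, 0.0), _parents=((a, lambda g: mul(g, mask)),))


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    a = _ensure(a)
    factor = Tensor(np.where(a.data > 0, 1.0, slope))
    return Tensor(
        np.where(a.data > 0, a.data, slope * a.data),
        _parents=((a, lambda g: mul(g, factor)),),
    )


def exp(a: Tensor) -> Tensor:
    a = _ensure(a)
    out = Tensor(np.exp(a.data))
    if a.requires_grad:
        out._parents = ((a, lambda g: mul(g, out)),)
        out.requires_grad = True
    return out


def log(a: Tensor) -> Tensor:
    a = _ensure(a)
    return Tensor(np.log(a.data), _parents=((a, lambda g: mul(g, power(a, -1.0))),))


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def where_positive(cond_data: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """``a`` where ``cond_data > 0`` else ``b``; the condition is constant."""
    a, b = _ensure(a), _ensure(b)
    mask = Tensor((np.asarray(cond_data) > 0).astype(np.float64))
    return add(mul(mask, a), mul(add(Tensor(1.0), neg(mask)), b))


# ---------------------------------------------------------------------------
# 1-D convolution, composed from pad + strided slice + matmul
# ---------------------------------------------------------------------------


def _pad_last(x: Tensor, left: int, right: int) -> Tensor:
    if left == 0 and right == 0:
        return x
    shape = x.shape[:-1] + (x.shape[-1] + left + right,)
    idx = (Ellipsis, slice(left, left + x.shape[-1]))
    return put(x, shape, idx)


def conv1d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """Cross-correlation of ``x`` (B, C_in, L) with ``w`` (C_out, C_in, K).

    Built as a sum over kernel taps of (C_out, C_in) x (B, C_in, L') matmuls,
    so its VJP — and the VJP of that VJP — come for free from the matmul and
    slicing primitives.
    """
    B, C, L = x.shape
    O, C2, K = w.shape
    if C != C2:
        raise ValueError(f"input has {C} channels but kernel expects {C2}")
    xp = _pad_last(x, padding, padding)
    Lp = L + 2 * padding
    out_len = (Lp - K) // stride + 1
    y = None
    for k in range(K):
        w_k = getitem(w, (slice(None), slice(None), k))  # (O, C)
        x_k = getitem(xp, (Ellipsis, slice(k, k + stride * out_len, stride)))
        term = matmul(w_k, x_k)  # (B, O, out_len)
        y = term if y is None else add(y, term)
    if b is not None:
        y = add(y, reshape(b, (1, O, 1)))
    return y


def conv_transpose1d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 2,
    padding: int = 1,
    output_padding: int = 1,
) -> Tensor:
    """Transposed 1-D convolution; ``w`` has shape (C_in, C_out, K).

    Realized as zero-interleaving (upsampling) followed by a stride-1
    convolution with the flipped, channel-swapped kernel. Output length is
    ``(L - 1) * stride - 2 * padding + K + output_padding`` — with the
    defaults (stride 2, K 3, padding 1, output padding 1) exactly ``2 L``.
    """
    B, C, L = x.shape
    C2, O, K = w.shape
    if C != C2:
        raise ValueError(f"input has {C} channels but kernel expects {C2}")
    pad_l = K - 1 - padding
    pad_r = K - 1 - padding + output_padding
    if pad_l < 0 or pad_r < 0:
        raise ValueError("padding exceeds kernel size - 1")
    z_len = (L - 1) * stride + 1
    z = put(x, (B, C, z_len), (Ellipsis, slice(0, z_len, stride)))
    zp = _pad_last(z, pad_l, pad_r)
    w_flip = getitem(w, (slice(None), slice(None), slice(None, None, -1)))
    w_swap = transpose(w_flip, (1, 0, 2))  # (C_out, C_in, K)
    return conv1d(zp, w_swap, b=b, stride=1, padding=0)
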