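"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numeric core behind the multi-task sequence CNN and the recurrent
architecture controller.  It implements exactly the operations those models
need — broadcasting arithmetic, matmul, the usual pointwise nonlinearities,
reductions, 1-D convolution with dilation and same-padding, and size-4
stride-1 pooling — in float64, which keeps finite-difference gradient checks
meaningful.

Design notes
------------
* ``Tensor`` holds ``data`` (ndarray), ``grad`` (ndarray or None) and a
  closure computing parent gradients; ``backward()`` runs a topological sort.
* Convolution and pooling are implemented as kernel-tap loops (K <= 8 taps),
  each tap a single vectorised einsum/slice — fast enough at desk scale and
  trivially correct in both directions.
* Average pooling over same-padded borders divides by the count of *valid*
  positions, not the nominal window size.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[Array], None] | None = None):
        self.data = _as_array(data)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- graph machinery ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: controller graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g: Array) -> None:
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        def bw(g: Array) -> None:
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor(self.data ** p, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                              self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                               other.data.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- pointwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bw(g: Array) -> None:
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g: Array) -> None:
            self._accumulate(g * (1.0 - out ** 2))

        return Tensor(out, parents=(self,), backward=bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g: Array) -> None:
            self._accumulate(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bw)

    def exp(self):
        out = np.exp(self.data)

        def bw(g: Array) -> None:
            self._accumulate(g * out)

        return Tensor(out, parents=(self,), backward=bw)

    def log(self):
        def bw(g: Array) -> None:
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def clip(self, lo: float, hi: float):
        """Clip values; gradient is passed only where unclipped."""
        mask = (self.data > lo) & (self.data < hi)

        def bw(g: Array) -> None:
            self._accumulate(g * mask)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bw)

    # -- reductions & reshaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g: Array) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g: Array) -> None:
            self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g: Array) -> None:
            self._accumulate(g.transpose(*inv))

        return Tensor(self.data.transpose(*axes), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        def bw(g: Array) -> None:
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accumulate(buf)

        return Tensor(self.data[idx], parents=(self,), backward=bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: Array) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """Same-padded 1-D convolution.

    ``x``: (B, C, L); ``weight``: (F, C, K); output (B, F, L).  The effective
    kernel span is (K-1)*dilation + 1; padding splits it floor-left.
    """
    B, C, L = x.data.shape
    F, Cw, K = weight.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    span = (K - 1) * dilation + 1
    pl = (span - 1) // 2
    pr = span - 1 - pl
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    out = np.zeros((B, F, L))
    for j in range(K):
        s = xp[:, :, j * dilation: j * dilation + L]
        out += np.einsum("bcl,fc->bfl", s, weight.data[:, :, j], optimize=True)
    if bias is not None:
        out += bias.data[None, :, None]

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def bw(g: Array) -> None:
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(K):
                dxp[:, :, j * dilation: j * dilation + L] += np.einsum(
                    "bfl,fc->bcl", g, weight.data[:, :, j], optimize=True)
            x._accumulate(dxp[:, :, pl: pl + L])
        if weight.requires_grad:
            dw = np.zeros_like(weight.data)
            for j in range(K):
                s = xp[:, :, j * dilation: j * dilation + L]
                dw[:, :, j] = np.einsum("bfl,bcl->fc", g, s, optimize=True)
            weight._accumulate(dw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))

    return Tensor(out, parents=parents, backward=bw)


def pool1d(x: Tensor, size: int = 4, mode: str = "max") -> Tensor:
    """Same-padded, stride-1 pooling over the last axis of (B, C, L).

    Max pooling pads with -inf; average pooling divides by the number of
    in-bounds positions under each window.
    """
    B, C, L = x.data.shape
    pl = (size - 1) // 2
    pr = size - 1 - pl
    if mode == "max":
        xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)), constant_values=-np.inf)
        taps = np.stack([xp[:, :, j: j + L] for j in range(size)], axis=0)
        arg = taps.argmax(axis=0)
        out = np.take_along_axis(taps, arg[None], axis=0)[0]

        def bw(g: Array) -> None:
            dxp = np.zeros((B, C, L + size - 1))
            for j in range(size):
                dxp[:, :, j: j + L] += g * (arg == j)
            x._accumulate(dxp[:, :, pl: pl + L])

        return Tensor(out, parents=(x,), backward=bw)

    if mode == "avg":
        xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
        valid = np.pad(np.ones(L), (pl, pr))
        count = np.zeros(L)
        acc = np.zeros((B, C, L))
        for j in range(size):
            acc += xp[:, :, j: j + L]
            count += valid[j: j + L]
        out = acc / count

        def bw(g: Array) -> None:
            gc = g / count
            dxp = np.zeros((B, C, L + size - 1))
            for j in range(size):
                dxp[:, :, j: j + L] += gc
            x._accumulate(dxp[:, :, pl: pl + L])

        return Tensor(out, parents=(x,), backward=bw)

    raise ValueError(f"unknown pooling mode {mode!r}")


def log_softmax(logits: Tensor) -> Tensor:
    """Numerically stable log-softmax over the last axis."""
    m = Tensor(logits.data.max(axis=-1, keepdims=True))  # constant shift
    z = logits - m
    return z - z.exp().sum(axis=-1, keepdims=True).log()


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def parameter(rng: np.random.Generator, *shape: int, scale: float | None = None,
              fan_in: int | None = None) -> Tensor:
    """Trainable tensor with Kaiming-uniform init (gain for ReLU nets).

    The default bound is sqrt(6/fan_in), i.e. variance 2/fan_in; ``fan_in``
    defaults to the product of all dims after the first (convolution layout
    (out, in, k)) and can be given explicitly for (in, out) matmul weights.
    """
    if scale is None:
        if fan_in is None:
            fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
        scale = float(np.sqrt(6.0 / max(fan_in, 1)))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)
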