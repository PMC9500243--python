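"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the detector needs: elementwise arithmetic
with broadcasting, matmul, 2-D convolution (im2col + BLAS), fused batch
normalization, nearest-neighbour 2x upsampling, channel concatenation,
activations, and gather-style indexing.  Gradients of every op are verified
against central finite differences in the test suite.

Tensors are thin wrappers around ``numpy.ndarray``; dtype follows the data
(float32 for training, float64 for gradient checks).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "concat",
    "maximum",
    "minimum",
    "conv2d",
    "batchnorm2d",
    "upsample2x",
    "Module",
    "ModuleList",
    "Conv2d",
    "BatchNorm2d",
    "Adam",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(x, like: "Tensor | None" = None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        if like is not None and arr.dtype != like.data.dtype:
            arr = arr.astype(like.data.dtype)
        return Tensor(arr)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self and not isinstance(node, Parameter):
                node._parents = ()
                node._backward = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other, self)
        out = _node(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                _accum(self, _unbroadcast(g, self.data.shape))
                _accum(other, _unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other, self))

    def __rsub__(self, other):
        return Tensor._wrap(other, self) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other, self)
        out = _node(self.data * other.data, (self, other))
        if out.requires_grad:
            a_data, b_data = self.data, other.data
            def bw(g):
                _accum(self, _unbroadcast(g * b_data, a_data.shape))
                _accum(other, _unbroadcast(g * a_data, b_data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other, self)
        out = _node(self.data / other.data, (self, other))
        if out.requires_grad:
            a_data, b_data = self.data, other.data
            def bw(g):
                _accum(self, _unbroadcast(g / b_data, a_data.shape))
                _accum(other, _unbroadcast(-g * a_data / (b_data * b_data), b_data.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor._wrap(other, self) / self

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))
        if out.requires_grad:
            x = self.data
            out._backward = lambda g: _accum(self, g * p * x ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other, self)
        out = _node(self.data @ other.data, (self, other))
        if out.requires_grad:
            a_data, b_data = self.data, other.data
            def bw(g):
                _accum(self, g @ b_data.T)
                _accum(other, a_data.T @ g)
            out._backward = bw
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out.requires_grad:
            orig = self.data.shape
            out._backward = lambda g: _accum(self, g.reshape(orig))
        return out

    def transpose(self, *axes):
        out = _node(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: _accum(self, g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out.requires_grad:
            shape, dtype = self.data.shape, self.data.dtype
            def bw(g):
                full = np.zeros(shape, dtype=dtype)
                np.add.at(full, idx, g)
                _accum(self, full)
            out._backward = bw
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                _accum(self, np.broadcast_to(g, shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _node(e, (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, g * e)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out.requires_grad:
            x = self.data
            out._backward = lambda g: _accum(self, g / x)
        return out

    def arctan(self):
        out = _node(np.arctan(self.data), (self,))
        if out.requires_grad:
            x = self.data
            out._backward = lambda g: _accum(self, g / (1.0 + x * x))
        return out

    def softplus(self):
        """log(1 + exp(x)), computed stably; derivative sigmoid(x)."""
        out = _node(np.logaddexp(0.0, self.data), (self,))
        if out.requires_grad:
            s = 1.0 / (1.0 + np.exp(-self.data))
            out._backward = lambda g: _accum(self, g * s)
        return out

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, slope * self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, np.where(mask, g, slope * g))
        return out


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g if g.dtype == t.data.dtype else g.astype(t.data.dtype)
    else:
        t.grad += g


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                _accum(t, piece)
        out._backward = bw
    return out


def maximum(a, b) -> Tensor:
    a = Tensor._wrap(a)
    b = Tensor._wrap(b, a)
    mask = a.data >= b.data
    out = _node(np.where(mask, a.data, b.data), (a, b))
    if out.requires_grad:
        def bw(g):
            _accum(a, _unbroadcast(np.where(mask, g, 0.0), a.data.shape))
            _accum(b, _unbroadcast(np.where(mask, 0.0, g), b.data.shape))
        out._backward = bw
    return out


def minimum(a, b) -> Tensor:
    a = Tensor._wrap(a)
    b = Tensor._wrap(b, a)
    mask = a.data <= b.data
    out = _node(np.where(mask, a.data, b.data), (a, b))
    if out.requires_grad:
        def bw(g):
            _accum(a, _unbroadcast(np.where(mask, g, 0.0), a.data.shape))
            _accum(b, _unbroadcast(np.where(mask, 0.0, g), b.data.shape))
        out._backward = bw
    return out


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    s0, s1, s2, s3 = xp.strides
    view = as_strided(
        xp, (n, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride))
    # (C*k*k, N*Ho*Wo), contiguous copy
    return view.transpose(1, 2, 3, 0, 4, 5).reshape(c * k * k, n * ho * wo)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """NCHW convolution. weight: (Cout, Cin, k, k)."""
    n, cin, h, w = x.data.shape
    cout, cin_w, k, _ = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = _im2col(xp, k, stride, ho, wo)
    wmat = weight.data.reshape(cout, cin * k * k)
    out_mat = wmat @ cols  # (Cout, N*Ho*Wo)
    out_data = out_mat.reshape(cout, n, ho, wo).transpose(1, 0, 2, 3)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(np.ascontiguousarray(out_data), parents)
    if out.requires_grad:
        def bw(g):
            gmat = g.transpose(1, 0, 2, 3).reshape(cout, n * ho * wo)
            if bias is not None:
                _accum(bias, g.sum(axis=(0, 2, 3)))
            _accum(weight, (gmat @ cols.T).reshape(weight.data.shape))
            if x.requires_grad:
                dcols = (wmat.T @ gmat).reshape(cin, k, k, n, ho, wo)
                dxp = np.zeros(
                    (n, cin, h + 2 * pad, w + 2 * pad), dtype=x.data.dtype)
                for ky in range(k):
                    for kx in range(k):
                        dxp[:, :,
                            ky:ky + stride * ho:stride,
                            kx:kx + stride * wo:stride] += \
                            dcols[:, ky, kx].transpose(1, 0, 2, 3)
                _accum(x, dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp)
        out._backward = bw
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Fused batch normalization over (N, H, W) per channel."""
    if training:
        axes = (0, 2, 3)
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = _node(out_data, (x, gamma, beta))
    if out.requires_grad:
        def bw(g):
            axes = (0, 2, 3)
            _accum(beta, g.sum(axis=axes))
            _accum(gamma, (g * xhat).sum(axis=axes))
            if x.requires_grad:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
                if training:
                    gm = g.mean(axis=axes)[None, :, None, None]
                    gxm = (g * xhat).mean(axis=axes)[None, :, None, None]
                    _accum(x, gs * (g - gm - xhat * gxm))
                else:
                    _accum(x, gs * g)
        out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling (NCHW)."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = _node(out_data, (x,))
    if out.requires_grad:
        n, c, h, w = x.data.shape
        def bw(g):
            _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Module:
    """Tiny nn.Module analogue: attribute-based submodule/parameter discovery."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterable[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterable[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):  # declared by subclasses
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(params) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"state_dict missing keys: {sorted(missing)[:5]} ...")
        for name, p in params.items():
            p.data = np.asarray(state[name]).astype(p.data.dtype).copy()
        for name, buf in bufs.items():
            np.copyto(buf, np.asarray(state[name]))


class ModuleList(Module):
    def __init__(self, modules: Sequence[Module] = ()):
        super().__init__()
        self._items: list[Module] = list(modules)

    def append(self, m: Module) -> None:
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def _children(self):
        for i, m in enumerate(self._items):
            yield str(i), m

    def forward(self, x):
        for m in self._items:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        scale = math.sqrt(2.0 / fan_in)  # He init for leaky-ReLU stacks
        self.weight = Parameter(
            (rng.standard_normal((cout, cin, k, k)) * scale).astype(np.float32))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None
        self.stride = stride
        self.pad = k // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                           self.running_var, self.training, self.momentum,
                           self.eps)


class Adam:
    """Adam with decoupled lr that can be reassigned between steps."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
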