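"""Minimal reverse-mode autodiff and neural-network layers on NumPy.

Everything operates on NHWC float32 arrays.  The graph is a dynamic tape:
each :class:`Tensor` records the backward closure of the op that produced
it, and :meth:`Tensor.backward` runs the tape in reverse topological order.
Convolutions are lowered to a single GEMM via im2col so that the heavy
lifting happens inside BLAS; spatial resizing is expressed as two separable
matrix products, which makes its transpose (the gradient) exact.

Only the operations the segmentation network needs are implemented; this is
not a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm",
    "Dense",
    "relu",
    "sigmoid",
    "silu",
    "concat",
    "resize_bilinear",
    "global_avg_pool",
    "Adam",
    "mac_meter",
    "add_macs",
]

# ---------------------------------------------------------------------------
# MAC metering
# ---------------------------------------------------------------------------

_MAC_METER: list | None = None


class mac_meter:
    """Context manager that accumulates multiply-accumulate counts.

    While active, every conv/dense forward adds ``k_h*k_w*C_in*C_out*H_out*
    W_out / groups`` (or ``C_in*C_out`` for dense layers) to the meter.
    Normalisation, activations, resizes and element-wise ops cost zero.
    """

    def __init__(self) -> None:
        self.total = 0
        self.by_kind = {"conv": 0, "dense": 0}

    def __enter__(self) -> "mac_meter":
        global _MAC_METER
        self._prev = _MAC_METER
        _MAC_METER = self
        return self

    def __exit__(self, *exc) -> None:
        global _MAC_METER
        _MAC_METER = self._prev


def add_macs(n: int, kind: str = "conv") -> None:
    if _MAC_METER is not None:
        _MAC_METER.total += int(n)
        _MAC_METER.by_kind[kind] = _MAC_METER.by_kind.get(kind, 0) + int(n)


# ---------------------------------------------------------------------------
# Tensor / tape
# ---------------------------------------------------------------------------


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [t]
            while stack:
                node = stack[-1]
                if id(node) in seen:
                    stack.pop()
                    continue
                unvisited = [p for p in node._prev if id(p) not in seen]
                if unvisited:
                    stack.extend(unvisited)
                else:
                    seen.add(id(node))
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free closure + grad buffers of interior nodes promptly
            node._backward = None
            node._prev = ()
            if not node.requires_grad and node is not self:
                node.grad = None

    # -- arithmetic --------------------------------------------------------
    def _binop(self, other, fwd, bwd_self, bwd_other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(fwd(self.data, other.data))
        out._prev = (self, other)

        def _back(g):
            self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        out._backward = _back
        return out

    def __add__(self, other):
        return self._binop(other, lambda a, b: a + b,
                           lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __mul__(self, other):
        return self._binop(other, lambda a, b: a * b,
                           lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __sub__(self, other):
        return self._binop(other, lambda a, b: a - b,
                           lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return other.__sub__(self)

    def __truediv__(self, other):
        return self._binop(other, lambda a, b: a / b,
                           lambda g, a, b: g / b,
                           lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return self * -1.0

    def square(self):
        return self * self

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32))
        out._prev = (self,)
        shape = self.data.shape

        def _back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).astype(np.float32))
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accum(np.broadcast_to(g, shape).astype(np.float32))

        out._backward = _back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# activations and shape ops
# ---------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0))
    out._prev = (x,)
    mask = x.data > 0

    def _back(g):
        x._accum(g * mask)

    out._backward = _back
    return out


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def sigmoid(x: Tensor) -> Tensor:
    s = _expit(x.data)
    out = Tensor(s)
    out._prev = (x,)

    def _back(g):
        x._accum(g * s * (1.0 - s))

    out._backward = _back
    return out


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x) — the backbone's activation."""
    s = _expit(x.data)
    out = Tensor(x.data * s)
    out._prev = (x,)

    def _back(g):
        x._accum(g * (s * (1.0 + x.data * (1.0 - s))))

    out._backward = _back
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._prev = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = _back
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,H,W,C) -> (N,C)."""
    return x.mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# bilinear resize as separable matrix products
# ---------------------------------------------------------------------------

_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _resize_matrix(src: int, dst: int) -> np.ndarray:
    """Half-pixel-centred bilinear interpolation matrix (dst x src)."""
    key = (src, dst)
    m = _RESIZE_CACHE.get(key)
    if m is not None:
        return m
    pos = (np.arange(dst, dtype=np.float64) + 0.5) * (src / dst) - 0.5
    pos = np.clip(pos, 0, src - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    w = (pos - lo).astype(np.float64)
    m = np.zeros((dst, src), dtype=np.float32)
    m[np.arange(dst), lo] += (1.0 - w).astype(np.float32)
    m[np.arange(dst), hi] += w.astype(np.float32)
    _RESIZE_CACHE[key] = m
    return m


def _apply_h(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    # x: (N,H,W,C), m: (Ho,H) -> (N,Ho,W,C)
    n, h, w, c = x.shape
    y = m @ x.transpose(1, 0, 2, 3).reshape(h, -1)
    return y.reshape(m.shape[0], n, w, c).transpose(1, 0, 2, 3)


def _apply_w(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    y = m @ x.transpose(2, 0, 1, 3).reshape(w, -1)
    return y.reshape(m.shape[0], n, h, c).transpose(1, 2, 0, 3)


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    ho, wo = out_hw
    n, h, w, c = x.data.shape
    if (h, w) == (ho, wo):
        return x
    mh = _resize_matrix(h, ho)
    mw = _resize_matrix(w, wo)
    out = Tensor(_apply_w(_apply_h(x.data, mh), mw))
    out._prev = (x,)

    def _back(g):
        x._accum(_apply_w(_apply_h(g, mh.T), mw.T))

    out._backward = _back
    return out


# ---------------------------------------------------------------------------
# im2col convolution
# ---------------------------------------------------------------------------


def _same_pads(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """Returns (cols, pads, out_hw). cols: (N, Ho, Wo, kh, kw, C)."""
    n, h, w, c = x.shape
    pt, pb = _same_pads(h, kh, stride)
    pl, pr = _same_pads(w, kw, stride)
    if pt or pb or pl or pr:
        x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]            # (N, Ho, Wo, C, kh, kw)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols, (pt, pb, pl, pr), cols.shape[1:3]


def _col2im(gcols: np.ndarray, in_shape, kh, kw, stride, pads):
    n, h, w, c = in_shape
    pt, pb, pl, pr = pads
    gx = np.zeros((n, h + pt + pb, w + pl + pr, c), dtype=np.float32)
    ho, wo = gcols.shape[1:3]
    for i in range(kh):
        for j in range(kw):
            gx[:, i:i + ho * stride:stride, j:j + wo * stride:stride, :] += gcols[:, :, :, i, j, :]
    return gx[:, pt:pt + h, pl:pl + w, :]


class Module:
    """Base class: parameter discovery by attribute walk."""

    name: str = ""

    def params(self) -> list[Parameter]:
        found: list[Parameter] = []
        seen = set()

        def walk(obj):
            for k, v in vars(obj).items():
                if k.startswith("_"):       # private refs are not owned params
                    continue
                if isinstance(v, Parameter):
                    if id(v) not in seen:
                        seen.add(id(v))
                        found.append(v)
                elif isinstance(v, Module):
                    if id(v) not in seen:
                        seen.add(id(v))
                        walk(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Module) and id(item) not in seen:
                            seen.add(id(item))
                            walk(item)
                        elif isinstance(item, Parameter) and id(item) not in seen:
                            seen.add(id(item))
                            found.append(item)

        walk(self)
        return found

    def submodules(self) -> list["Module"]:
        found: list[Module] = []
        seen = {id(self)}

        def walk(obj):
            for k, v in vars(obj).items():
                if k.startswith("_"):
                    continue
                items = v if isinstance(v, (list, tuple)) else [v]
                for item in items:
                    if isinstance(item, Module) and id(item) not in seen:
                        seen.add(id(item))
                        found.append(item)
                        walk(item)

        walk(self)
        return found

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.params()))


class Conv2d(Module):
    """2-D convolution, 'same' padding, optional bias."""

    def __init__(self, cin, cout, kernel, stride=1, bias=True, rng=None, name=""):
        kh, kw = kernel if isinstance(kernel, tuple) else (kernel, kernel)
        self.cin, self.cout, self.kh, self.kw, self.stride = cin, cout, kh, kw, stride
        self.name = name
        rng = rng or np.random.default_rng(0)
        fan_in = kh * kw * cin
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           (kh, kw, cin, cout)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        cols, pads, (ho, wo) = _im2col(x.data, self.kh, self.kw, self.stride)
        n = x.data.shape[0]
        flat = cols.reshape(n * ho * wo, -1)
        wmat = self.weight.data.reshape(-1, self.cout)
        y = flat @ wmat
        if self.bias is not None:
            y += self.bias.data
        add_macs(self.kh * self.kw * self.cin * self.cout * ho * wo)
        out = Tensor(y.reshape(n, ho, wo, self.cout))
        out._prev = (x, self.weight) + ((self.bias,) if self.bias is not None else ())
        in_shape = x.data.shape

        def _back(g):
            gflat = g.reshape(n * ho * wo, self.cout)
            self.weight._accum((flat.T @ gflat).reshape(self.weight.data.shape))
            if self.bias is not None:
                self.bias._accum(gflat.sum(axis=0))
            gcols = (gflat @ wmat.T).reshape(n, ho, wo, self.kh, self.kw, self.cin)
            x._accum(_col2im(gcols, in_shape, self.kh, self.kw, self.stride, pads))

        out._backward = _back
        return out

    def macs(self, out_h: int, out_w: int) -> int:
        return self.kh * self.kw * self.cin * self.cout * out_h * out_w


class DepthwiseConv2d(Module):
    """Depthwise convolution (groups == channels)."""

    def __init__(self, channels, kernel, stride=1, rng=None, name=""):
        self.c, self.k, self.stride = channels, kernel, stride
        self.name = name
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           (kernel, kernel, channels)))

    def __call__(self, x: Tensor) -> Tensor:
        cols, pads, (ho, wo) = _im2col(x.data, self.k, self.k, self.stride)
        y = np.einsum("nhwijc,ijc->nhwc", cols, self.weight.data, optimize=True)
        add_macs(self.k * self.k * self.c * ho * wo)
        out = Tensor(y)
        out._prev = (x, self.weight)
        in_shape = x.data.shape

        def _back(g):
            self.weight._accum(np.einsum("nhwijc,nhwc->ijc", cols, g, optimize=True))
            gcols = g[:, :, :, None, None, :] * self.weight.data[None, None, None]
            x._accum(_col2im(gcols, in_shape, self.k, self.k, self.stride, pads))

        out._backward = _back
        return out


class BatchNorm(Module):
    """Channel-wise batch normalisation over (N,H,W).

    ``scale=False`` keeps only the shift beta (the form used in the decoder's
    asymmetric-convolution branches); batch statistics in training mode,
    frozen running statistics in inference mode.
    """

    def __init__(self, channels, scale=True, momentum=0.9, eps=1e-3, name=""):
        self.c, self.eps, self.momentum = channels, eps, momentum
        self.name = name
        self.gamma = Parameter(np.ones(channels)) if scale else None
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        red = tuple(range(x.data.ndim - 1))
        if training:
            mean = x.data.mean(axis=red)
            var = x.data.var(axis=red)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean) * invstd
        y = xhat
        if self.gamma is not None:
            y = y * self.gamma.data
        y = y + self.beta.data
        out = Tensor(y)
        out._prev = (x, self.beta) + ((self.gamma,) if self.gamma is not None else ())
        m = x.data.size // self.c

        def _back(g):
            gsum = g.sum(axis=red)
            self.beta._accum(gsum)
            if self.gamma is not None:
                self.gamma._accum((g * xhat).sum(axis=red))
                gxhat = g * self.gamma.data
            else:
                gxhat = g
            if training:
                # full batch-norm gradient (statistics depend on x)
                gx = (gxhat - gxhat.mean(axis=red)
                      - xhat * (gxhat * xhat).sum(axis=red) / m) * invstd
            else:
                gx = gxhat * invstd
            x._accum(gx.astype(np.float32))

        out._backward = _back
        return out


class Dense(Module):
    def __init__(self, cin, cout, bias=True, rng=None, name=""):
        self.cin, self.cout = cin, cout
        self.name = name
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x.data @ self.weight.data
        if self.bias is not None:
            y = y + self.bias.data
        add_macs(self.cin * self.cout, kind="dense")
        out = Tensor(y)
        out._prev = (x, self.weight) + ((self.bias,) if self.bias is not None else ())

        def _back(g):
            self.weight._accum(x.data.T @ g)
            if self.bias is not None:
                self.bias._accum(g.sum(axis=0))
            x._accum(g @ self.weight.data.T)

        out._backward = _back
        return out


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Parameter], lr=1e-4, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
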