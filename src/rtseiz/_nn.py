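"""Minimal reverse-mode autodiff engine and neural-network layers on numpy.

Everything the detector/classifier architectures need and nothing more:
dense / 2-D convolution / depthwise convolution / squeeze-excitation /
LSTM cell, ReLU-family activations, channel normalization, Adam, and the
two losses (binary cross-entropy and softmax cross-entropy, both from
logits).  Arrays are float64 throughout; forward passes are deterministic
on a single thread, which the streaming-consistency and fixed-seed
training contracts rely on.

The engine is define-by-run: each op returns a :class:`Tensor` holding a
closure that propagates the upstream gradient to its parents; ``backward``
runs the closures in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Linear",
    "Conv2d",
    "DepthwiseConv2d",
    "ChannelNorm",
    "LSTMCell",
    "SqueezeExcite",
    "Adam",
    "concat",
    "relu",
    "hardswish",
    "sigmoid",
    "tanh",
    "softplus",
    "mean_pool",
    "mean_max_pool",
    "binary_cross_entropy_with_logits",
    "cross_entropy_with_logits",
    "numeric_gradient",
]


# ---------------------------------------------------------------------------
# Tensor and primitive ops
# ---------------------------------------------------------------------------

def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes numpy prepended
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other.pow(-1.0)

    def pow(self, p: float):
        def back(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(self.data ** p, (self,), back)

    def sqrt(self):
        return self.pow(0.5)

    def matmul(self, other: "Tensor"):
        other = Tensor._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), back)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), back)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), back)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return self._make(self.data[idx], (self,), back)

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def amax(self, axis: int):
        """Maximum along one axis; gradient routes to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                 axis).squeeze(axis)

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis),
                                  np.expand_dims(g, axis), axis)
                self._accum(full)

        return self._make(out, (self,), back)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), back)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def back(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), back)

    def tanh(self):
        t = np.tanh(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return self._make(t, (self,), back)

    def exp(self):
        e = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * e)

        return self._make(e, (self,), back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), back)

    def softplus(self):
        # stable: log(1+e^x) = max(x,0) + log1p(e^-|x|)
        out = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def back(g):
            if self.requires_grad:
                self._accum(g * s)

        return self._make(out, (self,), back)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along an axis; gradient splits back to the parents."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    out = np.concatenate(datas, axis=axis)
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, o, s in zip(tensors, offsets, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(o, o + s)
                t._accum(g[tuple(idx)])

    res = Tensor(out)
    if any(t.requires_grad for t in tensors):
        res.requires_grad = True
        res._parents = tuple(tensors)
        res._backward = back
    return res


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def tanh(x: Tensor) -> Tensor:
    return x.tanh()


def softplus(x: Tensor) -> Tensor:
    return x.softplus()


def hardswish(x: Tensor) -> Tensor:
    """x * clip(x+3, 0, 6)/6 — the MobileNetV3 activation, built from primitives."""
    data = x.data
    inner = np.clip(data + 3.0, 0.0, 6.0) / 6.0
    mask = ((data > -3.0) & (data < 3.0)).astype(np.float64) / 6.0

    def back(g):
        if x.requires_grad:
            x._accum(g * (inner + data * mask))

    return x._make(data * inner, (x,), back)


def mean_pool(x: Tensor, axes=(2, 3)) -> Tensor:
    """Global average pool over the given spatial axes."""
    return x.mean(axis=axes)


def mean_max_pool(x: Tensor) -> Tensor:
    """Concatenated global mean and max pooling of (N, C, 1, T) -> (N, 2C).

    Max pooling keeps short, localized events visible in the clip-level
    feature even when they occupy a small fraction of the clip.
    """
    n, c, h, t = x.shape
    flat = x.reshape(n, c, h * t)
    return concat([flat.mean(axis=2), flat.amax(axis=2)], axis=1)


# ---------------------------------------------------------------------------
# Convolution primitives
# ---------------------------------------------------------------------------

def _conv_geometry(H, W, KH, KW, stride, dilation, padding):
    sh, sw = stride
    dh, dw = dilation
    ph, pw = padding
    eh = (KH - 1) * dh + 1
    ew = (KW - 1) * dw + 1
    Ho = (H + 2 * ph - eh) // sh + 1
    Wo = (W + 2 * pw - ew) // sw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(
            f"convolution output empty: input {H}x{W}, kernel {KH}x{KW}, "
            f"stride {stride}, dilation {dilation}, padding {padding}"
        )
    return sh, sw, dh, dw, ph, pw, Ho, Wo


def _patches(xp: np.ndarray, KH, KW, sh, sw, dh, dw, Ho, Wo) -> np.ndarray:
    """Strided view (N, C, KH, KW, Ho, Wo) of the padded input."""
    N, C, H, W = xp.shape
    sN, sC, sH, sW = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, KH, KW, Ho, Wo),
        strides=(sN, sC, sH * dh, sW * dw, sH * sh, sW * sw),
        writeable=False,
    )


def _scatter_taps(dpatch: np.ndarray, xshape, KH, KW, sh, sw, dh, dw, ph, pw):
    """Inverse of _patches: accumulate (N,C,KH,KW,Ho,Wo) grads into (N,C,H,W)."""
    N, C, H, W = xshape
    Ho, Wo = dpatch.shape[4], dpatch.shape[5]
    dxp = np.zeros((N, C, H + 2 * ph, W + 2 * pw))
    for kh in range(KH):
        for kw in range(KW):
            dxp[:, :, kh * dh: kh * dh + sh * Ho: sh,
                kw * dw: kw * dw + sw * Wo: sw] += dpatch[:, :, kh, kw]
    if ph or pw:
        dxp = dxp[:, :, ph: ph + H, pw: pw + W]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=(1, 1),
           dilation=(1, 1), padding=(0, 0)) -> Tensor:
    """Cross-correlation of x:(N,C,H,W) with w:(F,C,KH,KW) -> (N,F,Ho,Wo)."""
    N, C, H, W = x.data.shape
    F, Cw, KH, KW = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    sh, sw, dh, dw, ph, pw, Ho, Wo = _conv_geometry(H, W, KH, KW, stride, dilation, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    pat = _patches(xp, KH, KW, sh, sw, dh, dw, Ho, Wo)
    col = np.ascontiguousarray(pat.transpose(0, 4, 5, 1, 2, 3)).reshape(N * Ho * Wo, C * KH * KW)
    wmat = w.data.reshape(F, C * KH * KW)
    out = (col @ wmat.T).reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, F, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def back(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, F)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if w.requires_grad:
            w._accum((g2.T @ col).reshape(F, C, KH, KW))
        if x.requires_grad:
            dcol = (g2 @ wmat).reshape(N, Ho, Wo, C, KH, KW)
            dpatch = dcol.transpose(0, 3, 4, 5, 1, 2)
            x._accum(_scatter_taps(dpatch, x.data.shape, KH, KW, sh, sw, dh, dw, ph, pw))

    return x._make(out, parents, back)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=(1, 1),
                     dilation=(1, 1), padding=(0, 0)) -> Tensor:
    """Per-channel convolution; w:(C,KH,KW), x:(N,C,H,W) -> (N,C,Ho,Wo)."""
    N, C, H, W = x.data.shape
    Cw, KH, KW = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    sh, sw, dh, dw, ph, pw, Ho, Wo = _conv_geometry(H, W, KH, KW, stride, dilation, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    pat = _patches(xp, KH, KW, sh, sw, dh, dw, Ho, Wo)
    out = np.einsum("nckuij,cku->ncij", pat, w.data, optimize=True)
    if b is not None:
        out = out + b.data.reshape(1, C, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def back(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.einsum("ncij,nckuij->cku", g, pat, optimize=True))
        if x.requires_grad:
            dpatch = g[:, :, None, None, :, :] * w.data[None, :, :, :, None, None]
            x._accum(_scatter_taps(dpatch, x.data.shape, KH, KW, sh, sw, dh, dw, ph, pw))

    return x._make(out, parents, back)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean BCE from logits: softplus(z) - y*z, numerically stable."""
    y = np.asarray(targets, dtype=np.float64)
    return (logits.softplus() - logits * Tensor(y)).mean()


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; logits (N,K), integer labels (N,)."""
    labels = np.asarray(labels)
    n, k = logits.data.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # detached
    z = logits - shift
    lse = z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    picked = (z * Tensor(onehot)).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Tiny module base: tracks parameter Tensors and sub-modules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_mods", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._mods[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._mods.values():
            out.extend(m.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=np.float64)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch {a.shape} vs {p.data.shape}")
            p.data = a.copy()


def _he(rng: np.random.Generator, shape, fan_in) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float = 1.0):
        super().__init__()
        self.w = _he(rng, (n_in, n_out), n_in)
        if scale != 1.0:  # small-scale init for output heads
            self.w.data *= scale
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, rng, stride=(1, 1), dilation=(1, 1),
                 padding=(0, 0), bias=True):
        super().__init__()
        kh, kw = kernel
        self.stride, self.dilation, self.padding = stride, dilation, padding
        self.w = _he(rng, (c_out, c_in, kh, kw), c_in * kh * kw)
        self.b = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.dilation, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, c, kernel, rng, stride=(1, 1), padding=(0, 0)):
        super().__init__()
        kh, kw = kernel
        self.stride, self.padding = stride, padding
        self.w = _he(rng, (c, kh, kw), kh * kw)
        self.b = Tensor(np.zeros(c), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.w, self.b, self.stride, (1, 1), self.padding)


class ChannelNorm(Module):
    """Per-sample, per-channel normalization over spatial axes (instance norm,
    no running stats) — stable under batch size 1, unlike batch norm."""

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones((1, c, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2] * x.shape[3] == 1:
            # single spatial point: centering would zero the signal entirely
            return x * self.gamma + self.beta
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc * (var + self.eps).pow(-0.5)
        return xhat * self.gamma + self.beta


class SqueezeExcite(Module):
    """Global-pool -> bottleneck MLP -> sigmoid channel gates."""

    def __init__(self, c: int, rng, reduction: int = 4):
        super().__init__()
        hidden = max(1, c // reduction)
        self.fc1 = Linear(c, hidden, rng)
        self.fc2 = Linear(hidden, c, rng)
        self.c = c

    def __call__(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3))            # (N, C)
        s = self.fc2(self.fc1(s).relu()).sigmoid()
        n = x.data.shape[0]
        return x * s.reshape(n, self.c, 1, 1)


class LSTMCell(Module):
    """Standard LSTM cell; gate order (input, forget, cell, output)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / np.sqrt(n_hidden)
        self.n_hidden = n_hidden
        self.w_ih = Tensor(rng.uniform(-k, k, (n_in, 4 * n_hidden)), requires_grad=True)
        self.w_hh = Tensor(rng.uniform(-k, k, (n_hidden, 4 * n_hidden)), requires_grad=True)
        # forget-gate bias +1: standard trick for gradient flow early in training
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.n_hidden
        gates = x @ self.w_ih + h @ self.w_hh + self.b
        i = gates.narrow(1, 0, H).sigmoid()
        f = gates.narrow(1, H, H).sigmoid()
        g = gates.narrow(1, 2 * H, H).tanh()
        o = gates.narrow(1, 3 * H, H).sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def zero_state(self, batch: int) -> tuple[Tensor, Tensor]:
        return (Tensor(np.zeros((batch, self.n_hidden))),
                Tensor(np.zeros((batch, self.n_hidden))))


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Testing aid
# ---------------------------------------------------------------------------

def numeric_gradient(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar fn(x) — used by the unit tests
    to validate every analytic backward pass."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn(x)
        flat[i] = orig - eps
        fm = fn(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
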