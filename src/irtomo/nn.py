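"""Minimal reverse-mode automatic differentiation and neural-net layers.

A small, self-contained NumPy engine: `Tensor` records a computation graph,
`backward()` runs reverse-mode accumulation in topological order.  Layers
cover exactly what the inverse-scattering model needs — 1D convolution,
max-pooling and nearest-neighbour unpooling, multi-head self-attention,
batch normalisation, 3D (transpose) convolution — plus an Adam optimizer.

Shapes follow the channels-first convention: 1D data is (B, C, L), 3D data
is (B, C, D, H, W).
"""

from __future__ import annotations

import numpy as np

# Default compute precision.  float32 keeps the memory-bound layers fast;
# tests that finite-difference the gradients switch to float64.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = dtype


# ---------------------------------------------------------------------------
# autograd core
# ---------------------------------------------------------------------------


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            node._parents = ()
            node._backward = None

    def _accum(self, g: np.ndarray) -> None:
        # Adopt the first gradient without copying; later fan-in contributions
        # allocate (never mutate in place) so adopted buffers stay safe to
        # share with already-processed nodes.
        if self.grad is None:
            self.grad = g if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, powt(other, -1.0))

    def __pow__(self, p):
        return powt(self, p)

    def item(self) -> float:
        return float(self.data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, req, tuple(p for p in parents if p.requires_grad),
                  backward if req else None)


# -- elementwise ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def back(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), back)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def back(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), back)


def powt(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** p

    def back(g):
        a._accum(_unbroadcast(g * p * a.data ** (p - 1.0), a.shape))

    return _make(out_data, (a,), back)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def back(g):
        a._accum(g * out_data)

    return _make(out_data, (a,), back)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def back(g):
        a._accum(g / a.data)

    return _make(np.log(a.data), (a,), back)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def back(g):
        a._accum(g * 0.5 / out_data)

    return _make(out_data, (a,), back)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def back(g):
        a._accum(g * mask)

    return _make(a.data * mask, (a,), back)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def back(g):
        a._accum(g * s * (1.0 - s))

    return _make(s, (a,), back)


def softplus(a) -> Tensor:
    """log(1 + e^x), numerically stabilised; positive output."""
    a = _as_tensor(a)
    out_data = np.logaddexp(0.0, a.data)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def back(g):
        a._accum(g * s)

    return _make(out_data, (a,), back)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    t = np.tanh(a.data)

    def back(g):
        a._accum(g * (1.0 - t * t))

    return _make(t, (a,), back)


# -- reductions / shaping ---------------------------------------------------

def sumt(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.shape).copy())

    return _make(out_data, (a,), back)


def meant(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sumt(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)

    def back(g):
        a._accum(g.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), back)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    inv = np.argsort(axes)

    def back(g):
        a._accum(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), back)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), back)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    a = _as_tensor(a)
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def back(g):
        gg = np.zeros(a.shape)
        gg[sl] = g
        a._accum(gg)

    return _make(a.data[sl], (a,), back)


def matmul(a, b) -> Tensor:
    """Batched matrix product via numpy's @ broadcasting."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def back(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _make(out_data, (a, b), back)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accum(s * (g - dot))

    return _make(s, (a,), back)


# -- convolutions -----------------------------------------------------------

def conv1d(x, w, b=None, pad: int = 0) -> Tensor:
    """1D convolution (cross-correlation), stride 1.

    x: (B, Ci, L), w: (Co, Ci, K), b: (Co,) -> (B, Co, L + 2 pad - K + 1).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    B, Ci, L = x.shape
    Co, _, K = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    Lo = xp.shape[2] - K + 1
    # im2col so the heavy lifting is one BLAS matmul
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # B,Ci,Lo,K
    cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B, Lo, Ci * K)
    wmat = w.data.reshape(Co, Ci * K)
    out_data = (cols @ wmat.T).transpose(0, 2, 1)  # B, Co, Lo
    if b is not None:
        out_data = out_data + b.data[None, :, None]

    def back(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 1))  # B, Lo, Co
        if w.requires_grad:
            gw = gt.reshape(-1, Co).T @ cols.reshape(-1, Ci * K)
            w._accum(gw.reshape(Co, Ci, K))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = (gt @ wmat).reshape(B, Lo, Ci, K).transpose(0, 2, 1, 3)
            gx = np.zeros_like(xp)
            for k in range(K):
                gx[:, :, k:k + Lo] += dcols[:, :, :, k]
            x._accum(gx[:, :, pad:pad + L] if pad else gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, back)


def maxpool1d(x, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; trailing remainder channels are dropped."""
    x = _as_tensor(x)
    B, C, L = x.shape
    Lo = L // size
    xv = x.data[:, :, :Lo * size].reshape(B, C, Lo, size)
    idx = xv.argmax(axis=3)
    out_data = np.take_along_axis(xv, idx[..., None], axis=3)[..., 0]

    def back(g):
        gx = np.zeros((B, C, Lo, size))
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=3)
        full = np.zeros(x.shape)
        full[:, :, :Lo * size] = gx.reshape(B, C, Lo * size)
        x._accum(full)

    return _make(out_data, (x,), back)


def upsample1d(x, factor: int = 2) -> Tensor:
    """Nearest-neighbour unpooling along the length axis."""
    x = _as_tensor(x)

    def back(g):
        B, C, Lf = g.shape
        x._accum(g.reshape(B, C, Lf // factor, factor).sum(axis=3))

    return _make(np.repeat(x.data, factor, axis=2), (x,), back)


def _conv3d_raw(xp: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Valid-mode 3D cross-correlation by kernel-offset accumulation;
    xp: (B, Ci, D, H, W) already padded, w: (Co, Ci, k, k, k)."""
    B, Ci, D, H, W = xp.shape
    Co, _, K, _, _ = w.shape
    Do = (D - K) // stride + 1
    Ho = (H - K) // stride + 1
    Wo = (W - K) // stride + 1
    out = np.zeros((B, Co, Do, Ho, Wo))
    for i in range(K):
        for j in range(K):
            for l in range(K):
                patch = xp[:, :,
                           i:i + stride * Do:stride,
                           j:j + stride * Ho:stride,
                           l:l + stride * Wo:stride]
                out += np.einsum("bcdhw,oc->bodhw", patch, w[:, :, i, j, l],
                                 optimize=True)
    return out


def conv3d(x, w, b=None, pad: int = 0, stride: int = 1) -> Tensor:
    """3D convolution; x: (B, Ci, D, H, W), w: (Co, Ci, K, K, K)."""
    x, w = _as_tensor(x), _as_tensor(w)
    K = w.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x.data
    out_data = _conv3d_raw(xp, w.data, stride)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]

    def back(g):
        B, Co, Do, Ho, Wo = g.shape
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(K):
                for j in range(K):
                    for l in range(K):
                        patch = xp[:, :,
                                   i:i + stride * Do:stride,
                                   j:j + stride * Ho:stride,
                                   l:l + stride * Wo:stride]
                        gw[:, :, i, j, l] = np.einsum(
                            "bodhw,bcdhw->oc", g, patch, optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gx = np.zeros_like(xp)
            for i in range(K):
                for j in range(K):
                    for l in range(K):
                        gx[:, :,
                           i:i + stride * Do:stride,
                           j:j + stride * Ho:stride,
                           l:l + stride * Wo:stride] += np.einsum(
                               "bodhw,oc->bcdhw", g, w.data[:, :, i, j, l],
                               optimize=True)
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad, pad:-pad]
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, back)


def zerostuff3d(x, stride: int) -> Tensor:
    """Insert stride-1 zeros between entries along the three spatial axes
    (the up-sampling half of a transpose convolution)."""
    x = _as_tensor(x)
    B, C, D, H, W = x.shape
    out_data = np.zeros((B, C, (D - 1) * stride + 1, (H - 1) * stride + 1,
                         (W - 1) * stride + 1))
    out_data[:, :, ::stride, ::stride, ::stride] = x.data

    def back(g):
        x._accum(g[:, :, ::stride, ::stride, ::stride])

    return _make(out_data, (x,), back)


def flip3(x) -> Tensor:
    """Flip the three trailing spatial axes (kernel flip for transpose conv)."""
    x = _as_tensor(x)

    def back(g):
        x._accum(g[..., ::-1, ::-1, ::-1])

    return _make(x.data[..., ::-1, ::-1, ::-1], (x,), back)


def conv_transpose3d(x, w, b=None, stride: int = 2, pad: int = 1) -> Tensor:
    """Transpose 3D convolution, the adjoint of conv3d(stride, pad).

    x: (B, Ci, D, H, W), w: (Ci, Co, K, K, K) ->
    (B, Co, (D-1) s - 2 pad + K, ...).  Implemented as zero-stuffing followed
    by a full convolution with the flipped kernel.
    """
    w = _as_tensor(w)
    xs = zerostuff3d(x, stride)
    wf = flip3(transpose(w, (1, 0, 2, 3, 4)))
    K = w.shape[2]
    return conv3d(xs, wf, b, pad=K - 1 - pad, stride=1)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Module:
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            if hasattr(m, "training"):
                m.training = flag

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()] + [
            arr.copy() for m in self.modules()
            for arr in getattr(m, "buffers", lambda: [])()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        bufs = [m for m in self.modules() if hasattr(m, "buffers")]
        n = len(params)
        for p, a in zip(params, arrays[:n]):
            p.data[...] = a
        i = n
        for m in bufs:
            for buf in m.buffers():
                buf[...] = arrays[i]
                i += 1


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _kaiming(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x):
        return add(matmul(x, self.w), self.b)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 pad: int | None = None):
        self.w = _kaiming(rng, (c_out, c_in, k), c_in * k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = k // 2 if pad is None else pad

    def __call__(self, x):
        return conv1d(x, self.w, self.b, pad=self.pad)


class ConvTranspose3d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 2, pad: int = 1):
        self.w = _kaiming(rng, (c_in, c_out, k, k, k), c_in * k**3)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv_transpose3d(x, self.w, self.b, self.stride, self.pad)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 1):
        self.w = _kaiming(rng, (c_out, c_in, k, k, k), c_in * k**3)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv3d(x, self.w, self.b, pad=self.pad, stride=self.stride)


def _batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple,
                     bshape: tuple, eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch-norm forward/backward (training mode); returns the output
    tensor plus the batch mean/var for the running-stat update."""
    n = 1
    for ax in axes:
        n *= x.shape[ax]
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gb = gamma.data.reshape(bshape)
    out_data = gb * xhat + beta.data.reshape(bshape)

    def back(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gb
            t1 = dxhat.sum(axis=axes, keepdims=True)
            t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            x._accum((inv / n) * (n * dxhat - t1 - xhat * t2))

    return _make(out_data, (x, gamma, beta), back), mu, var


class BatchNorm(Module):
    """Batch normalisation over all axes except the channel axis (axis 1)."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum, self.eps = momentum, eps
        self.training = True

    def buffers(self):
        return [self.running_mean, self.running_var]

    def __call__(self, x):
        nd = len(x.shape)
        axes = tuple(i for i in range(nd) if i != 1)
        bshape = tuple(x.shape[1] if i == 1 else 1 for i in range(nd))
        if self.training:
            out, mu, var = _batchnorm_train(x, self.gamma, self.beta, axes,
                                            bshape, self.eps)
            m = self.momentum
            self.running_mean *= (1 - m)
            self.running_mean += m * mu.reshape(-1)
            self.running_var *= (1 - m)
            self.running_var += m * var.reshape(-1)
            return out
        xhat = mul(x - self.running_mean.reshape(bshape),
                   (self.running_var.reshape(bshape) + self.eps) ** -0.5)
        return add(mul(xhat, reshape(self.gamma, bshape)),
                   reshape(self.beta, bshape))


class MultiheadSelfAttention1d(Module):
    """Multi-head self-attention over the length axis of (B, C, L) data."""

    def __init__(self, c_in: int, c_out: int, n_heads: int,
                 rng: np.random.Generator):
        if c_out % n_heads:
            raise ValueError("c_out must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = c_out // n_heads
        self.wq = _kaiming(rng, (c_in, c_out), c_in)
        self.wk = _kaiming(rng, (c_in, c_out), c_in)
        self.wv = _kaiming(rng, (c_in, c_out), c_in)
        self.wo = _kaiming(rng, (c_out, c_out), c_out)

    def __call__(self, x):
        B, C, L = x.shape
        h, d = self.n_heads, self.d_head
        xt = transpose(x, (0, 2, 1))                      # B, L, C
        def split(w):
            y = matmul(xt, w)                             # B, L, h*d
            y = reshape(y, (B, L, h, d))
            return transpose(y, (0, 2, 1, 3))             # B, h, L, d
        q, k, v = split(self.wq), split(self.wk), split(self.wv)
        att = softmax(mul(matmul(q, transpose(k, (0, 1, 3, 2))),
                          1.0 / np.sqrt(d)), axis=-1)
        out = matmul(att, v)                              # B, h, L, d
        out = reshape(transpose(out, (0, 2, 1, 3)), (B, L, h * d))
        out = matmul(out, self.wo)
        return transpose(out, (0, 2, 1))                  # B, h*d, L


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

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
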