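"""Minimal reverse-mode automatic differentiation on numpy float32 arrays.

Only the operations the segmentation network needs are implemented:
elementwise arithmetic, activations, reductions, 3D (dilated) convolution,
group normalization, 2x max pooling, 2x trilinear upsampling and channel
concatenation.  Every op is gradient-checked against central finite
differences in the test suite.

Convolutions use a tap-loop formulation: a 3x3x3 kernel with dilation ``d``
is 27 shifted GEMMs, and taps whose offset falls entirely outside the grid
are skipped.  This makes large dilation rates on small grids cheap (they
reduce to the centre tap) and avoids materializing padded arrays.

Batched 5D activations are stored **channel-major**, ``(C, B, Z, Y, X)``,
so each convolution tap is a single (O x C) @ (C x B*n) GEMM over all batch
members at once — the layout that keeps a 1-CPU BLAS busy.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

Array = np.ndarray


def _tune_allocator() -> None:
    """Keep large allocations on the heap instead of mmap/munmap cycles.

    Training allocates and frees many multi-MB activation buffers per
    iteration; with glibc's default mmap threshold every one triggers page
    faults on first touch.  Raising the threshold roughly halves the
    per-iteration cost on a single CPU.  Best effort: silently skipped on
    non-glibc platforms.
    """
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()


class Tensor:
    """Node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Tuple["Tensor", ...] = (),
        _bwd: Optional[Callable[[Array], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._bwd = _bwd

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad: Optional[Array] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep at high iteration counts
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __sub__(self, other):
        return add(self, mul_scalar(_as_tensor(other), -1.0))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return mul_scalar(self, float(other))
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _accumulate(t: Tensor, g: Array) -> None:
    """Add ``g`` into ``t.grad`` without taking ownership of ``g``."""
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float32, copy=True)
    else:
        t.grad += g


def _give(t: Tensor, g: Array) -> None:
    """Accumulate a freshly allocated float32 array (ownership transfer:
    the caller must not reuse ``g`` afterwards)."""
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g
    else:
        t.grad += g


# ---------------------------------------------------------------------------
# elementwise / reductions
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _parents=(a, b))

    def bwd(g):
        for t in (a, b):
            ub = _unbroadcast(g, t.data.shape)
            if ub is g:
                _accumulate(t, ub)
            else:
                _give(t, ub)

    out._bwd = bwd
    return out


def _unbroadcast(g: Array, shape) -> Array:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _parents=(a, b))

    def bwd(g):
        _give(a, _unbroadcast(g * b.data, a.data.shape))
        _give(b, _unbroadcast(g * a.data, b.data.shape))

    out._bwd = bwd
    return out


def mul_scalar(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, _parents=(a,))
    out._bwd = lambda g: _give(a, g * s)
    return out


def square(a: Tensor) -> Tensor:
    out = Tensor(a.data * a.data, _parents=(a,))
    out._bwd = lambda g: _give(a, 2.0 * g * a.data)
    return out


def tsum(a: Tensor) -> Tensor:
    out = Tensor(a.data.sum(), _parents=(a,))
    out._bwd = lambda g: _give(a, np.full(a.data.shape, g, dtype=np.float32))
    return out


def tmean(a: Tensor) -> Tensor:
    n = a.data.size
    out = Tensor(a.data.mean(), _parents=(a,))
    out._bwd = lambda g: _give(a, np.full(a.data.shape, g / n, dtype=np.float32))
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, _parents=(a,))
    out._bwd = lambda g: _give(a, g * mask)
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, _parents=(a,))
    out._bwd = lambda g: _give(a, g * (1.0 - y * y))
    return out


def sigmoid(a: Tensor) -> Tensor:
    # clamp the pre-activation: float32 exp overflows below ~-88, and
    # gradients are zero to machine precision beyond +-60 anyway
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
    out = Tensor(y, _parents=(a,))
    out._bwd = lambda g: _give(a, g * y * (1.0 - y))
    return out


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate channel-major (C, B, Z, Y, X) tensors along channels."""
    data = np.concatenate([t.data for t in tensors], axis=0)
    out = Tensor(data, _parents=tuple(tensors))
    sizes = [t.data.shape[0] for t in tensors]

    def bwd(g):
        start = 0
        for t, c in zip(tensors, sizes):
            _accumulate(t, g[start : start + c])
            start += c

    out._bwd = bwd
    return out


def mean_over_batch(a: Tensor) -> Tensor:
    """(C, B, Z, Y, X) -> (C, 1, Z, Y, X), averaging over the batch axis."""
    n = a.data.shape[1]
    out = Tensor(a.data.mean(axis=1, keepdims=True), _parents=(a,))
    out._bwd = lambda g: _accumulate(a, np.broadcast_to(g / n, a.data.shape))
    return out


# ---------------------------------------------------------------------------
# 3D convolution (3x3x3 kernel, arbitrary dilation, stride 1, same padding)
# ---------------------------------------------------------------------------

def _tap_regions(dim: int, off: int):
    """Output/input index ranges for a shifted tap; None when disjoint."""
    o0, o1 = max(0, -off), dim - max(0, off)
    if o1 <= o0:
        return None
    return o0, o1, o0 + off, o1 + off


def _conv3d_flat(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Dilation-1 convolution via flattened shifted views.

    The input is zero-padded by one voxel and flattened; every kernel tap
    then becomes a *contiguous* offset slice of the flat buffer, so the
    whole convolution is a single (O x 27C) @ (27C x L) GEMM with no
    per-tap gather copies.  Tap slices that wrap across batch/slab
    boundaries only pollute columns that lie in the padding margin, which
    is discarded when the interior is extracted.
    """
    C, B, D, H, W = x.data.shape
    O = w.data.shape[0]
    Dp, Hp, Wp = D + 2, H + 2, W + 2
    Np = Dp * Hp * Wp
    L = B * Np
    G = Hp * Wp + Wp + 1  # max |flat offset| of any tap
    buf = np.zeros((C, L + 2 * G), dtype=np.float32)
    buf[:, G : G + L].reshape(C, B, Dp, Hp, Wp)[:, :, 1:-1, 1:-1, 1:-1] = x.data
    offsets = [
        kz * Hp * Wp + ky * Wp + kx
        for kz in (-1, 0, 1)
        for ky in (-1, 0, 1)
        for kx in (-1, 0, 1)
    ]
    x_all = np.concatenate([buf[:, G + off : G + off + L] for off in offsets], axis=0)
    w2 = np.ascontiguousarray(
        w.data.reshape(O, C, 27).transpose(0, 2, 1).reshape(O, 27 * C)
    )  # tap-major rows to match x_all's (tap, channel) block order
    yp = np.matmul(w2, x_all)  # (O, L)
    y = np.ascontiguousarray(
        yp.reshape(O, B, Dp, Hp, Wp)[:, :, 1:-1, 1:-1, 1:-1]
    )
    y += b.data.reshape(O, 1, 1, 1, 1)
    training = x.requires_grad or w.requires_grad or b.requires_grad
    keep = x_all if training else None

    out = Tensor(y, _parents=(x, w, b))

    def bwd(g):
        if b.requires_grad:
            _give(b, g.sum(axis=(1, 2, 3, 4)))
        gp = np.zeros((O, L), dtype=np.float32)
        gp.reshape(O, B, Dp, Hp, Wp)[:, :, 1:-1, 1:-1, 1:-1] = g
        if w.requires_grad:
            gw2 = np.matmul(gp, keep.T)  # (O, 27C); pad columns of gp are zero
            _give(
                w,
                np.ascontiguousarray(
                    gw2.reshape(O, 27, C).transpose(0, 2, 1).reshape(O, C, 3, 3, 3)
                ),
            )
        if x.requires_grad:
            gx_all = np.matmul(w2.T, gp)  # (27C, L)
            gbuf = np.zeros((C, L + 2 * G), dtype=np.float32)
            for t, off in enumerate(offsets):
                gbuf[:, G + off : G + off + L] += gx_all[t * C : (t + 1) * C]
            _give(
                x,
                np.ascontiguousarray(
                    gbuf[:, G : G + L].reshape(C, B, Dp, Hp, Wp)[
                        :, :, 1:-1, 1:-1, 1:-1
                    ]
                ),
            )

    out._bwd = bwd
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """3D convolution of channel-major (C, B, Z, Y, X) with kernel
    (O, C, 3, 3, 3).

    Zero ("same") padding; out-of-range taps contribute nothing, which is
    equivalent to explicit zero padding but skips dead work when
    ``dilation`` is comparable to the grid size.
    """
    if dilation == 1:
        C = x.data.shape[0]
        O = w.data.shape[0]
        if w.data.shape != (O, C, 3, 3, 3):
            raise ValueError(
                f"kernel shape {w.data.shape} incompatible with input C={C}"
            )
        return _conv3d_flat(x, w, b)
    C, B, D, H, W = x.data.shape
    O = w.data.shape[0]
    if w.data.shape != (O, C, 3, 3, 3):
        raise ValueError(f"kernel shape {w.data.shape} incompatible with input C={C}")
    d = int(dilation)
    y = np.empty((O, B, D, H, W), dtype=np.float32)
    y[:] = b.data.reshape(O, 1, 1, 1, 1)
    training = x.requires_grad or w.requires_grad or b.requires_grad
    taps = []  # region bookkeeping (+ cached input copies when training)
    for kz in (-1, 0, 1):
        rz = _tap_regions(D, kz * d)
        if rz is None:
            continue
        for ky in (-1, 0, 1):
            ry = _tap_regions(H, ky * d)
            if ry is None:
                continue
            for kx in (-1, 0, 1):
                rx = _tap_regions(W, kx * d)
                if rx is None:
                    continue
                wt = w.data[:, :, kz + 1, ky + 1, kx + 1]  # (O, C)
                xs = x.data[:, :, rz[2] : rz[3], ry[2] : ry[3], rx[2] : rx[3]]
                sub = xs.reshape(C, -1)  # copies when the view is strided
                res = np.matmul(wt, sub)  # one (O, C) @ (C, B*n) GEMM
                y[:, :, rz[0] : rz[1], ry[0] : ry[1], rx[0] : rx[1]] += res.reshape(
                    O, B, rz[1] - rz[0], ry[1] - ry[0], rx[1] - rx[0]
                )
                taps.append((kz, ky, kx, rz, ry, rx, sub if training else None))

    out = Tensor(y, _parents=(x, w, b))

    def bwd(g):
        if b.requires_grad:
            _give(b, g.sum(axis=(1, 2, 3, 4)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for kz, ky, kx, rz, ry, rx, sub in taps:
            gs = g[:, :, rz[0] : rz[1], ry[0] : ry[1], rx[0] : rx[1]].reshape(O, -1)
            if gw is not None:
                gw[:, :, kz + 1, ky + 1, kx + 1] += np.matmul(gs, sub.T)
            if gx is not None:
                wt = w.data[:, :, kz + 1, ky + 1, kx + 1]
                gxs = np.matmul(wt.T, gs)  # (C, B*n)
                gx[:, :, rz[2] : rz[3], ry[2] : ry[3], rx[2] : rx[3]] += gxs.reshape(
                    C, B, rz[3] - rz[2], ry[3] - ry[2], rx[3] - rx[2]
                )
        if gx is not None:
            _give(x, gx)
        if gw is not None:
            _give(w, gw)

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# group normalization
# ---------------------------------------------------------------------------

def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization of channel-major (C, B, Z, Y, X); statistics are
    per (sample, group), scale/shift per channel."""
    C, B, D, H, W = x.data.shape
    if C % groups:
        raise ValueError(f"channels {C} not divisible by groups {groups}")
    cg = C // groups
    xg = x.data.reshape(groups, cg, B, -1)
    mu = xg.mean(axis=(1, 3), keepdims=True)  # (G, 1, B, 1)
    var = xg.var(axis=(1, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xg - mu) * inv
    xhat5 = xhat.reshape(C, B, D, H, W)
    y = gamma.data.reshape(C, 1, 1, 1, 1) * xhat5 + beta.data.reshape(C, 1, 1, 1, 1)
    out = Tensor(y, _parents=(x, gamma, beta))

    def bwd(g):
        if beta.requires_grad:
            _give(beta, g.sum(axis=(1, 2, 3, 4)))
        if gamma.requires_grad:
            _give(gamma, (g * xhat5).sum(axis=(1, 2, 3, 4)))
        if x.requires_grad:
            dxhat = (g * gamma.data.reshape(C, 1, 1, 1, 1)).reshape(groups, cg, B, -1)
            # standard normalization backward per (sample, group)
            t1 = dxhat.mean(axis=(1, 3), keepdims=True)
            t2 = (dxhat * xhat).mean(axis=(1, 3), keepdims=True)
            dx = inv * (dxhat - t1 - xhat * t2)
            _give(x, np.ascontiguousarray(dx.reshape(C, B, D, H, W)))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# 2x max pooling / 2x trilinear upsampling
# ---------------------------------------------------------------------------

def max_pool2(x: Tensor) -> Tensor:
    """2x max pooling of channel-major (C, B, Z, Y, X)."""
    C, B, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"spatial dims must be even for 2x pooling, got {(D, H, W)}")
    D2, H2, W2 = D // 2, H // 2, W // 2
    r = (
        x.data.reshape(C, B, D2, 2, H2, 2, W2, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(C, B, D2, H2, W2, 8)
    )
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, _parents=(x,))

    def bwd(g):
        g8 = np.zeros((C, B, D2, H2, W2, 8), dtype=np.float32)
        np.put_along_axis(g8, idx[..., None], g[..., None], axis=-1)
        gx = (
            g8.reshape(C, B, D2, H2, W2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(C, B, D, H, W)
        )
        _give(x, np.ascontiguousarray(gx))

    out._bwd = bwd
    return out


def _upsample_axis(a: Array, ax: int) -> Array:
    """Double one spatial axis by linear interpolation (align_corners=False)."""
    a = np.moveaxis(a, ax, -1)
    left = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)  # clamped i-1
    right = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)  # clamped i+1
    even = 0.75 * a + 0.25 * left
    odd = 0.75 * a + 0.25 * right
    out = np.stack([even, odd], axis=-1).reshape(a.shape[:-1] + (2 * a.shape[-1],))
    return np.moveaxis(out, -1, ax)


def _upsample_axis_T(g: Array, ax: int) -> Array:
    """Adjoint of :func:`_upsample_axis`."""
    g = np.moveaxis(g, ax, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    dx = 0.75 * (ge + go)
    dx[..., :-1] += 0.25 * ge[..., 1:]
    dx[..., 0] += 0.25 * ge[..., 0]
    dx[..., 1:] += 0.25 * go[..., :-1]
    dx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(dx, -1, ax)


def upsample2(x: Tensor) -> Tensor:
    """Trilinear 2x upsampling of channel-major (C, B, Z, Y, X)."""
    y = x.data
    for ax in (2, 3, 4):
        y = _upsample_axis(y, ax)
    out = Tensor(y, _parents=(x,))

    def bwd(g):
        for ax in (4, 3, 2):
            g = _upsample_axis_T(g, ax)
        _give(x, np.ascontiguousarray(g, dtype=np.float32))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

def clip_grad_norm(grads: dict, max_norm: float) -> float:
    """Scale all gradients in place so their global L2 norm is at most
    ``max_norm``; returns the pre-clip norm.  Standard stabilizer for
    batch-1 optimization where occasional loss spikes occur."""
    total = 0.0
    for g in grads.values():
        if g is not None:
            total += float((g.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / norm
        for g in grads.values():
            if g is not None:
                g *= scale
    return norm


class Adam:
    """Adam over a named dict of numpy parameter arrays (updated in place)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            self.params[k] -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
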