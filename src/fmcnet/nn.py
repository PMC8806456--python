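"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the feature-multi-connection (FMC)
architecture family needs: 2-D convolution (im2col), ReLU, max pooling,
cross-channel local response normalization, channel concatenation, global
Lp ("generalized mean") pooling, dense layers and a binary logistic head.
Tensors are channels-last: images and feature maps are ``(N, H, W, C)``.

Gradients are accumulated by topological traversal of the operation graph;
every op's backward pass is closed-form and checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), name: str | None = None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = tuple(parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed gradient: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward):
    out = Tensor(data, parents=parents if _needs_graph(*parents) else ())
    if out._parents:
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution

def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    n, h, w, c = xp.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sn, sh, sw, sc = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, ho, wo, kh, kw, c),
        strides=(sn, sh * stride, sw * stride, sh, sw, sc),
        writeable=False,
    )
    return np.ascontiguousarray(windows).reshape(n * ho * wo, kh * kw * c), ho, wo


def _col2im(gcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int):
    n, h, w, c = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    g = gcols.reshape(n, ho, wo, kh, kw, c)
    gx = np.zeros((n, hp, wp, c), dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gx[:, i:i + ho * stride:stride, j:j + wo * stride:stride, :] += g[:, :, :, i, j, :]
    if pad:
        gx = gx[:, pad:-pad, pad:-pad, :]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (N,H,W,Cin); w: (kh,kw,Cin,Cout); b: (Cout,) -> (N,Ho,Wo,Cout)."""
    kh, kw, cin, cout = w.data.shape
    if x.data.shape[3] != cin:
        raise ValueError(f"conv input has {x.data.shape[3]} channels, kernel expects {cin}")
    xp = _pad_hw(x.data, pad)
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(-1, cout)
    out = (cols @ wmat + b.data).reshape(x.data.shape[0], ho, wo, cout)

    def backward(gout):
        gflat = gout.reshape(-1, cout)
        if w.requires_grad or w._parents:
            w._accumulate((cols.T @ gflat).reshape(w.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(gflat.sum(axis=0))
        if x.requires_grad or x._parents:
            gcols = gflat @ wmat.T
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, pad))

    return _make(out, (x, w, b), backward)


# ---------------------------------------------------------------------------
# pointwise / pooling

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(gout):
        x._accumulate(gout * mask)

    return _make(out, (x,), backward)


def maxpool2d(x: Tensor, k: int, stride: int) -> Tensor:
    n, h, w, c = x.data.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sn, sh, sw, sc = x.data.strides
    windows = np.lib.stride_tricks.as_strided(
        x.data,
        shape=(n, ho, wo, k, k, c),
        strides=(sn, sh * stride, sw * stride, sh, sw, sc),
        writeable=False,
    )
    flat = windows.reshape(n, ho, wo, k * k, c)
    arg = flat.argmax(axis=3)          # (n,ho,wo,c)
    out = np.take_along_axis(flat, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(gout):
        gx = np.zeros_like(x.data)
        for t in range(k * k):
            mask = arg == t
            if not mask.any():
                continue
            i, j = divmod(t, k)
            gx[:, i:i + ho * stride:stride, j:j + wo * stride:stride, :] += gout * mask
        x._accumulate(gx)

    return _make(out, (x,), backward)


def _window_sum(x: np.ndarray, radius: int) -> np.ndarray:
    """Sliding-window sum over the last (channel) axis, window [i-r, i+r] clipped."""
    n = x.shape[-1]
    cs = np.cumsum(x, axis=-1)
    idx_hi = np.minimum(np.arange(n) + radius, n - 1)
    idx_lo = np.arange(n) - radius - 1
    hi = cs[..., idx_hi]
    lo = np.where(idx_lo >= 0, cs[..., np.maximum(idx_lo, 0)], 0.0)
    return hi - lo


def lrn(x: Tensor, k: float = 2.0, n: int = 5, alpha: float = 0.0004, beta: float = 0.75) -> Tensor:
    """Local response normalization across channels (last axis).

    b_i = a_i / (k + alpha * sum_{j=max(0,i-n/2)}^{min(N-1,i+n/2)} a_j^2)^beta
    """
    if not np.all(np.isfinite(x.data)):
        raise FloatingPointError("non-finite input to LRN")
    r = n // 2
    s = _window_sum(x.data ** 2, r)
    d = k + alpha * s
    dmb = d ** (-beta)
    out = x.data * dmb

    def backward(gout):
        c = gout * x.data * d ** (-beta - 1.0)
        gx = gout * dmb - 2.0 * alpha * beta * x.data * _window_sum(c, r)
        x._accumulate(gx)

    return _make(out, (x,), backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    """Concatenate feature maps along the channel (last) axis."""
    shapes = [t.data.shape[:-1] for t in tensors]
    if len(set(shapes)) > 1:
        raise ValueError(f"spatial dimension mismatch among concat inputs: {shapes}")
    out = np.concatenate([t.data for t in tensors], axis=-1)
    sizes = [t.data.shape[-1] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def backward(gout):
        for t, lo, hi in zip(tensors, bounds[:-1], bounds[1:]):
            if t.requires_grad or t._parents:
                t._accumulate(gout[..., lo:hi])

    return _make(out, tuple(tensors), backward)


def lp_pool(x: Tensor, p: float) -> Tensor:
    """Global Lp pooling: (N,H,W,C) -> (N,C), out_c = (sum_xy |x|^p)^(1/p).

    The absolute value keeps the root real for odd p; for p=2 this is the
    spatial L2 norm per channel.
    """
    if p < 1:
        raise ValueError(f"Lp pooling requires p >= 1, got {p}")
    a = np.abs(x.data)
    t = a ** p
    s = t.sum(axis=(1, 2))
    out = s ** (1.0 / p)

    def backward(gout):
        # d out_c / d x = s^(1/p - 1) * |x|^(p-1) * sign(x); zero where s == 0
        safe = np.where(s > 0, s, 1.0)
        coef = (gout * safe ** (1.0 / p - 1.0)) * (s > 0)
        gx = coef[:, None, None, :] * a ** (p - 1.0) * np.sign(x.data)
        x._accumulate(gx)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# dense / head

def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    shape = x.data.shape
    out = x.data.reshape(n, -1)

    def backward(gout):
        x._accumulate(gout.reshape(shape))

    return _make(out, (x,), backward)


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    out = x.data @ w.data + b.data

    def backward(gout):
        if w.requires_grad or w._parents:
            w._accumulate(x.data.T @ gout)
        if b.requires_grad or b._parents:
            b._accumulate(gout.sum(axis=0))
        if x.requires_grad or x._parents:
            x._accumulate(gout @ w.data.T)

    return _make(out, (x, w, b), backward)


def pair_sigmoid(z: Tensor) -> Tensor:
    """Positive-class probability from a 2-logit output.

    For two classes softmax reduces to sigma(z1 - z0); numerically stable.
    """
    diff = z.data[:, 1] - z.data[:, 0]
    q = 0.5 * (1.0 + np.tanh(0.5 * diff))

    def backward(gout):
        g = gout * q * (1.0 - q)
        gz = np.stack([-g, g], axis=1)
        z._accumulate(gz)

    return _make(q, (z,), backward)


def bce_loss(p: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy; probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(labels, dtype=p.data.dtype)
    pc = np.clip(p.data, eps, 1.0 - eps)
    n = pc.shape[0]
    loss = -(y * np.log(pc) + (1.0 - y) * np.log1p(-pc)).mean()

    def backward(gout):
        inside = (p.data > eps) & (p.data < 1.0 - eps)
        g = gout * (pc - y) / (pc * (1.0 - pc) * n) * inside
        p._accumulate(g.astype(p.data.dtype))

    return _make(np.asarray(loss), (p,), backward)


def pair_logit_bce(z: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Fused two-logit sigmoid + binary cross-entropy.

    The loss value matches bce_loss(pair_sigmoid(z), y, eps) (probabilities
    clipped before the log), but the gradient is taken through the sigmoid
    analytically, dL/d(z1-z0) = (sigma - y)/n, so saturated predictions
    still receive a restoring gradient instead of a clipped zero.
    """
    y = np.asarray(labels, dtype=z.data.dtype)
    diff = z.data[:, 1] - z.data[:, 0]
    q = 0.5 * (1.0 + np.tanh(0.5 * diff))
    qc = np.clip(q, eps, 1.0 - eps)
    n = qc.shape[0]
    loss = -(y * np.log(qc) + (1.0 - y) * np.log1p(-qc)).mean()

    def backward(gout):
        g = gout * (q - y) / n
        z._accumulate(np.stack([-g, g], axis=1).astype(z.data.dtype))

    return _make(np.asarray(loss), (z,), backward)


# ---------------------------------------------------------------------------
# parameter initialization

def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=DEFAULT_DTYPE) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)
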