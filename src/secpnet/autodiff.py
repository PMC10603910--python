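"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the operations the segmentation networks in
:mod:`secpnet.nets` need: 2D convolution (stride 1, same padding), 2x max
pooling, 2x bilinear upsampling, batch normalisation, channel-wise
concatenation and gating, global average pooling, dense layers, the usual
pointwise nonlinearities, and a fused cross-entropy head.  Gradients are
accumulated on a tape and released by :meth:`Tensor.backward`; every
backward rule is covered by central-difference checks in the test suite.

All arithmetic is float64.  Forward passes are deterministic functions of
the input and parameters (no dropout, no stochastic layers), which the
networks rely on for reproducibility guarantees.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "relu",
    "sigmoid",
    "conv2d",
    "maxpool2x",
    "upsample_bilinear2x",
    "concat_channels",
    "scale_channels",
    "global_avg_pool",
    "linear",
    "batchnorm2d",
    "softmax_channels",
    "cross_entropy_from_probs",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Back-propagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError(
                    "backward() without an explicit gradient requires a "
                    f"scalar tensor, got shape {self.data.shape}"
                )
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A learnable tensor; optimizers collect these from modules."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _needs_grad(*tensors):
    return any(t.requires_grad for t in tensors)


def _make(data, parents, backward):
    out = Tensor(data)
    if _needs_grad(*parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# pointwise / elementary ops
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add requires equal shapes, got {a.shape} and {b.shape}")

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _make(a.data + b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-sided form
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    out[~pos] = e / (1.0 + e)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out * (1.0 - out))

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# convolution (stride 1, same padding)
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 convolution; w has shape (Cout, Cin, kh, kw)."""
    C = x.shape[1]
    Cout, Cin, kh, kw = w.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Cin}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d supports odd kernel sizes only")
    y = _kernels.conv2d_forward(x.data, w.data)
    if b is not None:
        y += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g = np.ascontiguousarray(g)
        if w.requires_grad:
            w._accumulate(_kernels.conv2d_backward_dw(g, x.data, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(_kernels.conv2d_backward_dx(g, w.data))

    return _make(y, parents, backward)


# ---------------------------------------------------------------------------
# spatial resampling
# ---------------------------------------------------------------------------


def maxpool2x(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x requires even spatial size, got {(H, W)}")
    r = (
        x.data.reshape(B, C, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, H // 2, W // 2, 4)
    )
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        go = np.zeros_like(r)
        np.put_along_axis(go, idx[..., None], g[..., None], axis=-1)
        gx = (
            go.reshape(B, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H, W)
        )
        x._accumulate(gx)

    return _make(y, (x,), backward)


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D interpolation matrix, half-pixel-centre convention."""
    A = np.zeros((n_out, n_in))
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        t = src - i0
        A[i, i0] += 1.0 - t
        A[i, i1] += t
    return A


_BILINEAR_CACHE: dict[int, np.ndarray] = {}


def _bilinear2x(n: int) -> np.ndarray:
    if n not in _BILINEAR_CACHE:
        _BILINEAR_CACHE[n] = _bilinear_matrix(2 * n, n)
    return _BILINEAR_CACHE[n]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear 2x upsampling (used instead of transposed convolution to
    avoid checkerboard artifacts); exact linear map, so its adjoint is the
    transpose."""
    B, C, H, W = x.shape
    Ah, Aw = _bilinear2x(H), _bilinear2x(W)
    flat = x.data.reshape(B * C, H, W)
    y = (Ah @ flat @ Aw.T).reshape(B, C, 2 * H, 2 * W)

    def backward(g):
        if x.requires_grad:
            gflat = g.reshape(B * C, 2 * H, 2 * W)
            x._accumulate((Ah.T @ gflat @ Aw).reshape(B, C, H, W))

    return _make(y, (x,), backward)


# ---------------------------------------------------------------------------
# channel ops
# ---------------------------------------------------------------------------


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    if a.shape[0] != b.shape[0] or a.shape[2:] != b.shape[2:]:
        raise ValueError(
            f"concat_channels requires matching batch/spatial dims, got "
            f"{a.shape} and {b.shape}"
        )
    Ca = a.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :Ca])
        if b.requires_grad:
            b._accumulate(g[:, Ca:])

    return _make(np.concatenate([a.data, b.data], axis=1), (a, b), backward)


def scale_channels(x: Tensor, g: Tensor) -> Tensor:
    """Multiply x (B,C,H,W) by per-(batch,channel) gates g (B,C)."""
    if g.shape != x.shape[:2]:
        raise ValueError(f"gate shape {g.shape} does not match channels {x.shape[:2]}")
    gate = g.data[:, :, None, None]

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * gate)
        if g.requires_grad:
            g._accumulate((grad * x.data).sum(axis=(2, 3)))

    return _make(x.data * gate, (x, g), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean per channel: (B,C,H,W) -> (B,C)."""
    B, C, H, W = x.shape
    y = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x._accumulate(
                np.broadcast_to(g[:, :, None, None] / (H * W), x.shape).copy()
            )

    return _make(y, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Dense layer on (B, F) input; w has shape (Fout, Fin)."""
    y = x.data @ w.data.T
    if b is not None:
        y = y + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data)
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))

    return _make(y, parents, backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation. In training mode the batch statistics
    are used and the running statistics are updated in place; in eval mode the
    running statistics are used (no update)."""
    B, C, H, W = x.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased estimate for the running buffer, biased for the batch itself
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) / std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] / std[None, :, None, None]
            if training:
                m = B * H * W
                gmean = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gdot = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                x._accumulate(gs * (g - gmean - xhat * gdot))
                del m
            else:
                x._accumulate(gs * g)

    return _make(y, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------------


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the channel axis of a (B,C,H,W) tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=1, keepdims=True)
            x._accumulate(s * (g - dot))

    return _make(s, (x,), backward)


def cross_entropy_from_probs(
    probs: Tensor, target: np.ndarray, eps: float = 1e-12, base: float = 2.0
) -> Tensor:
    """Mean over pixels of -log_base(q_true + eps).

    ``target`` is an integer (B,H,W) label map; gradients flow into ``probs``.
    """
    B, C, H, W = probs.shape
    target = np.asarray(target)
    if target.shape != (B, H, W):
        raise ValueError(f"target shape {target.shape} != {(B, H, W)}")
    if target.min() < 0 or target.max() >= C:
        bad = target.min() if target.min() < 0 else target.max()
        raise ValueError(f"target label {bad} outside [0, {C})")
    idx = target[:, None, :, :]
    q = np.take_along_axis(probs.data, idx, axis=1)[:, 0]  # (B,H,W)
    ln_base = np.log(base)
    loss = -np.log(q + eps).mean() / ln_base

    def backward(g):
        if probs.requires_grad:
            gq = -g / ((q + eps) * ln_base * q.size)  # (B,H,W)
            gp = np.zeros_like(probs.data)
            np.put_along_axis(gp, idx, gq[:, None], axis=1)
            probs._accumulate(gp)

    return _make(loss, (probs,), backward)
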