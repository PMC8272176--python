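"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the segmentation network: a tape-based
:class:`Tensor` with exactly the operator set an encoder–decoder segmentation
model needs (2D convolution, transposed convolution, max-pooling, nearest
up-sampling, fully connected layers, channel/spatial rescaling, ReLU, sigmoid,
channel concatenation and binary cross-entropy).

Convolutions are evaluated as a single GEMM per layer via im2col, which keeps
CPU training of the scaled-down models practical. Arrays keep the dtype they
are given; parameter initialisers produce float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "conv2d",
    "conv_transpose2d",
    "linear",
    "relu",
    "sigmoid",
    "maxpool2x2",
    "upsample_nearest2x",
    "global_mean_pool",
    "channel_scale",
    "spatial_scale",
    "add",
    "concat_channels",
    "bce",
    "he_normal",
]


class Tensor:
    """A node in the computation tape.

    Holds a numpy array, an accumulated gradient of the same shape, and a
    closure that routes the gradient to its parents.
    """

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) node through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def Parameter(data):
    """A leaf tensor whose gradient is wanted."""
    t = Tensor(np.asarray(data))
    t.requires_grad = True
    return t


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def he_normal(rng, shape, fan_in, dtype=np.float32):
    """He/Kaiming-normal initialisation, suited to ReLU stacks."""
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


# ---------------------------------------------------------------------------
# convolution machinery


def _im2col(xp, k, H, W):
    """View of all k x k patches of the padded input, flattened for GEMM.

    Returns an array of shape (N*H*W, C*k*k); the copy happens in reshape.
    """
    N, C, Hp, Wp = xp.shape
    s0, s1, s2, s3 = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, k, k, H, W),
        strides=(s0, s1, s2, s3, s2, s3),
        writeable=False,
    )
    return patches.transpose(0, 4, 5, 1, 2, 3).reshape(N * H * W, C * k * k)


def _col2im(dcols, N, C, k, H, W, pad):
    """Scatter-add column gradients back onto the (padded) input grid."""
    dcols = dcols.reshape(N, H, W, C, k, k).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + H, j : j + W] += dcols[:, :, i, j]
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int | None = None):
    """'same' 2D cross-correlation; w has shape (Cout, Cin, k, k)."""
    Cout, Cin, k, k2 = w.data.shape
    if k != k2 or k % 2 == 0:
        raise ValueError(f"square odd kernels only, got {w.data.shape}")
    N, C, H, W = x.data.shape
    if C != Cin:
        raise ValueError(f"input has {C} channels, kernel expects {Cin}")
    pad = k // 2 if padding is None else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, k, H, W)
    out = cols @ w.data.reshape(Cout, -1).T
    if b is not None:
        out = out + b.data
    out = out.reshape(N, H, W, Cout).transpose(0, 3, 1, 2)
    parents = (x, w) + ((b,) if b is not None else ())

    def backward(go):
        g = np.ascontiguousarray(go.transpose(0, 2, 3, 1)).reshape(N * H * W, Cout)
        if w.requires_grad:
            w.accumulate((g.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=0))
        if x.requires_grad:
            dcols = g @ w.data.reshape(Cout, -1)
            x.accumulate(_col2im(dcols, N, Cin, k, H, W, pad))

    return Tensor(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2):
    """Stride-s transposed convolution with an s x s kernel (no overlap).

    w has shape (Cin, Cout, s, s); output spatial size is exactly s*H x s*W.
    """
    Cin, Cout, k, k2 = w.data.shape
    if k != stride or k2 != stride:
        raise ValueError("kernel size must equal stride for this operator")
    N, C, H, W = x.data.shape
    if C != Cin:
        raise ValueError(f"input has {C} channels, kernel expects {Cin}")
    out = np.empty((N, Cout, H * stride, W * stride), dtype=x.data.dtype)
    for i in range(stride):
        for j in range(stride):
            # each input pixel contributes w[:, :, i, j] to output (2r+i, 2c+j)
            o = np.tensordot(x.data, w.data[:, :, i, j], axes=([1], [0]))
            out[:, :, i::stride, j::stride] = o.transpose(0, 3, 1, 2)
    if b is not None:
        out += b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())

    def backward(go):
        if b is not None and b.requires_grad:
            b.accumulate(go.sum(axis=(0, 2, 3)))
        dx = np.zeros_like(x.data) if x.requires_grad else None
        for i in range(stride):
            for j in range(stride):
                g = go[:, :, i::stride, j::stride]
                if w.requires_grad:
                    w.grad = w.grad if w.grad is not None else np.zeros_like(w.data)
                    w.grad[:, :, i, j] += np.tensordot(
                        x.data, g, axes=([0, 2, 3], [0, 2, 3])
                    )
                if dx is not None:
                    dx += np.tensordot(
                        g, w.data[:, :, i, j], axes=([1], [1])
                    ).transpose(0, 3, 1, 2)
        if dx is not None:
            x.accumulate(dx)

    return Tensor(out, parents, backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None):
    """x: (N, Cin), w: (Cout, Cin), b: (Cout,)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data
    parents = (x, w) + ((b,) if b is not None else ())

    def backward(go):
        if w.requires_grad:
            w.accumulate(go.T @ x.data)
        if b is not None and b.requires_grad:
            b.accumulate(go.sum(axis=0))
        if x.requires_grad:
            x.accumulate(go @ w.data)

    return Tensor(out, parents, backward)


# ---------------------------------------------------------------------------
# pointwise / structural ops


def relu(x: Tensor):
    mask = x.data > 0
    out = x.data * mask

    def backward(go):
        if x.requires_grad:
            x.accumulate(go * mask)

    return Tensor(out, (x,), backward)


def sigmoid(x: Tensor):
    out = 1.0 / (1.0 + np.exp(-x.data))

    def backward(go):
        if x.requires_grad:
            x.accumulate(go * out * (1.0 - out))

    return Tensor(out, (x,), backward)


def add(a: Tensor, b: Tensor):
    out = a.data + b.data

    def backward(go):
        if a.requires_grad:
            a.accumulate(go)
        if b.requires_grad:
            b.accumulate(go)

    return Tensor(out, (a, b), backward)


def maxpool2x2(x: Tensor):
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"spatial size {H}x{W} not divisible by 2")
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(N, C, H // 2, W // 2, 4)
    idx = r.argmax(axis=-1)  # first max wins on ties: deterministic
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(go):
        if not x.requires_grad:
            return
        g = np.zeros((N, C, H // 2, W // 2, 4), dtype=go.dtype)
        np.put_along_axis(g, idx[..., None], go[..., None], axis=-1)
        g = g.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate(g.reshape(N, C, H, W))

    return Tensor(out, (x,), backward)


def upsample_nearest2x(x: Tensor):
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(go):
        if x.requires_grad:
            N, C, H2, W2 = go.shape
            g = go.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            x.accumulate(g)

    return Tensor(out, (x,), backward)


def global_mean_pool(x: Tensor):
    """(N, C, H, W) -> per-channel spatial mean (N, C): the SE squeeze."""
    N, C, H, W = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(go):
        if x.requires_grad:
            x.accumulate(
                np.broadcast_to(go[:, :, None, None] / (H * W), x.data.shape).copy()
            )

    return Tensor(out, (x,), backward)


def channel_scale(x: Tensor, s: Tensor):
    """Multiply channel n of x (N,C,H,W) by scalar s[:, n] (N,C)."""
    out = x.data * s.data[:, :, None, None]

    def backward(go):
        if x.requires_grad:
            x.accumulate(go * s.data[:, :, None, None])
        if s.requires_grad:
            s.accumulate((go * x.data).sum(axis=(2, 3)))

    return Tensor(out, (x, s), backward)


def spatial_scale(x: Tensor, a: Tensor):
    """Multiply x (N,C,H,W) by a per-pixel map a (N,1,H,W): attention gating."""
    out = x.data * a.data

    def backward(go):
        if x.requires_grad:
            x.accumulate(go * a.data)
        if a.requires_grad:
            a.accumulate((go * x.data).sum(axis=1, keepdims=True))

    return Tensor(out, (x, a), backward)


def concat_channels(a: Tensor, b: Tensor):
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(go):
        if a.requires_grad:
            a.accumulate(go[:, :ca])
        if b.requires_grad:
            b.accumulate(go[:, ca:])

    return Tensor(out, (a, b), backward)


def bce(pred: Tensor, target: np.ndarray, eps: float = 1e-7):
    """Mean binary cross-entropy with probability clipping at ``eps``."""
    y = np.asarray(target, dtype=pred.data.dtype)
    if y.shape != pred.data.shape:
        raise ValueError(f"shape mismatch: pred {pred.data.shape} vs target {y.shape}")
    p = np.clip(pred.data, eps, 1.0 - eps)
    n = p.size
    loss = -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean()

    def backward(go):
        if pred.requires_grad:
            inside = (pred.data > eps) & (pred.data < 1.0 - eps)
            g = np.where(inside, (p - y) / (p * (1.0 - p)), 0.0) / n
            pred.accumulate(go * g.astype(pred.data.dtype))

    return Tensor(np.asarray(loss), (pred,), backward)
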