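"""Core computational operators: squeeze-and-excitation and attention gating.

Two surfaces are provided for each operator:

* **functional** — pure numpy forward passes on single feature maps
  (``(C, H, W)`` arrays) with explicit parameter containers. These are the
  reference semantics of the operators and are directly checkable against
  scalar-loop oracles.
* **layers** — trainable modules built on :mod:`casenet.nn` tensors, used by
  the full network. Their forward passes agree with the functional surface.

A *feature map* here is a ``(C, H, W)`` array: C channels, each an ``H x W``
plane. The SE block squeezes each plane to its spatial mean, passes the
length-C vector through a bottlenecked two-layer gate (C -> C/g -> C, ReLU
then sigmoid) and rescales each plane by its gate value. The attention gate
computes a per-pixel coefficient in (0, 1) from the skip features and a
same-resolution gating signal and multiplies it onto the skip features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "ExcitationParams",
    "AttentionGateParams",
    "validate_feature_map",
    "squeeze",
    "excite",
    "scale",
    "se_block",
    "attention_gate",
    "conv_block",
    "transposed_conv_up",
    "SEBlock",
    "AttentionGate",
    "ConvBlock",
    "UpConv",
    "Conv1x1Head",
]


def validate_feature_map(fm: np.ndarray, name: str = "feature map") -> np.ndarray:
    fm = np.asarray(fm)
    if fm.ndim != 3:
        raise ValueError(f"{name} must be (C, H, W), got shape {fm.shape}")
    if min(fm.shape) < 1:
        raise ValueError(f"{name} has an empty axis: {fm.shape}")
    if not np.all(np.isfinite(fm)):
        raise ValueError(f"{name} contains non-finite values")
    return fm


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ExcitationParams:
    """Weights of the SE gating network: C -> C/g -> C with biases.

    ``w1`` maps the squeezed channel descriptor down to the bottleneck
    (shape (C/g, C)), ``w2`` maps it back up (shape (C, C/g)). The reduction
    ``g`` (the "complexity value", 8 by convention) must divide C.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        if self.w1.ndim != 2 or self.w2.ndim != 2:
            raise ValueError("w1 and w2 must be 2D matrices")
        if self.w1.shape[0] != self.w2.shape[1] or self.w1.shape[1] != self.w2.shape[0]:
            raise ValueError(
                f"inconsistent bottleneck: w1 {self.w1.shape}, w2 {self.w2.shape}"
            )
        if self.b1.shape != (self.w1.shape[0],) or self.b2.shape != (self.w2.shape[0],):
            raise ValueError("bias shapes do not match the weight matrices")

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def init(cls, channels: int, reduction: int = 8, rng=None, bias: bool = True):
        """He-initialised parameters; ``reduction`` must divide ``channels``."""
        if channels % reduction:
            raise ValueError(
                f"channel count {channels} not divisible by reduction g={reduction}"
            )
        rng = np.random.default_rng(rng)
        hidden = channels // reduction
        return cls(
            w1=nn.he_normal(rng, (hidden, channels), channels),
            b1=np.zeros(hidden, dtype=np.float32),
            w2=nn.he_normal(rng, (channels, hidden), hidden),
            b2=np.zeros(channels, dtype=np.float32),
        )


@dataclass
class AttentionGateParams:
    """1x1-convolution weights of an additive attention gate.

    ``wx`` (F_int, C_skip) and ``wg`` (F_int, C_gate) project both inputs to a
    common intermediate width F_int; ``psi`` (F_int,) collapses the ReLU of
    their sum to a single pre-sigmoid logit per pixel.
    """

    wx: np.ndarray
    wg: np.ndarray
    psi: np.ndarray
    bx: np.ndarray
    bg: np.ndarray
    bpsi: float = 0.0

    def __post_init__(self):
        self.wx = np.asarray(self.wx, dtype=float)
        self.wg = np.asarray(self.wg, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float).reshape(-1)
        self.bx = np.asarray(self.bx, dtype=float)
        self.bg = np.asarray(self.bg, dtype=float)
        f = self.wx.shape[0]
        if self.wg.shape[0] != f or self.psi.shape[0] != f:
            raise ValueError("wx, wg and psi disagree on the intermediate width")

    @property
    def inter_channels(self) -> int:
        return self.wx.shape[0]

    @classmethod
    def init(cls, skip_channels: int, gate_channels: int, inter_channels=None, rng=None):
        rng = np.random.default_rng(rng)
        f = inter_channels or max(1, skip_channels // 2)
        return cls(
            wx=nn.he_normal(rng, (f, skip_channels), skip_channels),
            wg=nn.he_normal(rng, (f, gate_channels), gate_channels),
            psi=nn.he_normal(rng, (f,), f),
            bx=np.zeros(f, dtype=np.float32),
            bg=np.zeros(f, dtype=np.float32),
            bpsi=0.0,
        )


# ---------------------------------------------------------------------------
# functional surface


def squeeze(fm: np.ndarray) -> np.ndarray:
    """Global average pooling: channel n maps to the mean of its H x W plane."""
    fm = validate_feature_map(fm)
    return fm.mean(axis=(1, 2))


def excite(z: np.ndarray, params: ExcitationParams) -> np.ndarray:
    """Bottlenecked gating: sigmoid(w2 @ relu(w1 @ z + b1) + b2), in (0, 1)."""
    z = np.asarray(z, dtype=float).reshape(-1)
    if z.shape[0] != params.channels:
        raise ValueError(
            f"descriptor length {z.shape[0]} != parameter channels {params.channels}"
        )
    hidden = np.maximum(params.w1 @ z + params.b1, 0.0)
    return _sigmoid(params.w2 @ hidden + params.b2)


def scale(fm: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Channel-wise rescaling: output plane n = s[n] * input plane n."""
    fm = validate_feature_map(fm)
    s = np.asarray(s, dtype=float).reshape(-1)
    if s.shape[0] != fm.shape[0]:
        raise ValueError(f"scale length {s.shape[0]} != channel count {fm.shape[0]}")
    return fm * s[:, None, None]


def se_block(fm: np.ndarray, params: ExcitationParams) -> np.ndarray:
    """Squeeze -> excite -> scale; shape-preserving channel recalibration."""
    return scale(fm, excite(squeeze(fm), params))


def attention_gate(
    skip: np.ndarray, gate: np.ndarray, params: AttentionGateParams
) -> tuple[np.ndarray, np.ndarray]:
    """Additive attention gate at matched resolution.

    Both inputs pass through a 1x1 convolution into F_int channels, are summed,
    ReLU-ed, collapsed by another 1x1 convolution and squashed by a sigmoid,
    giving a per-pixel coefficient ``alpha`` in (0, 1). The output is
    ``alpha * skip`` broadcast over the skip channels.

    Returns ``(gated_skip, alpha)``.
    """
    skip = validate_feature_map(skip, "skip")
    gate = validate_feature_map(gate, "gate")
    if skip.shape[1:] != gate.shape[1:]:
        raise ValueError(
            f"spatial size mismatch: skip {skip.shape} vs gate {gate.shape}"
        )
    # 1x1 convolutions are per-pixel linear maps over channels
    px = np.tensordot(params.wx, skip, axes=([1], [0])) + params.bx[:, None, None]
    pg = np.tensordot(params.wg, gate, axes=([1], [0])) + params.bg[:, None, None]
    h = np.maximum(px + pg, 0.0)
    logit = np.tensordot(params.psi, h, axes=([0], [0])) + params.bpsi
    alpha = _sigmoid(logit)
    return skip * alpha[None, :, :], alpha


def conv_block(fm: np.ndarray, weights, biases=None, activation: str = "relu"):
    """Stacked 'same'-padded convolution(+activation) stages on one feature map.

    ``weights`` is a sequence of (Cout, Cin, k, k) kernels applied in order;
    ``activation`` is ``"relu"`` or ``"linear"``. Spatial size is preserved.
    """
    fm = validate_feature_map(fm)
    if biases is None:
        biases = [None] * len(weights)
    x = nn.Tensor(fm[None])
    for w, b in zip(weights, biases):
        k = np.asarray(w).shape[-1]
        if k % 2 == 0:
            raise ValueError(f"even kernel size {k} not supported (no 'same' padding)")
        x = nn.conv2d(
            x, nn.Tensor(w), None if b is None else nn.Tensor(np.asarray(b))
        )
        if activation == "relu":
            x = nn.relu(x)
        elif activation != "linear":
            raise ValueError(f"unknown activation {activation!r}")
    return x.data[0]


def transposed_conv_up(fm: np.ndarray, w: np.ndarray, b=None, stride: int = 2):
    """Stride-2 transposed convolution: doubles H and W; w is (Cin, Cout, 2, 2)."""
    fm = validate_feature_map(fm)
    out = nn.conv_transpose2d(
        nn.Tensor(fm[None]),
        nn.Tensor(np.asarray(w)),
        None if b is None else nn.Tensor(np.asarray(b)),
        stride=stride,
    )
    return out.data[0]


# ---------------------------------------------------------------------------
# trainable layers


class Module:
    """Base for layers: recursively collects trainable parameter tensors."""

    def parameters(self) -> list[nn.Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, nn.Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, nn.Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


class ConvBlock(Module):
    """``n_convs`` stacked same-padded conv+ReLU stages (U-Net level block)."""

    def __init__(self, in_channels, out_channels, kernel_size=5, n_convs=2, rng=None):
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel_size}")
        rng = np.random.default_rng(rng)
        self.kernel_size = kernel_size
        self.ws, self.bs = [], []
        cin = in_channels
        for _ in range(n_convs):
            fan_in = cin * kernel_size * kernel_size
            self.ws.append(
                nn.Parameter(
                    nn.he_normal(rng, (out_channels, cin, kernel_size, kernel_size), fan_in)
                )
            )
            self.bs.append(nn.Parameter(np.zeros(out_channels, dtype=np.float32)))
            cin = out_channels

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for w, b in zip(self.ws, self.bs):
            x = nn.relu(nn.conv2d(x, w, b))
        return x


class SEBlock(Module):
    """Trainable squeeze-and-excitation channel recalibration."""

    def __init__(self, channels, reduction=8, rng=None, bias=True):
        if channels % reduction:
            raise ValueError(
                f"channel count {channels} not divisible by reduction g={reduction}"
            )
        rng = np.random.default_rng(rng)
        hidden = channels // reduction
        self.w1 = nn.Parameter(nn.he_normal(rng, (hidden, channels), channels))
        self.w2 = nn.Parameter(nn.he_normal(rng, (channels, hidden), hidden))
        self.b1 = nn.Parameter(np.zeros(hidden, dtype=np.float32)) if bias else None
        self.b2 = nn.Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        z = nn.global_mean_pool(x)
        s = nn.sigmoid(nn.linear(nn.relu(nn.linear(z, self.w1, self.b1)), self.w2, self.b2))
        return nn.channel_scale(x, s)


class AttentionGate(Module):
    """Trainable additive attention gate acting on the skip connection."""

    def __init__(self, skip_channels, gate_channels, inter_channels=None, rng=None):
        rng = np.random.default_rng(rng)
        f = inter_channels or max(1, skip_channels // 2)
        self.wx = nn.Parameter(
            nn.he_normal(rng, (f, skip_channels, 1, 1), skip_channels)
        )
        self.wg = nn.Parameter(
            nn.he_normal(rng, (f, gate_channels, 1, 1), gate_channels)
        )
        self.psi = nn.Parameter(nn.he_normal(rng, (1, f, 1, 1), f))
        self.bx = nn.Parameter(np.zeros(f, dtype=np.float32))
        self.bg = nn.Parameter(np.zeros(f, dtype=np.float32))
        self.bpsi = nn.Parameter(np.zeros(1, dtype=np.float32))

    def __call__(self, skip: nn.Tensor, gate: nn.Tensor) -> nn.Tensor:
        if skip.data.shape[2:] != gate.data.shape[2:]:
            raise ValueError(
                f"spatial size mismatch: skip {skip.data.shape} vs gate {gate.data.shape}"
            )
        px = nn.conv2d(skip, self.wx, self.bx)
        pg = nn.conv2d(gate, self.wg, self.bg)
        alpha = nn.sigmoid(nn.conv2d(nn.relu(nn.add(px, pg)), self.psi, self.bpsi))
        return nn.spatial_scale(skip, alpha)


class UpConv(Module):
    """Stride-2 transposed convolution halving the channel count."""

    def __init__(self, in_channels, out_channels, rng=None):
        rng = np.random.default_rng(rng)
        self.w = nn.Parameter(
            nn.he_normal(rng, (in_channels, out_channels, 2, 2), in_channels * 4)
        )
        self.b = nn.Parameter(np.zeros(out_channels, dtype=np.float32))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.conv_transpose2d(x, self.w, self.b, stride=2)


class Conv1x1Head(Module):
    """Final 1x1 convolution + sigmoid producing the probability map."""

    def __init__(self, in_channels, rng=None):
        rng = np.random.default_rng(rng)
        self.w = nn.Parameter(nn.he_normal(rng, (1, in_channels, 1, 1), in_channels))
        self.b = nn.Parameter(np.zeros(1, dtype=np.float32))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.sigmoid(nn.conv2d(x, self.w, self.b))
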