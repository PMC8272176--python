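"""Assembly of the segmentation network and its ablation variants.

The model is a U-shaped encoder–decoder. The encoder has ``depth`` levels of
stacked same-padded convolutions whose width doubles per level; from level 2
on, each level is entered through a 2x2 max-pool and (optionally) exits
through a squeeze-and-excitation block, so that the skip connection carries
the recalibrated channels. The decoder mirrors the encoder: each stage
up-samples (learnable stride-2 transposed convolution by default), optionally
gates the skip features with an additive attention gate driven by the
up-sampled decoder features, concatenates, and convolves back down to the
level width. A 1x1 convolution + sigmoid emits a single-channel probability
map at input resolution.

``summarize`` performs purely analytic parameter and multiply–accumulate
accounting from the configuration, without instantiating the model, so that
the cost of the SE blocks (the "<0.5% overhead" property) can be checked in
closed form.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .core_blocks import (
    AttentionGate,
    Conv1x1Head,
    ConvBlock,
    Module,
    SEBlock,
    UpConv,
)

__all__ = [
    "ArchitectureConfig",
    "ModelSummary",
    "CaseNet",
    "build_model",
    "make_variant",
    "summarize",
    "VARIANTS",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Structural description of a network variant."""

    depth: int = 5
    base_width: int = 64
    kernel_size: int = 5
    use_se: bool = True
    use_attention: bool = True
    se_reduction: int = 8
    upsample_mode: str = "transposed"  # "transposed" | "nearest"
    input_size: tuple[int, int] = (384, 384)
    convs_per_block: int = 2
    out_activation: str = "sigmoid"

    def __post_init__(self):
        object.__setattr__(self, "input_size", tuple(self.input_size))
        if self.kernel_size % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {self.kernel_size}")
        if self.upsample_mode not in ("transposed", "nearest"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        h, w = self.input_size
        f = 2 ** (self.depth - 1)
        if h % f or w % f:
            raise ValueError(
                f"input size {h}x{w} not divisible by 2^(depth-1)={f}; "
                "the encoder cannot pool that far"
            )

    @property
    def level_widths(self) -> list[int]:
        return [self.base_width * 2**i for i in range(self.depth)]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureConfig":
        return cls(**json.loads(text))


#: Ablation / baseline variants. ``casenet`` is the full model; the three
#: ablations each change exactly one delta; the baselines are the classic
#: U-Net (3x3 kernels, nearest-neighbour upsampling, no SE, no attention)
#: and its single-module extensions.
VARIANTS: dict[str, dict] = {
    "casenet": {},
    "casenet_3x3": {"kernel_size": 3},
    "casenet_no_atn": {"use_attention": False},
    "casenet_no_se": {"use_se": False},
    "unet": {
        "kernel_size": 3,
        "use_se": False,
        "use_attention": False,
        "upsample_mode": "nearest",
    },
    "use_net": {
        "kernel_size": 3,
        "use_se": True,
        "use_attention": False,
        "upsample_mode": "nearest",
    },
    "atn_net": {
        "kernel_size": 3,
        "use_se": False,
        "use_attention": True,
        "upsample_mode": "nearest",
    },
}


def make_variant(name: str, **overrides) -> ArchitectureConfig:
    """Named architecture variants used by the ablation/comparison study."""
    if name not in VARIANTS:
        raise ValueError(
            f"unknown variant {name!r}; choose one of {sorted(VARIANTS)}"
        )
    kwargs = dict(VARIANTS[name])
    kwargs.update(overrides)
    return ArchitectureConfig(**kwargs)


class CaseNet(Module):
    """The trainable encoder–decoder segmentation network."""

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.level_widths
        k, nconv = cfg.kernel_size, cfg.convs_per_block

        self.enc_blocks: list[ConvBlock] = []
        self.se_blocks: list[SEBlock | None] = []
        cin = 1
        for lvl, cout in enumerate(widths):
            self.enc_blocks.append(ConvBlock(cin, cout, k, nconv, rng))
            # recalibration only at non-superficial levels (after each pool)
            if cfg.use_se and lvl >= 1:
                self.se_blocks.append(SEBlock(cout, cfg.se_reduction, rng))
            else:
                self.se_blocks.append(None)
            cin = cout

        self.up_convs: list[UpConv | None] = []
        self.attention_gates: list[AttentionGate | None] = []
        self.dec_blocks: list[ConvBlock] = []
        for lvl in range(cfg.depth - 2, -1, -1):
            c_skip, c_deep = widths[lvl], widths[lvl + 1]
            if cfg.upsample_mode == "transposed":
                self.up_convs.append(UpConv(c_deep, c_skip, rng))
                c_gate = c_skip
            else:
                self.up_convs.append(None)
                c_gate = c_deep
            if cfg.use_attention:
                self.attention_gates.append(AttentionGate(c_skip, c_gate, rng=rng))
            else:
                self.attention_gates.append(None)
            self.dec_blocks.append(ConvBlock(c_skip + c_gate, c_skip, k, nconv, rng))

        self.head = Conv1x1Head(widths[0], rng)

    # -- forward -----------------------------------------------------------
    def forward(self, x) -> nn.Tensor:
        """Run a batch (N, 1, H, W) through the network; returns probabilities."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[2:] != self.cfg.input_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} != configured "
                f"{self.cfg.input_size}"
            )
        t = nn.Tensor(x)
        skips = []
        for lvl, block in enumerate(self.enc_blocks):
            if lvl > 0:
                t = nn.maxpool2x2(t)
            t = block(t)
            if self.se_blocks[lvl] is not None:
                t = self.se_blocks[lvl](t)
            if lvl < self.cfg.depth - 1:
                skips.append(t)
        for i, lvl in enumerate(range(self.cfg.depth - 2, -1, -1)):
            if self.up_convs[i] is not None:
                t = self.up_convs[i](t)
            else:
                t = nn.upsample_nearest2x(t)
            skip = skips[lvl]
            if self.attention_gates[i] is not None:
                skip = self.attention_gates[i](skip, t)
            t = self.dec_blocks[i](nn.concat_channels(skip, t))
        return self.head(t)

    def predict_probs(self, x, batch_size: int = 4) -> np.ndarray:
        """Forward in batches, returning a (N, H, W) probability array."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[i : i + batch_size]).data[:, 0])
        return np.concatenate(outs, axis=0)

    # -- structural introspection ------------------------------------------
    @property
    def n_se_blocks(self) -> int:
        return sum(b is not None for b in self.se_blocks)

    @property
    def n_attention_gates(self) -> int:
        return sum(g is not None for g in self.attention_gates)


def build_model(cfg: ArchitectureConfig, seed: int = 0) -> CaseNet:
    return CaseNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# analytic accounting


@dataclass
class ModelSummary:
    """Analytic parameter and multiply–accumulate accounting."""

    trainable_parameters: int
    mac_count: int
    per_component: dict

    def __post_init__(self):
        p = sum(c["parameters"] for c in self.per_component.values())
        m = sum(c["macs"] for c in self.per_component.values())
        assert p == self.trainable_parameters and m == self.mac_count


def _conv_cost(cin, cout, k, h, w, bias=True):
    params = k * k * cin * cout + (cout if bias else 0)
    macs = k * k * cin * cout * h * w
    return params, macs


def summarize(cfg: ArchitectureConfig) -> ModelSummary:
    """Count parameters and forward-pass MACs from the configuration alone.

    Conventions: a k x k convolution over a C_in -> C_out map of output size
    H x W costs k^2*C_in*C_out*H*W MACs; a fully connected layer costs
    C_in*C_out; the stride-2 transposed convolution costs 4*C_in*C_out per
    *input* pixel; pooling and activations are free; the elementwise
    recalibration multiplies (SE scaling, attention masking) are charged one
    multiply per affected value.
    """
    widths = cfg.level_widths
    k, nconv = cfg.kernel_size, cfg.convs_per_block
    comp = {
        name: {"parameters": 0, "macs": 0}
        for name in ("convolutions", "upsampling", "se_blocks", "attention_gates", "output_head")
    }

    def charge(name, params, macs):
        comp[name]["parameters"] += int(params)
        comp[name]["macs"] += int(macs)

    h, w = cfg.input_size
    # encoder
    cin = 1
    for lvl, cout in enumerate(widths):
        if lvl > 0:
            h, w = h // 2, w // 2
        c = cin
        for _ in range(nconv):
            charge("convolutions", *_conv_cost(c, cout, k, h, w))
            c = cout
        if cfg.use_se and lvl >= 1:
            g = cfg.se_reduction
            hid = cout // g
            charge(
                "se_blocks",
                cout * hid + hid + hid * cout + cout,  # two FC layers + biases
                cout * hid + hid * cout + cout * h * w,  # FCs + channel rescale
            )
        cin = cout
    # decoder
    for lvl in range(cfg.depth - 2, -1, -1):
        c_skip, c_deep = widths[lvl], widths[lvl + 1]
        hin, win = h, w
        h, w = h * 2, w * 2
        if cfg.upsample_mode == "transposed":
            charge(
                "upsampling",
                4 * c_deep * c_skip + c_skip,
                4 * c_deep * c_skip * hin * win,
            )
            c_gate = c_skip
        else:
            c_gate = c_deep
        if cfg.use_attention:
            f = max(1, c_skip // 2)
            p = (c_skip * f + f) + (c_gate * f + f) + (f + 1)
            m = (c_skip * f + c_gate * f + f) * h * w + c_skip * h * w
            charge("attention_gates", p, m)
        c = c_skip + c_gate
        for _ in range(nconv):
            charge("convolutions", *_conv_cost(c, c_skip, k, h, w))
            c = c_skip
    # head
    charge("output_head", *_conv_cost(widths[0], 1, 1, h, w))

    total_p = sum(c["parameters"] for c in comp.values())
    total_m = sum(c["macs"] for c in comp.values())
    return ModelSummary(total_p, total_m, comp)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: CaseNet, path) -> None:
    """Write weights as .npz plus a JSON sidecar with the full config."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    path.with_suffix(".json").write_text(model.cfg.to_json())


def load_checkpoint(path) -> CaseNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    cfg = ArchitectureConfig.from_json(path.with_suffix(".json").read_text())
    model = CaseNet(cfg)
    with np.load(path) as zf:
        arrays = [zf[f"p{i}"] for i in range(len(zf.files))]
    model.load_state_arrays(arrays)
    return model
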