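"""Segmentation networks: plain U-Net backbone, the SE-connection (SEC)
pyramid network, and the auto-context cascade.

The primary network replaces the plain copy skip-connections of a U-Net with
SEC modules.  Each SEC takes the encoder feature of its own level ("level 1")
and the output of the SEC one level deeper ("level 2"), convolves the deeper
map to the shallower channel width, bilinearly upsamples it 2x, concatenates
with the encoder feature, convolves the concatenation back down, and finally
applies squeeze-and-excitation channel gating.  Chaining the SEC outputs from
the network bottom upward forms a pyramid along which global context and
multi-size organ information flows to every decoder stage — the design is
aimed at tasks mixing large and very small structures, such as organ-at-risk
segmentation in head-and-neck CT.

The cascade concatenates the original image with the primary network's
per-class probability maps (auto-context) and feeds the stack to a second,
plain U-Net for refinement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import (
    Tensor,
    concat_channels,
    global_avg_pool,
    maxpool2x,
    relu,
    scale_channels,
    sigmoid,
    softmax_channels,
    upsample_bilinear2x,
)
from .layers import Conv2d, ConvBlock, Linear, Module

__all__ = [
    "NetworkConfig",
    "SEBlock",
    "SECFuse",
    "UNetBackbone",
    "SECPNet",
    "CascadeNet",
    "predict_labels",
    "parameter_count",
    "gradient_flow_audit",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters shared by all networks in this module.

    ``depth`` is the number of 2x down-samplings; ``stage_channels`` lists the
    feature widths shallow-to-deep and must have ``depth + 1`` entries (the
    last is the bottleneck width).  Valid input sizes are multiples of
    ``2 ** depth``.  ``se_reduction`` is the squeeze-and-excitation bottleneck
    ratio; the hidden width is clamped to at least 1.
    """

    num_classes: int
    in_channels: int = 1
    depth: int = 4
    stage_channels: tuple = (64, 128, 256, 512, 1024)
    se_reduction: int = 16
    batch_norm: bool = True
    upsample_mode: str = field(default="bilinear")

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2 (background + organs)")
        if self.in_channels < 1 or self.depth < 1 or self.se_reduction < 1:
            raise ValueError("in_channels, depth and se_reduction must be >= 1")
        if len(self.stage_channels) != self.depth + 1:
            raise ValueError(
                f"stage_channels must have depth+1={self.depth + 1} entries, "
                f"got {len(self.stage_channels)}"
            )
        if any(c < 1 for c in self.stage_channels):
            raise ValueError("all stage widths must be >= 1")
        if self.upsample_mode != "bilinear":
            raise ValueError("only bilinear upsampling is supported")

    @classmethod
    def small(cls, num_classes, in_channels=1, batch_norm=True):
        """CPU-friendly preset: depth 3, widths 8/16/32/64, SE reduction 4."""
        return cls(
            num_classes=num_classes,
            in_channels=in_channels,
            depth=3,
            stage_channels=(8, 16, 32, 64),
            se_reduction=4,
            batch_norm=batch_norm,
        )

    def to_dict(self):
        return {
            "num_classes": self.num_classes,
            "in_channels": self.in_channels,
            "depth": self.depth,
            "stage_channels": list(self.stage_channels),
            "se_reduction": self.se_reduction,
            "batch_norm": self.batch_norm,
            "upsample_mode": self.upsample_mode,
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["stage_channels"] = tuple(d["stage_channels"])
        return cls(**d)

    def check_spatial(self, H, W):
        step = 2**self.depth
        if H % step:
            raise ValueError(f"height {H} is not a multiple of 2^depth={step}")
        if W % step:
            raise ValueError(f"width {W} is not a multiple of 2^depth={step}")


def _as_tensor(x):
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    return Tensor(x)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate.

    Squeeze: global average pooling reduces each channel to one statistic.
    Excitation: a two-layer bottleneck (ReLU then sigmoid) produces a gate
    in (0, 1) per channel, which rescales the input channel-wise.
    """

    def __init__(self, channels, reduction, rng):
        super().__init__()
        if channels < 1 or reduction < 1:
            raise ValueError("channels and reduction must be >= 1")
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        return sigmoid(self.fc2(relu(self.fc1(global_avg_pool(x)))))

    def forward(self, x) -> Tensor:
        x = _as_tensor(x)
        if not np.all(np.isfinite(x.data)):
            raise ValueError("SE block input contains non-finite values")
        return scale_channels(x, self.gates(x))


class SECFuse(Module):
    """SE-connection module fusing two adjacent pyramid levels.

    Pipeline: 3x3 same-padding conv mapping the deeper map to the shallower
    width -> bilinear 2x upsample -> channel concatenation with the shallower
    encoder feature -> 3x3 conv back to the shallower width -> SE gating.
    """

    def __init__(self, shallow_channels, deep_channels, reduction, rng):
        super().__init__()
        self.conv_deep = Conv2d(deep_channels, shallow_channels, 3, rng)
        self.conv_fuse = Conv2d(2 * shallow_channels, shallow_channels, 3, rng)
        self.se = SEBlock(shallow_channels, reduction, rng)

    def forward(self, level1, level2) -> Tensor:
        level1, level2 = _as_tensor(level1), _as_tensor(level2)
        h1, w1 = level1.shape[2:]
        h2, w2 = level2.shape[2:]
        if (h1, w1) != (2 * h2, 2 * w2):
            raise ValueError(
                f"SEC spatial mismatch: level1 {level1.shape} must be exactly "
                f"2x level2 {level2.shape}"
            )
        up = upsample_bilinear2x(self.conv_deep(level2))
        fused = self.conv_fuse(concat_channels(level1, up))
        return self.se(fused)


class _Stage(Module):
    """Two conv(-BN)-ReLU blocks, the standard U-Net stage."""

    def __init__(self, in_channels, out_channels, rng, batch_norm):
        super().__init__()
        self.block1 = ConvBlock(in_channels, out_channels, rng, batch_norm)
        self.block2 = ConvBlock(out_channels, out_channels, rng, batch_norm)

    def forward(self, x):
        return self.block2(self.block1(x))


class _UShape(Module):
    """Shared encoder/decoder scaffolding for the backbone and pyramid nets."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        self.cfg = cfg
        ch = cfg.stage_channels
        D = cfg.depth
        self.enc = [
            _Stage(cfg.in_channels if d == 0 else ch[d - 1], ch[d], rng, cfg.batch_norm)
            for d in range(D)
        ]
        self.bottleneck = _Stage(ch[D - 1], ch[D], rng, cfg.batch_norm)
        # decoder stage d consumes [skip ch[d], upsampled ch[d+1]]
        self.dec = [
            _Stage(ch[d] + ch[d + 1], ch[d], rng, cfg.batch_norm) for d in range(D)
        ]
        self.head = Conv2d(ch[0], cfg.num_classes, 1, rng)

    def _encode(self, x: Tensor):
        feats = []
        h = x
        for stage in self.enc:
            h = stage(h)
            feats.append(h)
            h = maxpool2x(h)
        return feats, self.bottleneck(h)

    def _decode(self, bottom: Tensor, skips) -> Tensor:
        h = bottom
        for d in range(self.cfg.depth - 1, -1, -1):
            h = self.dec[d](concat_channels(skips[d], upsample_bilinear2x(h)))
        return self.head(h)

    def _check_input(self, x: Tensor):
        if x.ndim != 4:
            raise ValueError(f"expected (batch, channel, H, W) input, got {x.shape}")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, network expects "
                f"{self.cfg.in_channels}"
            )
        self.cfg.check_spatial(*x.shape[2:])


class UNetBackbone(_UShape):
    """Plain U-Net: encoder, bottleneck, decoder with copy skip-connections,
    bilinear upsampling and a 1x1 classification head. Returns logits."""

    def forward(self, x) -> Tensor:
        x = _as_tensor(x)
        self._check_input(x)
        feats, bott = self._encode(x)
        return self._decode(bott, feats)


class SECPNet(_UShape):
    """Primary pyramid network.

    The encoder matches the backbone.  At the bottom, an SE block gates the
    bottleneck features to form the deepest pyramid level; for levels
    ``depth-1`` down to ``1`` an SEC module fuses the encoder feature with the
    pyramid output from one level deeper.  Each SEC output serves both as the
    decoder skip input of its level and as the deeper input to the next SEC.
    The shallowest skip is the plain encoder feature, and the bottleneck
    itself (ungated) feeds the first decoder upsampling, as in the backbone.
    """

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__(cfg, rng)
        ch = cfg.stage_channels
        D = cfg.depth
        self.se_bottom = SEBlock(ch[D], cfg.se_reduction, rng)
        # secs[i] fuses level d = D-1-i with the pyramid output from d+1
        self.secs = [
            SECFuse(ch[d], ch[d + 1], cfg.se_reduction, rng)
            for d in range(D - 1, 0, -1)
        ]

    def forward(self, x):
        x = _as_tensor(x)
        self._check_input(x)
        feats, bott = self._encode(x)
        D = self.cfg.depth
        skips = [None] * D
        pyramid = self.se_bottom(bott)
        for i, d in enumerate(range(D - 1, 0, -1)):
            pyramid = self.secs[i](feats[d], pyramid)
            skips[d] = pyramid
        skips[0] = feats[0]
        logits = self._decode(bott, skips)
        return logits, softmax_channels(logits)


class CascadeNet(Module):
    """Auto-context cascade: the secondary U-Net consumes the original image
    concatenated channel-wise with the primary network's probability maps."""

    def __init__(self, cfg: NetworkConfig, rng, secondary_cfg=None):
        super().__init__()
        self.primary = SECPNet(cfg, rng)
        if secondary_cfg is None:
            secondary_cfg = NetworkConfig(
                num_classes=cfg.num_classes,
                in_channels=cfg.in_channels + cfg.num_classes,
                depth=cfg.depth,
                stage_channels=cfg.stage_channels,
                se_reduction=cfg.se_reduction,
                batch_norm=cfg.batch_norm,
            )
        expected = cfg.in_channels + cfg.num_classes
        if secondary_cfg.in_channels != expected:
            raise ValueError(
                f"secondary network expects {secondary_cfg.in_channels} input "
                f"channels but the auto-context stack has {expected} "
                f"(image {cfg.in_channels} + classes {cfg.num_classes})"
            )
        self.secondary = UNetBackbone(secondary_cfg, rng)

    def forward(self, x):
        x = _as_tensor(x)
        _, primary_probs = self.primary(x)
        stacked = concat_channels(x, primary_probs)
        final_logits = self.secondary(stacked)
        return primary_probs, final_logits, softmax_channels(final_logits)


def predict_labels(probs) -> np.ndarray:
    """Per-pixel argmax over the class axis; ties go to the lowest index.

    Accepts (B, C, H, W) or (C, H, W) probability (or logit) arrays.
    """
    data = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
    axis = 1 if data.ndim == 4 else 0
    return data.argmax(axis=axis)


def parameter_count(module: Module) -> int:
    return sum(p.data.size for p in module.parameters())


def gradient_flow_audit(module: Module, loss: Tensor) -> dict:
    """Backprop ``loss`` and report, per parameter name, whether any gradient
    component is nonzero.  Used to verify no branch of the pyramid is dead."""
    for p in module.parameters():
        p.zero_grad()
    loss.backward()
    return {
        name: p.grad is not None and bool(np.any(p.grad != 0.0))
        for name, p in module.named_parameters()
    }


# ---------------------------------------------------------------------------
# checkpoints: one .npz parameter archive + one .json config sidecar
# ---------------------------------------------------------------------------

_NET_CLASSES = {"UNetBackbone": UNetBackbone, "SECPNet": SECPNet}


def save_checkpoint(module: Module, path) -> Path:
    """Serialise parameters to ``<path>.npz`` and the config to
    ``<path>.json`` so the checkpoint is self-describing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(module, CascadeNet):
        np.savez(
            path.with_suffix(".npz"),
            **{f"primary.{k}": v for k, v in module.primary.state_dict().items()},
            **{f"secondary.{k}": v for k, v in module.secondary.state_dict().items()},
        )
        meta = {
            "class": "CascadeNet",
            "config": module.primary.cfg.to_dict(),
            "secondary_config": module.secondary.cfg.to_dict(),
        }
    else:
        np.savez(path.with_suffix(".npz"), **module.state_dict())
        meta = {"class": type(module).__name__, "config": module.cfg.to_dict()}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path) -> Module:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = NetworkConfig.from_dict(meta["config"])
    rng = np.random.default_rng(0)  # overwritten immediately by the load
    with np.load(path.with_suffix(".npz")) as archive:
        state = {k: archive[k] for k in archive.files}
    if meta["class"] == "CascadeNet":
        secondary_cfg = NetworkConfig.from_dict(meta["secondary_config"])
        net = CascadeNet(cfg, rng, secondary_cfg)
        net.primary.load_state_dict(
            {k[len("primary.") :]: v for k, v in state.items() if k.startswith("primary.")}
        )
        net.secondary.load_state_dict(
            {
                k[len("secondary.") :]: v
                for k, v in state.items()
                if k.startswith("secondary.")
            }
        )
        return net
    cls = _NET_CLASSES[meta["class"]]
    net = cls(cfg, rng)
    net.load_state_dict(state)
    return net
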