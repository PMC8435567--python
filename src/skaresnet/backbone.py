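"""ResNet-50-style backbones with optional SGE / SK / SKA attention blocks.

Four variants share one bottleneck skeleton (1x1 reduce, 3x3, 1x1 expand,
identity or projection shortcut):

- ``resnet`` — plain bottleneck;
- ``sge``    — an SGE gate appended to the residual path;
- ``sk``     — a selective-kernel module (two-kernel divide/fuse/select,
  no SGE) appended to the residual path;
- ``ska``    — the full SKA module (SK + per-branch SGE).

The attention module is applied to the residual-path output immediately
before the shortcut addition.  ``width_divisor`` shrinks every channel
width (and the SGE group count) proportionally for desk-scale models;
it does not change the topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .attention import SGE, SKAConfig, SKAModule
from .autodiff import Tensor, global_avg_pool, max_pool2d
from .layers import BatchNorm2d, Conv2d, Linear, Module

VARIANTS = ("resnet", "sge", "sk", "ska")
STAGE_MIDS = (64, 128, 256, 512)
EXPANSION = 4


@dataclass
class NetSpec:
    """Architecture description (Table-1 style)."""

    variant: str = "ska"
    stage_blocks: tuple = (3, 4, 6, 3)
    num_classes: int = 1000
    input_size: int = 224
    width_divisor: int = 1
    groups: int = 32

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if len(self.stage_blocks) != 4:
            raise ValueError("stage_blocks must list four stage depths")
        if self.width_divisor < 1:
            raise ValueError("width_divisor must be >= 1")

    @property
    def effective_groups(self) -> int:
        return max(self.groups // self.width_divisor, 1)

    @property
    def stem_channels(self) -> int:
        return max(64 // self.width_divisor, 1)

    def stage_channels(self, stage: int) -> tuple:
        mid = max(STAGE_MIDS[stage] // self.width_divisor, 1)
        return mid, mid * EXPANSION

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "stage_blocks": list(self.stage_blocks),
            "num_classes": self.num_classes,
            "input_size": self.input_size,
            "width_divisor": self.width_divisor,
            "groups": self.groups,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetSpec":
        d = dict(d)
        d["stage_blocks"] = tuple(d["stage_blocks"])
        return cls(**d)


class FeatureBundle(NamedTuple):
    """Intermediate maps tapped for the multi-scale heads."""

    F3: Tensor       # last conv4 block output, (N, C3, H/16, W/16)
    F4: Tensor       # last conv5 block output, (N, C4, H/32, W/32)
    pooled: Tensor   # global-average-pooled F4, (N, C4)
    logits: Tensor   # main-head class scores, (N, num_classes)


class Bottleneck(Module):
    """1x1 / 3x3 / 1x1 bottleneck with optional attention on the residual path."""

    def __init__(self, variant: str, in_ch: int, mid_ch: int, stride: int,
                 groups: int, rng=None):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"invalid variant {variant!r}")
        out_ch = mid_ch * EXPANSION
        self.variant, self.in_ch, self.out_ch, self.stride = variant, in_ch, out_ch, stride
        self.conv1 = Conv2d(in_ch, mid_ch, 1, rng=rng)
        self.bn1 = BatchNorm2d(mid_ch)
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(mid_ch)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        cfg = SKAConfig(groups=groups)
        if variant == "sge":
            self.attn = SGE(out_ch, groups)
        elif variant == "sk":
            self.attn = SKAModule(out_ch, cfg, use_sge=False, rng=rng)
        elif variant == "ska":
            self.attn = SKAModule(out_ch, cfg, use_sge=True, rng=rng)
        else:
            self.attn = None
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.down_bn = BatchNorm2d(out_ch)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1.forward(self.conv1.forward(x)).relu()
        out = self.bn2.forward(self.conv2.forward(out)).relu()
        out = self.bn3.forward(self.conv3.forward(out))
        if self.attn is not None:
            out = self.attn.forward(out)
        shortcut = x
        if self.down_conv is not None:
            shortcut = self.down_bn.forward(self.down_conv.forward(x))
        return (out + shortcut).relu()


def build_block(variant: str, in_ch: int, mid_ch: int, stride: int,
                groups: int = 32, rng=None) -> Bottleneck:
    return Bottleneck(variant, in_ch, mid_ch, stride, groups, rng=rng)


class SKAResNet(Module):
    """Stem + four bottleneck stages + global average pool + fc head."""

    def __init__(self, spec: NetSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        g = spec.effective_groups
        stem = spec.stem_channels
        self.stem_conv = Conv2d(3, stem, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = BatchNorm2d(stem)
        self.stages = []
        in_ch = stem
        for s, depth in enumerate(spec.stage_blocks):
            mid, out_ch = spec.stage_channels(s)
            if (spec.variant in ("sge", "sk", "ska")) and out_ch % g:
                raise ValueError(
                    f"groups={g} must divide stage output channels {out_ch}"
                )
            blocks = []
            for b in range(depth):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(Bottleneck(spec.variant, in_ch, mid, stride, g, rng=rng))
                in_ch = out_ch
            self.stages.append(blocks)
        self.feature_channels = in_ch
        self.f3_channels = spec.stage_channels(2)[1]
        self.fc = Linear(in_ch, spec.num_classes, bias=True, rng=rng)

    # -- forward ---------------------------------------------------------
    def _check_input(self, x: Tensor) -> None:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected NCHW RGB input, got shape {x.shape}")
        if x.shape[2] < 32 or x.shape[3] < 32:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} too small: five stride-2 "
                "reductions need at least 32x32"
            )

    def forward_features(self, x) -> FeatureBundle:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        self._check_input(x)
        h = self.stem_bn.forward(self.stem_conv.forward(x)).relu()
        h = max_pool2d(h, 3, 2, 1)
        f3 = None
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                h = blk.forward(h)
            if s == 2:
                f3 = h
        pooled = global_avg_pool(h)
        logits = self.fc.forward(pooled)
        return FeatureBundle(F3=f3, F4=h, pooled=pooled, logits=logits)

    def forward(self, x) -> Tensor:
        return self.forward_features(x).logits


def build_model(spec: NetSpec, rng=None) -> SKAResNet:
    return SKAResNet(spec, rng=rng)


def forward_features(model: SKAResNet, batch) -> FeatureBundle:
    return model.forward_features(batch)


# ---------------------------------------------------------------------------
# checkpointing (weights + spec serialized together)
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: SKAResNet, path, head: Module | None = None) -> None:
    state = {f"model::{k}": v for k, v in model.state_arrays().items()}
    if head is not None:
        state.update({f"head::{k}": v for k, v in head.state_arrays().items()})
    meta = json.dumps({"version": CHECKPOINT_VERSION, "spec": model.spec.to_dict(),
                       "has_head": head is not None})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path, head_factory=None):
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        spec = NetSpec.from_dict(meta["spec"])
        model = SKAResNet(spec)
        model.load_state_arrays(
            {k[len("model::"):]: z[k] for k in z.files if k.startswith("model::")}
        )
        head = None
        if meta["has_head"] and head_factory is not None:
            head = head_factory(model)
            head.load_state_arrays(
                {k[len("head::"):]: z[k] for k in z.files if k.startswith("head::")}
            )
    return model, head


def model_summary(model: SKAResNet) -> str:
    """Human-readable layer inventory."""
    lines = [f"{model.spec.variant}-net  classes={model.spec.num_classes}  "
             f"width_divisor={model.spec.width_divisor}"]
    lines.append(f"stem: 7x7/{model.spec.stem_channels} stride 2 + 3x3 maxpool stride 2")
    for s, blocks in enumerate(model.stages):
        mid, out_ch = model.spec.stage_channels(s)
        lines.append(f"stage{s + 1}: {len(blocks)} x bottleneck({mid}->{out_ch})"
                     + ("" if model.spec.variant == "resnet" else f" + {model.spec.variant} module"))
    lines.append(f"head: global avg pool + fc({model.feature_channels}->{model.spec.num_classes})")
    lines.append(f"parameters: {model.num_parameters():,}")
    return "\n".join(lines)
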