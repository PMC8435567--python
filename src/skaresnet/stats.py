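"""Closed-form parameter and multiply-add accounting.

Parameter counts are exact: every learnable scalar (conv/fc weights and
biases, batch-norm gamma/beta, SGE gamma/beta) is summed from the actual
arrays, itemized per layer.

Multiply-adds are computed analytically from layer shapes, without
running the network, under one frozen convention:

- convolution: k^2 * (Cin/groups) * Cout * Hout * Wout  (+ Cout*Hout*Wout for bias)
- fully connected: Cin * Cout (+ Cout for bias)
- batch norm: 2 ops per element (scale and shift)
- ReLU / sigmoid: 1 op per element
- pooling (max, average, global): 1 op per input element
- attention arithmetic (sums, gates, standardizations): 1 op per element
  of each elementwise stage
- residual additions are not counted

Counts are reported both as raw integers and in the M / G units used in
architecture tables (2-decimal M parameters, 3-decimal G multiply-adds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .attention import SGE, CBAM, SKAModule
from .backbone import Bottleneck, NetSpec, SKAResNet
from .layers import BatchNorm1d, BatchNorm2d, Conv2d, Linear


@dataclass
class LayerRow:
    name: str
    kind: str
    params: int
    madds: int


@dataclass
class ModelStats:
    params: int
    madds: int
    per_layer: list = field(default_factory=list)

    @property
    def params_millions(self) -> float:
        return round(self.params / 1e6, 2)

    @property
    def gmadds(self) -> float:
        return round(self.madds / 1e9, 3)

    def as_table(self) -> str:
        lines = [f"{'layer':<40}{'kind':<14}{'params':>12}{'madds':>16}"]
        for row in self.per_layer:
            lines.append(f"{row.name:<40}{row.kind:<14}{row.params:>12,}{row.madds:>16,}")
        lines.append(f"{'TOTAL':<40}{'':<14}{self.params:>12,}{self.madds:>16,}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "params": self.params,
            "params_millions": self.params_millions,
            "madds": self.madds,
            "gmadds": self.gmadds,
            "per_layer": [vars(r) for r in self.per_layer],
        }


# ---------------------------------------------------------------------------
# primitive counting rules
# ---------------------------------------------------------------------------

def conv2d_counts(kernel: int, cin: int, cout: int, hout: int, wout: int,
                  groups: int = 1, bias: bool = False) -> tuple:
    params = kernel * kernel * (cin // groups) * cout + (cout if bias else 0)
    madds = kernel * kernel * (cin // groups) * cout * hout * wout
    if bias:
        madds += cout * hout * wout
    return params, madds


def linear_counts(cin: int, cout: int, bias: bool = True) -> tuple:
    params = cin * cout + (cout if bias else 0)
    madds = cin * cout + (cout if bias else 0)
    return params, madds


def _conv_out(hw: tuple, kernel: int, stride: int, padding: int) -> tuple:
    h, w = hw
    return ((h + 2 * padding - kernel) // stride + 1,
            (w + 2 * padding - kernel) // stride + 1)


class _Ledger:
    def __init__(self):
        self.rows = []

    def add(self, name, kind, params, madds):
        self.rows.append(LayerRow(name, kind, int(params), int(madds)))

    def conv(self, name, conv: Conv2d, hw):
        ho, wo = _conv_out(hw, conv.kernel, conv.stride, conv.padding)
        p, m = conv2d_counts(conv.kernel, conv.in_ch, conv.out_ch, ho, wo,
                             conv.groups, conv.bias is not None)
        self.add(name, "conv", p, m)
        return ho, wo

    def bn2d(self, name, bn: BatchNorm2d, hw):
        self.add(name, "bn", 2 * bn.num_features, 2 * bn.num_features * hw[0] * hw[1])

    def act(self, name, numel, kind="relu"):
        self.add(name, kind, 0, numel)

    def linear(self, name, lin: Linear):
        p, m = linear_counts(lin.in_features, lin.out_features, lin.bias is not None)
        self.add(name, "fc", p, m)


def _sge_stats(led: _Ledger, name: str, sge: SGE, c: int, hw: tuple):
    h, w = hw
    numel = c * h * w
    g = sge.groups
    # group GAP + similarity dot + spatial standardize + gate + scale
    madds = numel + numel + 2 * g * h * w + g * h * w + numel
    led.add(name, "sge", 2 * g, madds)


def _ska_stats(led: _Ledger, name: str, ska: SKAModule, c: int, hw: tuple):
    h, w = hw
    numel = c * h * w
    for tag, branch in (("a", ska.branch_a), ("b", ska.branch_b)):
        led.conv(f"{name}.branch_{tag}.conv", branch.conv, hw)
        led.bn2d(f"{name}.branch_{tag}.bn", branch.bn, hw)
        led.act(f"{name}.branch_{tag}.relu", numel)
    # fuse: branch sum + GAP + channel standardize + group average
    led.add(f"{name}.fuse.pool", "pool", 0, numel + numel + 2 * c + c)
    led.linear(f"{name}.fuse.fc", ska.fuse.fc)
    d = ska.fuse.d
    led.add(f"{name}.fuse.bn", "bn", 2 * d, 2 * d)
    led.act(f"{name}.fuse.relu", d)
    if ska.use_sge:
        _sge_stats(led, f"{name}.sge_a", ska.sge_a, c, hw)
        _sge_stats(led, f"{name}.sge_b", ska.sge_b, c, hw)
    led.linear(f"{name}.select", ska.select.head)
    led.add(f"{name}.select.softmax", "softmax", 0, 4)
    # aggregation: two scales + one add per element
    led.add(f"{name}.aggregate", "agg", 0, 3 * numel)


def _cbam_stats(led: _Ledger, name: str, cbam: CBAM, c: int, hw: tuple):
    h, w = hw
    numel = c * h * w
    led.add(f"{name}.pool", "pool", 0, 2 * numel)  # global avg + max
    for tag in ("avg", "max"):
        led.linear(f"{name}.mlp1.{tag}", cbam.mlp1)
        led.linear(f"{name}.mlp2.{tag}", cbam.mlp2)
    # de-duplicate the shared MLP parameters (counted once, used twice)
    led.rows[-2].params = 0
    led.rows[-1].params = 0
    led.add(f"{name}.channel_gate", "gate", 0, c + numel)  # sigmoid + scale
    led.add(f"{name}.spatial_pool", "pool", 0, 2 * numel)
    ho, wo = led.conv(f"{name}.spatial_conv", cbam.spatial, hw)
    led.add(f"{name}.spatial_gate", "gate", 0, ho * wo + numel)


def _bottleneck_stats(led: _Ledger, name: str, blk: Bottleneck, hw: tuple) -> tuple:
    hw1 = led.conv(f"{name}.conv1", blk.conv1, hw)
    led.bn2d(f"{name}.bn1", blk.bn1, hw1)
    led.act(f"{name}.relu1", blk.conv1.out_ch * hw1[0] * hw1[1])
    hw2 = led.conv(f"{name}.conv2", blk.conv2, hw1)
    led.bn2d(f"{name}.bn2", blk.bn2, hw2)
    led.act(f"{name}.relu2", blk.conv2.out_ch * hw2[0] * hw2[1])
    hw3 = led.conv(f"{name}.conv3", blk.conv3, hw2)
    led.bn2d(f"{name}.bn3", blk.bn3, hw3)
    if isinstance(blk.attn, SGE):
        _sge_stats(led, f"{name}.sge", blk.attn, blk.out_ch, hw3)
    elif isinstance(blk.attn, SKAModule):
        _ska_stats(led, f"{name}.ska", blk.attn, blk.out_ch, hw3)
    if blk.down_conv is not None:
        hwd = led.conv(f"{name}.down.conv", blk.down_conv, hw)
        led.bn2d(f"{name}.down.bn", blk.down_bn, hwd)
    led.act(f"{name}.relu3", blk.out_ch * hw3[0] * hw3[1])
    return hw3


def count_multiply_adds(model: SKAResNet, input_size: int | None = None) -> ModelStats:
    """Analytic multiply-add (and parameter) ledger at a stated input size."""
    size = input_size or model.spec.input_size
    if size < 32:
        raise ValueError("input size must be at least 32")
    led = _Ledger()
    hw = led.conv("stem.conv", model.stem_conv, (size, size))
    led.bn2d("stem.bn", model.stem_bn, hw)
    c = model.stem_conv.out_ch
    led.act("stem.relu", c * hw[0] * hw[1])
    led.add("stem.maxpool", "pool", 0, c * hw[0] * hw[1])
    hw = _conv_out(hw, 3, 2, 1)
    for s, blocks in enumerate(model.stages):
        for b, blk in enumerate(blocks):
            hw = _bottleneck_stats(led, f"stage{s + 1}.block{b + 1}", blk, hw)
    cf = model.feature_channels
    led.add("head.gap", "pool", 0, cf * hw[0] * hw[1])
    led.linear("head.fc", model.fc)
    return ModelStats(params=sum(r.params for r in led.rows),
                      madds=sum(r.madds for r in led.rows),
                      per_layer=led.rows)


def count_parameters(model: SKAResNet) -> ModelStats:
    """Exact trainable-scalar count, itemized per named parameter."""
    rows = [LayerRow(name, "param", int(p.data.size), 0)
            for name, p in model.named_parameters()]
    return ModelStats(params=sum(r.params for r in rows), madds=0, per_layer=rows)


def variant_table(num_classes: int = 1000, input_size: int = 224) -> dict:
    """Params (M) and multiply-adds (G) for the four architecture variants."""
    out = {}
    for variant in ("resnet", "sge", "sk", "ska"):
        model = SKAResNet(NetSpec(variant=variant, num_classes=num_classes,
                                  input_size=input_size))
        st = count_multiply_adds(model, input_size)
        exact = model.num_parameters()
        if st.params != exact:
            raise AssertionError(
                f"ledger params {st.params} != model params {exact} for {variant}"
            )
        out[variant] = {"params": exact,
                        "params_millions": round(exact / 1e6, 2),
                        "madds": st.madds,
                        "gmadds": st.gmadds}
    return out
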