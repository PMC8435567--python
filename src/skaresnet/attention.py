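"""Selective-kernel attention (SKA), spatial group-wise enhance (SGE) and
the CBAM channel/spatial gating layer.

The SKA block runs three stages on a feature map ``X`` of shape
``(N, C, H, W)``:

*Divide* — two depthwise convolution branches with kernel sizes 3 and 5
(padding chosen so spatial size is preserved), each followed by batch
norm and ReLU, giving ``Y1`` and ``Y2`` with different receptive fields.

*Fuse* — a channel descriptor ``g = GAP(Y1 + Y2)`` is standardized per
sample across channels, compressed by group-averaging to a ``G``-length
vector, then passed through ``fc -> BN -> ReLU`` to the compact
descriptor ``g1``.  Each branch is independently enhanced by an SGE
gate (per-group similarity between spatial positions and the group's
global descriptor).

*Aggregation* — a linear head maps ``g1`` to two branch logits; softmax
across the branch axis yields selection weights ``(v1, v2)`` with
``v1 + v2 = 1``, and the output is ``X' = v1*Y1' + v2*Y2'``.

Selection weights are per-sample scalars: the softmax head keeps the
module within a ~0.6 M parameter overhead across a 50-layer network,
which is what makes the block "lightweight" relative to per-channel
selective-kernel variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .autodiff import Tensor, as_tensor, concat, global_avg_pool
from .layers import BatchNorm1d, BatchNorm2d, Conv2d, Linear, Module, Parameter

EPS_STANDARDIZE = 1e-5


@dataclass
class SKAConfig:
    """Hyper-parameters of the SKA block.

    ``reduction_r``/``d_min`` give the nominal descriptor width rule
    ``d = max(C / r, d_min)``; the realized fuse path compresses the
    standardized channel descriptor to ``groups`` dims and maps it to a
    fixed ``d_min``-dim descriptor, which is the parameter-budget-
    faithful reading of that rule.
    """

    kernel_a: int = 3
    kernel_b: int = 5
    reduction_r: int = 16
    d_min: int = 32
    groups: int = 32

    def __post_init__(self):
        if self.kernel_a % 2 == 0 or self.kernel_b % 2 == 0:
            raise ValueError("branch kernels must be odd")
        if self.reduction_r < 1 or self.d_min < 1 or self.groups < 1:
            raise ValueError("reduction_r, d_min and groups must be >= 1")

    def validate_channels(self, channels: int) -> None:
        if channels % self.groups:
            raise ValueError(
                f"groups={self.groups} must divide channel count {channels}"
            )


class FuseDescriptor(NamedTuple):
    g: np.ndarray   # (N, C) pooled + standardized channel descriptor
    g1: np.ndarray  # (N, d) compact descriptor after fc/BN/ReLU


class BranchWeights(NamedTuple):
    v1: np.ndarray
    v2: np.ndarray


# ---------------------------------------------------------------------------
# pure functional pieces
# ---------------------------------------------------------------------------

def channel_standardize(g, eps: float = EPS_STANDARDIZE):
    """Zero-mean/unit-std per sample across the channel axis (population std)."""
    g = as_tensor(g)
    mu = g.mean(axis=1, keepdims=True)
    var = ((g - mu) ** 2).mean(axis=1, keepdims=True)
    return (g - mu) / ((var + eps) ** 0.5)


def aggregate(y1p, y2p, v):
    """Eq. X' = v1*Y1' + v2*Y2' with per-sample weights v of shape (N, 2)."""
    unwrap = not isinstance(y1p, Tensor)
    y1p, y2p, v = as_tensor(y1p), as_tensor(y2p), as_tensor(v)
    if y1p.shape != y2p.shape:
        raise ValueError(f"branch shapes differ: {y1p.shape} vs {y2p.shape}")
    n = y1p.shape[0]
    v1 = v.take_rows(np.zeros(n, dtype=int)).reshape(n, 1, 1, 1)
    v2 = v.take_rows(np.ones(n, dtype=int)).reshape(n, 1, 1, 1)
    out = y1p * v1 + y2p * v2
    return out.numpy() if unwrap else out


def sge_enhance(y, gamma, beta, groups: int, eps: float = EPS_STANDARDIZE):
    """Spatial group-wise enhancement.

    Per channel group: similarity between each position's feature vector
    and the group's global-average descriptor, standardized over spatial
    positions, scaled/shifted by the learnable (gamma, beta), squashed by
    a sigmoid and applied as a multiplicative gate.
    """
    unwrap = not isinstance(y, Tensor)
    y = as_tensor(y)
    gamma, beta = as_tensor(gamma), as_tensor(beta)
    n, c, h, w = y.shape
    if c % groups:
        raise ValueError(f"groups={groups} must divide C={c}")
    yg = y.reshape(n, groups, c // groups, h, w)
    gdesc = yg.mean(axis=(3, 4), keepdims=True)
    sim = (yg * gdesc).sum(axis=2)                       # (N, G, H, W)
    mu = sim.mean(axis=(2, 3), keepdims=True)
    var = ((sim - mu) ** 2).mean(axis=(2, 3), keepdims=True)
    shat = (sim - mu) / ((var + eps) ** 0.5)
    gate = (shat * gamma.reshape(1, groups, 1, 1) + beta.reshape(1, groups, 1, 1)).sigmoid()
    out = (yg * gate.reshape(n, groups, 1, h, w)).reshape(n, c, h, w)
    return out.numpy() if unwrap else out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class BranchTransform(Module):
    """One Divide branch: depthwise conv (size-preserving) + BN + ReLU."""

    def __init__(self, channels: int, kernel: int, rng=None):
        super().__init__()
        self.channels, self.kernel = channels, kernel
        self.conv = Conv2d(channels, channels, kernel, stride=1,
                           padding=(kernel - 1) // 2, groups=channels, rng=rng)
        self.bn = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn.forward(self.conv.forward(x)).relu()


class SGE(Module):
    """Learnable (gamma, beta) wrapper around :func:`sge_enhance`.

    gamma initialized to 1 and beta to 0 so the similarity gate is
    active from the start.
    """

    def __init__(self, channels: int, groups: int):
        super().__init__()
        if channels % groups:
            raise ValueError(f"groups={groups} must divide C={channels}")
        self.channels, self.groups = channels, groups
        self.gamma = Parameter(np.ones(groups))
        self.beta = Parameter(np.zeros(groups))

    def forward(self, y: Tensor) -> Tensor:
        return sge_enhance(y, self.gamma, self.beta, self.groups)


class SKAFuse(Module):
    """Fuse stage: pooled descriptor -> standardize -> group-average ->
    fc -> BN -> ReLU, yielding the compact selector input ``g1``."""

    def __init__(self, channels: int, cfg: SKAConfig, rng=None):
        super().__init__()
        cfg.validate_channels(channels)
        self.channels, self.groups, self.d = channels, cfg.groups, cfg.d_min
        self.fc = Linear(cfg.groups, cfg.d_min, bias=False, rng=rng)
        self.bn = BatchNorm1d(cfg.d_min)

    def forward(self, y1: Tensor, y2: Tensor):
        if y1.shape != y2.shape:
            raise ValueError(f"branch shapes differ: {y1.shape} vs {y2.shape}")
        n, c = y1.shape[0], y1.shape[1]
        g = channel_standardize(global_avg_pool(y1 + y2))
        g_grp = g.reshape(n, self.groups, c // self.groups).mean(axis=2)
        g1 = self.bn.forward(self.fc.forward(g_grp)).relu()
        return g, g1


class SKASelect(Module):
    """Aggregation head: g1 -> 2 branch logits -> softmax over branches."""

    def __init__(self, d: int, rng=None):
        super().__init__()
        self.head = Linear(d, 2, bias=True, rng=rng)

    def forward(self, g1: Tensor) -> Tensor:
        return self.head.forward(g1).softmax(axis=1)


class SKAModule(Module):
    """Full Divide/Fuse/Aggregation block; ``use_sge=False`` gives the
    plain selective-kernel (SK) variant."""

    def __init__(self, channels: int, cfg: SKAConfig | None = None,
                 use_sge: bool = True, rng=None):
        super().__init__()
        cfg = cfg or SKAConfig()
        cfg.validate_channels(channels)
        self.channels, self.cfg, self.use_sge = channels, cfg, use_sge
        self.branch_a = BranchTransform(channels, cfg.kernel_a, rng=rng)
        self.branch_b = BranchTransform(channels, cfg.kernel_b, rng=rng)
        self.fuse = SKAFuse(channels, cfg, rng=rng)
        if use_sge:
            self.sge_a = SGE(channels, cfg.groups)
            self.sge_b = SGE(channels, cfg.groups)
        self.select = SKASelect(cfg.d_min, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.branch_a.forward(x)
        y2 = self.branch_b.forward(x)
        _, g1 = self.fuse.forward(y1, y2)
        if self.use_sge:
            y1 = self.sge_a.forward(y1)
            y2 = self.sge_b.forward(y2)
        v = self.select.forward(g1)
        return aggregate(y1, y2, v)


class CBAM(Module):
    """Channel gate then spatial gate, both sigmoid, both multiplicative.

    Channel gate: sigmoid(MLP(avg-pool F) + MLP(max-pool F)) with a shared
    two-layer MLP (reduction ``rho``).  Spatial gate: 7x7 convolution over
    the channel-wise [avg; max] maps.
    """

    def __init__(self, channels: int, rho: int = 16, spatial_kernel: int = 7, rng=None):
        super().__init__()
        if rho < 1:
            raise ValueError("rho must be >= 1")
        hidden = max(channels // rho, 1)
        self.channels, self.rho = channels, rho
        self.mlp1 = Linear(channels, hidden, bias=True, rng=rng)
        self.mlp2 = Linear(hidden, channels, bias=True, rng=rng)
        self.spatial = Conv2d(2, 1, spatial_kernel, stride=1,
                              padding=(spatial_kernel - 1) // 2, bias=True, rng=rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.mlp2.forward(self.mlp1.forward(v).relu())

    def forward(self, f: Tensor) -> Tensor:
        n, c, h, w = f.shape
        avg = global_avg_pool(f)
        mx = f.reshape(n, c, h * w).max(axis=2)
        mc = (self._mlp(avg) + self._mlp(mx)).sigmoid().reshape(n, c, 1, 1)
        fc_ = f * mc
        sp_avg = fc_.mean(axis=1, keepdims=True)
        sp_max = fc_.max(axis=1, keepdims=True)
        ms = self.spatial.forward(concat([sp_avg, sp_max], axis=1)).sigmoid()
        return fc_ * ms


# ---------------------------------------------------------------------------
# spec-surface functional wrappers (ndarray in / ndarray out)
# ---------------------------------------------------------------------------

def branch_transform(x, branch: BranchTransform) -> np.ndarray:
    return branch(np.asarray(x, dtype=np.float64))


def fuse_descriptor(y1, y2, fuse: SKAFuse) -> FuseDescriptor:
    g, g1 = fuse.forward(as_tensor(np.asarray(y1, dtype=np.float64)),
                         as_tensor(np.asarray(y2, dtype=np.float64)))
    return FuseDescriptor(g=g.numpy(), g1=g1.numpy())


def select_branch_weights(g1, select: SKASelect) -> BranchWeights:
    v = select(np.asarray(g1, dtype=np.float64))
    return BranchWeights(v1=v[:, 0], v2=v[:, 1])


def ska_module(x, module: SKAModule) -> np.ndarray:
    return module(np.asarray(x, dtype=np.float64))


def cbam_layer(f, cbam: CBAM) -> np.ndarray:
    return cbam(np.asarray(f, dtype=np.float64))
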