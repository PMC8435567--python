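"""Multi-scale heads and the KL prediction-matching regularizer.

Two auxiliary classifiers tap the backbone's stage-3 and stage-4 feature
maps (F3, F4).  Each map passes a CBAM layer, global average pooling and
its own fc layer to give a prediction distribution (P3 resp. P4); P is
the main head's distribution.  The regularizer sums directed KL terms
between pairs of these distributions:

    strategy "A + B"  =>  KL(B || A)   (A is encouraged to match B)

so the full strategy set {P3+P4, P+P4, P3+P} contributes
KL(P4||P3) + KL(P4||P) + KL(P||P3), each averaged over the mini-batch.

The classification term is the cross-entropy of the combined head
distribution against the one-hot label; by default the three
distributions are averaged so the argument stays a valid distribution
(``reduce="sum"`` restores the literal three-mass sum).  The total
objective is ``cls + alpha * msl`` with alpha defaulting to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .attention import CBAM
from .autodiff import Tensor, as_tensor, global_avg_pool
from .backbone import FeatureBundle, SKAResNet
from .layers import Linear, Module

EPS_LOG = 1e-8
ROW_TOL = 1e-6

STRATEGY_P3_P4 = "P3+P4"
STRATEGY_P_P4 = "P+P4"
STRATEGY_P3_P = "P3+P"
ALL_STRATEGIES = (STRATEGY_P3_P4, STRATEGY_P_P4, STRATEGY_P3_P)

#: the six strategy sets of the ablation grid
STRATEGY_SETS = (
    (STRATEGY_P_P4,),
    (STRATEGY_P3_P4,),
    (STRATEGY_P3_P,),
    (STRATEGY_P3_P4, STRATEGY_P_P4),
    (STRATEGY_P3_P4, STRATEGY_P3_P),
    (STRATEGY_P3_P4, STRATEGY_P_P4, STRATEGY_P3_P),
)


@dataclass
class MSLConfig:
    strategies: tuple = ALL_STRATEGIES
    alpha: float = 1.0
    epsilon: float = EPS_LOG

    def __post_init__(self):
        self.strategies = tuple(self.strategies)
        unknown = set(self.strategies) - set(ALL_STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0 < self.epsilon <= 1e-4):
            raise ValueError("epsilon must lie in (0, 1e-4]")


class LossValues(NamedTuple):
    cls: float
    msl: float
    total: float


def _validate_dist(p, name: str) -> Tensor:
    t = as_tensor(p)
    rows = t.data.sum(axis=1)
    if np.any(t.data < -ROW_TOL) or np.any(np.abs(rows - 1.0) > 1e-4):
        raise ValueError(f"{name} rows must be probability vectors summing to 1")
    return t


class MSLHead(Module):
    """CBAM-enhanced auxiliary classifiers over F3 and F4."""

    def __init__(self, model: SKAResNet, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c3, c4 = model.f3_channels, model.feature_channels
        self.num_classes = model.spec.num_classes
        self.cbam3 = CBAM(c3, rng=rng)
        self.cbam4 = CBAM(c4, rng=rng)
        self.fc3 = Linear(c3, self.num_classes, bias=True, rng=rng)
        self.fc4 = Linear(c4, self.num_classes, bias=True, rng=rng)

    def forward(self, bundle: FeatureBundle):
        return self.head_predictions(bundle)

    def head_predictions(self, bundle: FeatureBundle):
        """(P3, P4, P): auxiliary and main prediction distributions."""
        p3 = self.fc3.forward(global_avg_pool(self.cbam3.forward(bundle.F3))).softmax(axis=1)
        p4 = self.fc4.forward(global_avg_pool(self.cbam4.forward(bundle.F4))).softmax(axis=1)
        p = bundle.logits.softmax(axis=1)
        return p3, p4, p


def head_predictions(bundle: FeatureBundle, head: MSLHead):
    p3, p4, p = head.head_predictions(bundle)
    return p3.numpy(), p4.numpy(), p.numpy()


def kl_match(pa, pb, epsilon: float = EPS_LOG):
    """Batch-averaged KL(Pa || Pb) = (1/N) sum_i sum_j pa_ij log(pa_ij / pb_ij)."""
    unwrap = not isinstance(pa, Tensor)
    pa = _validate_dist(pa, "Pa")
    pb = _validate_dist(pb, "Pb")
    pa_f, pb_f = pa + epsilon, pb + epsilon
    kl = (pa * (pa_f.log() - pb_f.log())).sum(axis=1).mean()
    return float(kl.data) if unwrap else kl


def msl_loss(p3, p4, p, cfg: MSLConfig | None = None):
    """Sum of directed KL terms over the configured strategy set."""
    cfg = cfg or MSLConfig()
    unwrap = not isinstance(p3, Tensor)
    terms = {
        STRATEGY_P3_P4: lambda: kl_match(as_tensor(p4), as_tensor(p3), cfg.epsilon),
        STRATEGY_P_P4: lambda: kl_match(as_tensor(p4), as_tensor(p), cfg.epsilon),
        STRATEGY_P3_P: lambda: kl_match(as_tensor(p), as_tensor(p3), cfg.epsilon),
    }
    total = Tensor(0.0)
    for s in cfg.strategies:
        total = total + terms[s]()
    return float(total.data) if unwrap else total


def classification_loss(p3, p4, p, labels, epsilon: float = EPS_LOG,
                        reduce: str = "mean"):
    """Cross-entropy of the combined head distribution against the labels.

    ``reduce="mean"`` (default) uses (P3+P4+P)/3; ``reduce="sum"`` is the
    literal three-mass sum (whose cross-entropy can go negative at
    confident agreement and is provided for comparison only).
    """
    unwrap = not isinstance(p3, Tensor)
    p3 = _validate_dist(p3, "P3")
    p4 = _validate_dist(p4, "P4")
    p = _validate_dist(p, "P")
    labels = np.asarray(labels, dtype=int)
    c = p.shape[1]
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    combined = p3 + p4 + p
    if reduce == "mean":
        combined = combined * (1.0 / 3.0)
    elif reduce != "sum":
        raise ValueError("reduce must be 'mean' or 'sum'")
    loss = -((combined.take_rows(labels) + epsilon).log()).mean()
    return float(loss.data) if unwrap else loss


def total_loss(cls, msl, cfg: MSLConfig | None = None) -> "LossValues | Tensor":
    """total = cls + alpha * msl (Tensor in -> Tensor out for training)."""
    cfg = cfg or MSLConfig()
    if isinstance(cls, Tensor) or isinstance(msl, Tensor):
        return as_tensor(cls) + cfg.alpha * as_tensor(msl)
    if not (np.isfinite(cls) and np.isfinite(msl)):
        raise ValueError("loss components must be finite")
    return LossValues(cls=float(cls), msl=float(msl),
                      total=float(cls) + cfg.alpha * float(msl))


def combined_prediction(p3, p4, p, msl_enabled: bool = True) -> np.ndarray:
    """Inference-time distribution: mean of the three heads when the
    regularizer is active, the main head alone otherwise."""
    arr = lambda t: t.numpy() if isinstance(t, Tensor) else np.asarray(t)
    if msl_enabled:
        return (arr(p3) + arr(p4) + arr(p)) / 3.0
    return arr(p)
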