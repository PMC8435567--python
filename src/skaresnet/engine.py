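"""Training/evaluation loop, learning-rate schedule and activation maps.

The schedule is the step decay used for the 50-epoch runs: base rate
0.01 divided by 10 at floor(E/2) and floor(3E/4).  The optimizer is SGD
with momentum 0.9 and weight decay 1e-4 (the canonical residual-network
defaults).  Everything is seeded and single-device; two runs with the
same seed and config produce identical metric logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .autodiff import Tensor
from .backbone import NetSpec, SKAResNet, build_model, save_checkpoint
from .heads import (MSLConfig, MSLHead, classification_loss, combined_prediction,
                    msl_loss, total_loss)


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    base_lr: float = 0.01
    lr_decay_factor: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 1e-4
    input_scale: int = 224
    seed: int = 0
    msl: bool = True
    alpha: float = 1.0
    strategies: tuple | None = None   # None -> full strategy set
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.base_lr <= 0:
            raise ValueError("epochs, batch_size must be >= 1 and base_lr > 0")

    def msl_config(self) -> MSLConfig:
        kw = {"alpha": self.alpha}
        if self.strategies is not None:
            kw["strategies"] = self.strategies
        return MSLConfig(**kw)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """base_lr * factor^k, k = number of passed milestones {E//2, 3E//4}."""
    if not (0 <= epoch < cfg.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    milestones = (cfg.epochs // 2, (3 * cfg.epochs) // 4)
    k = sum(epoch >= m for m in milestones)
    return cfg.base_lr * cfg.lr_decay_factor**k


class SGD:
    """SGD with momentum and (coupled) weight decay."""

    def __init__(self, params, momentum: float = 0.9, weight_decay: float = 1e-4):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buffers = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, buf in zip(self.params, self.buffers):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= lr * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class ArrayDataset(NamedTuple):
    """In-memory split: images (n, 3, H, W), integer labels."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


@dataclass
class TrainHistory:
    steps: list = field(default_factory=list)    # per-iteration loss components
    epochs: list = field(default_factory=list)   # per-epoch summary rows

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.steps).to_csv(str(path).replace(".csv", "_steps.csv"),
                                        index=False)
        pd.DataFrame(self.epochs).to_csv(path, index=False)

    @property
    def final_test_top1(self) -> float:
        return self.epochs[-1]["test_top1"]

    @property
    def best_test_top1(self) -> float:
        return max(r["test_top1"] for r in self.epochs)


def _forward_losses(model: SKAResNet, head: MSLHead | None, xb, yb,
                    mcfg: MSLConfig, use_msl: bool):
    bundle = model.forward_features(xb)
    if use_msl and head is not None:
        p3, p4, p = head.head_predictions(bundle)
        cls = classification_loss(p3, p4, p, yb)
        msl = msl_loss(p3, p4, p, mcfg)
        tot = total_loss(cls, msl, mcfg)
        pred = combined_prediction(p3, p4, p, msl_enabled=True)
    else:
        p = bundle.logits.softmax(axis=1)
        cls = -((p.take_rows(yb) + 1e-8).log()).mean()
        msl = Tensor(0.0)
        tot = cls
        pred = p.numpy()
    return tot, float(cls.data), float(msl.data), pred


def train(spec: NetSpec, data: ArrayDataset, cfg: TrainConfig,
          checkpoint_path=None, verbose: bool = False):
    """Train a fresh model on an in-memory split.

    Returns ``(model, head, history)``; ``head`` is None when the
    multi-scale regularizer is disabled.  The best-test-top-1 model is
    checkpointed if a path is given.
    """
    if data.y_train.max() >= spec.num_classes or data.y_test.max() >= spec.num_classes:
        raise ValueError("labels exceed spec.num_classes")
    rng = np.random.default_rng(cfg.seed)
    model = build_model(spec, rng=rng)
    head = MSLHead(model, rng=rng) if cfg.msl else None
    mcfg = cfg.msl_config()
    params = model.parameters() + (head.parameters() if head else [])
    opt = SGD(params, cfg.momentum, cfg.weight_decay)
    history = TrainHistory()
    n = len(data.y_train)
    best = -1.0
    for epoch in range(cfg.epochs):
        lr = lr_at(epoch, cfg)
        model.train()
        if head:
            head.train()
        order = rng.permutation(n)
        ep_tot, ep_cls, ep_msl, correct, steps, seen = 0.0, 0.0, 0.0, 0, 0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs at least two samples
            xb, yb = data.X_train[idx], data.y_train[idx]
            tot, cls_v, msl_v, pred = _forward_losses(model, head, xb, yb,
                                                      mcfg, cfg.msl)
            if not np.isfinite(tot.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {steps} (cls={cls_v}, msl={msl_v})"
                )
            opt.zero_grad()
            tot.backward()
            opt.step(lr)
            history.steps.append({"epoch": epoch, "step": steps, "cls": cls_v,
                                  "msl": msl_v, "total": float(tot.data),
                                  "lr": lr})
            ep_tot += float(tot.data) * len(idx)
            ep_cls += cls_v * len(idx)
            ep_msl += msl_v * len(idx)
            correct += int((pred.argmax(axis=1) == yb).sum())
            steps += 1
            seen += len(idx)
        test_top1 = evaluate(model, data.X_test, data.y_test, cfg, head=head)
        row = {"epoch": epoch, "lr": lr,
               "train_loss": ep_tot / max(seen, 1),
               "train_cls": ep_cls / max(seen, 1),
               "train_msl": ep_msl / max(seen, 1),
               "train_top1": 100.0 * correct / max(seen, 1),
               "test_top1": test_top1}
        history.epochs.append(row)
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.4g}  loss {row['train_loss']:.4f}  "
                  f"test top-1 {test_top1:.2f}%")
        if checkpoint_path is not None and test_top1 > best:
            best = test_top1
            save_checkpoint(model, checkpoint_path, head=head)
    return model, head, history


def evaluate(model: SKAResNet, X, y, cfg: TrainConfig | None = None,
             head: MSLHead | None = None, batch_size: int = 64) -> float:
    """Top-1 accuracy (percent) of argmax predictions on a test split."""
    if len(y) == 0:
        raise ValueError("empty evaluation split")
    model.eval()
    if head:
        head.eval()
    correct = 0
    for start in range(0, len(y), batch_size):
        xb = X[start:start + batch_size]
        bundle = model.forward_features(xb)
        if head is not None:
            p3, p4, p = head.head_predictions(bundle)
            pred = combined_prediction(p3, p4, p, msl_enabled=True)
        else:
            pred = bundle.logits.softmax(axis=1).numpy()
        correct += int((pred.argmax(axis=1) == y[start:start + batch_size]).sum())
    return 100.0 * correct / len(y)


@dataclass
class ActivationMap:
    heatmap: np.ndarray       # (H, W) in [0, 1], max 1 unless degenerate
    score: float              # softmax probability of the target class
    target_class: int
    degenerate: bool = False


def activation_map(model: SKAResNet, image, target_class: int | None = None) -> ActivationMap:
    """Gradient-weighted class activation map over the last conv outputs.

    Channel weights are the spatially averaged gradients of the target
    class score w.r.t. F4; the weighted sum is rectified, bilinearly
    upsampled to the input size and min-max normalized.
    """
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    model.eval()
    bundle = model.forward_features(x)
    probs = bundle.logits.softmax(axis=1)
    if target_class is None:
        target_class = int(np.argmax(probs.data[0]))
    score = float(probs.data[0, target_class])
    grad_seed = np.zeros_like(bundle.logits.data)
    grad_seed[0, target_class] = 1.0
    bundle.logits.backward(grad_seed)
    grads = bundle.F4.grad[0]                     # (C, h, w)
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * bundle.F4.data[0]).sum(axis=0), 0.0)
    h, w = x.shape[2], x.shape[3]
    cam = ndimage.zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return ActivationMap(np.zeros((h, w)), score, target_class, degenerate=True)
    return ActivationMap((cam - lo) / (hi - lo), score, target_class)


# ---------------------------------------------------------------------------
# ablation grids
# ---------------------------------------------------------------------------

BATCH_GRID = (16, 32, 64, 128)
SCALE_GRID = (112, 224, 336, 448)


def ablation_configs(base: TrainConfig, which: str):
    """Runnable config grids for the batch / scale / strategy ablations."""
    from .heads import STRATEGY_SETS

    if which == "batch":
        return [replace(base, batch_size=b) for b in BATCH_GRID]
    if which == "scale":
        return [replace(base, input_scale=s) for s in SCALE_GRID]
    if which == "strategy":
        return [replace(base, strategies=s) for s in STRATEGY_SETS]
    raise ValueError("which must be 'batch', 'scale' or 'strategy'")
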