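"""Scikit-learn estimator interface to the attention classifiers.

``SKAResNetClassifier`` wraps architecture construction, the training
loop and the multi-scale-regularized objective behind the standard
``fit`` / ``predict`` / ``predict_proba`` / ``score`` surface, so the
model composes with sklearn pipelines and model selection.  Input is a
``(n, 3, H, W)`` image array (values on any consistent scale; callers
normally pass the output of :func:`skaresnet.synthetic.preprocess`).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .backbone import NetSpec
from .engine import ArrayDataset, TrainConfig, evaluate, train
from .heads import combined_prediction


class SKAResNetClassifier(ClassifierMixin, BaseEstimator):
    """Fine-grained image classifier with selective-kernel attention.

    Parameters
    ----------
    variant : {"resnet", "sge", "sk", "ska"}
        Backbone flavor: plain bottleneck, SGE-gated, selective-kernel,
        or selective-kernel attention (SK + per-branch SGE).
    stage_blocks : tuple of 4 ints
        Bottleneck count per stage; (3, 4, 6, 3) is the 50-layer network.
    width_divisor : int
        Divides every channel width (and the group count) for desk-scale
        models; 1 is the published width.
    msl : bool
        Enable the CBAM-enhanced auxiliary heads and the KL
        prediction-matching regularizer.
    strategies : tuple or None
        KL strategy subset; None means all three directed terms.
    alpha : float
        Weight of the regularizer in the total objective.
    epochs, batch_size, base_lr, momentum, weight_decay, seed
        Optimization knobs (SGD, step decay at E//2 and 3E//4).
    validation_fraction : float
        Stratified tail of the training data held out to track test
        top-1 during fit (the epoch log needs an eval split).
    """

    def __init__(self, variant="ska", stage_blocks=(3, 4, 6, 3),
                 width_divisor=1, msl=True, strategies=None, alpha=1.0,
                 epochs=10, batch_size=16, base_lr=0.02, momentum=0.9,
                 weight_decay=1e-4, seed=0, validation_fraction=0.2,
                 verbose=False):
        self.variant = variant
        self.stage_blocks = stage_blocks
        self.width_divisor = width_divisor
        self.msl = msl
        self.strategies = strategies
        self.alpha = alpha
        self.epochs = epochs
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.seed = seed
        self.validation_fraction = validation_fraction
        self.verbose = verbose

    # -- helpers ---------------------------------------------------------
    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4 or X.shape[1] != 3:
            raise ValueError(f"X must have shape (n, 3, H, W); got {X.shape}")
        return X

    def _train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           base_lr=self.base_lr, momentum=self.momentum,
                           weight_decay=self.weight_decay, seed=self.seed,
                           msl=self.msl, alpha=self.alpha,
                           strategies=self.strategies)

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.seed)
        n = len(y_enc)
        # stratified holdout for the per-epoch test-top-1 column
        holdout = np.zeros(n, dtype=bool)
        for c in range(len(self.classes_)):
            idx = np.flatnonzero(y_enc == c)
            k = max(int(round(self.validation_fraction * len(idx))), 1)
            holdout[rng.permutation(idx)[:k]] = True
        if holdout.all():
            raise ValueError("validation_fraction leaves no training data")
        data = ArrayDataset(X[~holdout], y_enc[~holdout], X[holdout], y_enc[holdout])
        spec = NetSpec(variant=self.variant, stage_blocks=tuple(self.stage_blocks),
                       num_classes=len(self.classes_),
                       input_size=X.shape[2], width_divisor=self.width_divisor)
        self.model_, self.head_, self.history_ = train(
            spec, data, self._train_config(), verbose=self.verbose)
        self.n_features_in_ = X.shape[1] * X.shape[2] * X.shape[3]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        self.model_.eval()
        if self.head_:
            self.head_.eval()
        out = []
        for start in range(0, len(X), 64):
            bundle = self.model_.forward_features(X[start:start + 64])
            if self.head_ is not None:
                p3, p4, p = self.head_.head_predictions(bundle)
                out.append(combined_prediction(p3, p4, p, msl_enabled=True))
            else:
                out.append(bundle.logits.softmax(axis=1).numpy())
        return np.concatenate(out, axis=0)

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y):
        """Top-1 accuracy as a fraction (sklearn convention)."""
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def top1_accuracy(self, X, y) -> float:
        """Top-1 accuracy as a percentage."""
        return 100.0 * self.score(X, y)
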