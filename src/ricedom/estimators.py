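"""scikit-learn-style estimators over the segmentation and classification
pipeline.

`IRBOAClassifier` wraps plan construction, channel standardization and
the training loop behind the familiar fit/predict surface, so the model
composes with sklearn model selection. `GrainSegmenter` exposes scan ->
crop extraction as a transformer.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import arch, nn
from .dataset import ChannelStats, center_crop
from .preprocess import PreprocessConfig
from .segment import segment_image
from .train import HyperParams, predict_logits, train_model

__all__ = ["IRBOAClassifier", "GrainSegmenter"]


class IRBOAClassifier(ClassifierMixin, BaseEstimator):
    """Multi-scale Inception/ResNet image classifier.

    Parameters mirror the training recipe: optimizer ('SGD' or 'Adam'),
    initial learning rate, step-decay interval and factor, L2 weight
    decay, batch size and epoch count; `width_mult` scales every layer's
    kernel count for reduced-width runs and `input_size` sets the square
    input side. X is an (n, H, W, 3) uint8/float array of grain crops;
    channel statistics are computed on the fit data and reused at predict
    time.

    Fitted attributes: `classes_`, `model_`, `plan_`, `stats_`,
    `history_`.
    """

    def __init__(self, width_mult: float = 1.0, input_size: int = 224,
                 optimizer: str = "Adam", learning_rate: float = 0.00019,
                 step_size: int = 15, gamma: float = 0.085,
                 weight_decay: float = 0.0002, batch_size: int = 64,
                 epochs: int = 100, literal_table: bool = False,
                 stop_at_val_acc: float | None = None,
                 validation_fraction: float = 0.0, random_state: int = 0):
        self.width_mult = width_mult
        self.input_size = input_size
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.step_size = step_size
        self.gamma = gamma
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.literal_table = literal_table
        self.stop_at_val_acc = stop_at_val_acc
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _prepare(self, X: np.ndarray, stats: ChannelStats | None):
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (n, H, W, 3) color images")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            X = np.stack([center_crop(x, self.input_size) for x in X])
        scaled = X.astype(np.float32) / 255.0
        if stats is None:
            flat = scaled.reshape(-1, 3)
            stats = ChannelStats(flat.mean(axis=0), flat.std(axis=0))
        out = (scaled - stats.mean.astype(np.float32)) / stats.std.astype(np.float32)
        return out.transpose(0, 3, 1, 2).copy(), stats

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        Xp, self.stats_ = self._prepare(X, None)
        val = None
        rng = np.random.default_rng(self.random_state)
        if X_val is not None:
            Xv, _ = self._prepare(X_val, self.stats_)
            yv = np.searchsorted(self.classes_, np.asarray(y_val))
            val = (Xv, yv)
        elif self.validation_fraction > 0:
            n_val = int(round(self.validation_fraction * len(Xp)))
            order = rng.permutation(len(Xp))
            val = (Xp[order[:n_val]], y_idx[order[:n_val]])
            Xp, y_idx = Xp[order[n_val:]], y_idx[order[n_val:]]
        self.plan_ = arch.default_plan(
            num_classes=len(self.classes_), width_mult=self.width_mult,
            input_size=self.input_size, literal_table=self.literal_table,
        )
        self.model_ = arch.build_model(self.plan_, rng=rng)
        hp = HyperParams(
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            step_size=self.step_size, gamma=self.gamma,
            weight_decay=self.weight_decay, batch_size=self.batch_size,
            epochs=self.epochs,
        )
        self.history_, best = train_model(
            self.model_, Xp, y_idx, hp, rng=rng,
            X_val=val[0] if val else None, y_val=val[1] if val else None,
            stop_at_val_acc=self.stop_at_val_acc,
        )
        if val is not None:
            self.model_.load_state_dict(best["state"])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        Xp, _ = self._prepare(X, self.stats_)
        return predict_logits(self.model_, Xp, self.batch_size)

    def predict_proba(self, X):
        return nn.softmax(self.decision_function(X))

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[scores.argmax(axis=1)]


class GrainSegmenter(TransformerMixin, BaseEstimator):
    """Scan-to-crops transformer: preprocessing, contour detection,
    minimum-area boxes, upright crop extraction.

    `transform` maps a list of color scans to a list of per-scan
    `GrainCrop` lists. Stateless; `fit` only validates parameters."""

    def __init__(self, median_kernel: int = 3, threshold: int = 100,
                 open_kernel: int = 3, close_kernel: int = 3,
                 min_area_px: int = 200, margin: int = 5, background: int = 0):
        self.median_kernel = median_kernel
        self.threshold = threshold
        self.open_kernel = open_kernel
        self.close_kernel = close_kernel
        self.min_area_px = min_area_px
        self.margin = margin
        self.background = background

    def _cfg(self) -> PreprocessConfig:
        return PreprocessConfig(self.median_kernel, self.threshold,
                                self.open_kernel, self.close_kernel)

    def fit(self, X=None, y=None):
        self._cfg()
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        cfg = self._cfg()
        return [segment_image(img, cfg, self.min_area_px, self.margin,
                              self.background) for img in X]
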