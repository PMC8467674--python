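"""scikit-learn-style estimator facade over the segmentation pipeline.

``UNetSegmenter`` wraps architecture construction, he_normal
initialization, Adam training and thresholded prediction behind the usual
fit/predict/score surface, so the models compose with sklearn model
selection and pipelines. ``X`` is an array of grayscale images
``(n, H, W)`` with values in [0, 1]; ``y`` is the matching stack of binary
masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .architectures import BackboneConfig, UNetModel, build_variant
from .evaluation import dice, UndefinedMetricError
from .training import TrainConfig, TrainResult, train


class UNetSegmenter(BaseEstimator):
    """Binary lesion segmenter: plain U-Net, U-Net + Res Path, or RCU-Net.

    Parameters
    ----------
    variant : {"unet", "unet_respath", "rcunet"}
    base_filters : width of the first encoder level; deeper levels double it
        (the published model uses 64; smaller values give desk-scale models).
    epochs, batch_size, learning_rate, beta1, beta2 : Adam training setup.
    threshold : probability cutoff for binarizing the sigmoid output.
    random_state : seed controlling initialization and batch shuffling.

    Attributes (after fit)
    ----------------------
    model_ : the trained network
    config_ : the backbone configuration actually built
    history_ : per-epoch mean training loss
    """

    def __init__(self, variant: str = "rcunet", base_filters: int = 64,
                 epochs: int = 120, batch_size: int = 4,
                 learning_rate: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, threshold: float = 0.5,
                 loss_reduction: str = "sum", random_state: int = 0):
        self.variant = variant
        self.base_filters = base_filters
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.threshold = threshold
        self.loss_reduction = loss_reduction
        self.random_state = random_state

    def _validate_images(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_images, H, W), got {X.shape}")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        if y is not None:
            y = np.asarray(y)
            if y.shape != X.shape:
                raise ValueError(
                    f"mask stack {y.shape} does not match images {X.shape}")
            y = y > (127 if y.max() > 1 else 0)
            return X, y
        return X

    def fit(self, X, y):
        X, y = self._validate_images(X, y)
        f0 = self.base_filters
        cfg = BackboneConfig(
            input_extent=X.shape[1:],
            encoder_filters=tuple(f0 * 2 ** i for i in range(5)))
        self.config_ = cfg
        self.model_: UNetModel = build_variant(self.variant, cfg)
        tc = TrainConfig(learning_rate=self.learning_rate, beta1=self.beta1,
                         beta2=self.beta2, batch_size=self.batch_size,
                         epochs=self.epochs, seed=self.random_state,
                         loss_reduction=self.loss_reduction)
        result: TrainResult = train(self.model_, list(zip(X, y)), tc)
        self.history_ = result.history
        self.n_steps_ = result.steps
        return self

    def predict_proba(self, X, batch_size: int = 8) -> np.ndarray:
        """Per-pixel lesion probabilities, shape (n, H, W)."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted yet")
        X = self._validate_images(X)
        self.model_.eval()
        out = [self.model_(X[i:i + batch_size, None])[:, 0]
               for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Binary masks: probability >= threshold, shape (n, H, W)."""
        return self.predict_proba(X) >= self.threshold

    def score(self, X, y) -> float:
        """Mean Dice coefficient over the defined pairs."""
        X, y = self._validate_images(X, y)
        preds = self.predict(X)
        scores = []
        for gt, sr in zip(y, preds):
            try:
                scores.append(dice(gt, sr))
            except UndefinedMetricError:
                pass
        if not scores:
            raise UndefinedMetricError("Dice undefined on every pair")
        return float(np.mean(scores))
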