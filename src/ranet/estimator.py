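"""Scikit-learn-style estimator wrapping the whole pipeline.

``RaNetSegmenter`` takes stacks of 2-D slices ``X`` of shape (n, H, W)
and binary masks ``y`` of the same shape, trains the attention
encoder-decoder under the hybrid loss, and predicts binary masks (or
probability maps, or Monte-Carlo-dropout uncertainty). It follows the
estimator contract — ``get_params``/``set_params``, fitted attributes
with a trailing underscore, ``score`` — so it composes with sklearn
model selection.

Example
-------
>>> from ranet.phantom import PhantomParams, generate_dataset
>>> import numpy as np
>>> splits = generate_dataset(10, PhantomParams.small(64), seed=0)
>>> X = np.stack([p.image.pixels for p in splits["train"]])
>>> y = np.stack([p.mask.labels for p in splits["train"]])
>>> seg = RaNetSegmenter(max_epochs=2, validation_fraction=0.25)
>>> seg.fit(X, y).predict(X).shape
(7, 64, 64)
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .encoder import EncoderConfig
from .losses import LossWeights
from .model import RaNet
from .msaf import MSAFConfig
from .training import (TrainConfig, evaluate, fit_model, mc_dropout_predict,
                    predict_masks, predict_proba)


class RaNetSegmenter(BaseEstimator):
    """Attention encoder-decoder segmenter with a hybrid boundary-aware loss.

    Parameters
    ----------
    preset : {"thin", "paper"}
        "thin" is the CPU-scale architecture (widths /8, short stages);
        "paper" the full ResNet-50-width backbone for 256x256 inputs.
    dilation_rate : int
        Dilation of the stage-4 second-block convolution.
    keep_prob : float
        Dropout KEEP probability after each encoder stage.
    lambda_dice, lambda_wce, lambda_boundary : float
        Hybrid-loss term weights.
    epsilon : float
        Dice smoothing constant.
    class_weight_mode : {"auto", "fixed"}
        "auto" sets the cross-entropy foreground weight to the
        background/foreground pixel ratio of each mask.
    validation_fraction : float
        Held-out share of the training stack used for early stopping and
        checkpoint selection when no explicit validation set is passed;
        0 monitors the training data itself.
    max_steps : int or None
        Optional cap on total optimiser steps (useful for quick runs).
    random_state : int
        Seeds initialisation, shuffling and dropout.
    """

    def __init__(self, preset: str = "thin", dilation_rate: int = 2,
                 keep_prob: float = 0.5, msaf_transition: str = "prelu",
                 msaf_on_deepest: bool = True,
                 lambda_dice: float = 1.0, lambda_wce: float = 1.0,
                 lambda_boundary: float = 1.0, epsilon: float = 1.0,
                 class_weight_mode: str = "auto", class_weight: float = 1.0,
                 wce_mode: str = "foreground_weighted",
                 boundary_normalize: bool = True,
                 batch_size: int = 8, learning_rate: float = 1e-3,
                 max_epochs: int = 200, early_stopping_patience: int = 20,
                 scheduler_factor: float = 0.1, scheduler_patience: int = 10,
                 max_steps: int | None = None,
                 validation_fraction: float = 0.2,
                 threshold: float = 0.5, random_state: int = 0):
        self.preset = preset
        self.dilation_rate = dilation_rate
        self.keep_prob = keep_prob
        self.msaf_transition = msaf_transition
        self.msaf_on_deepest = msaf_on_deepest
        self.lambda_dice = lambda_dice
        self.lambda_wce = lambda_wce
        self.lambda_boundary = lambda_boundary
        self.epsilon = epsilon
        self.class_weight_mode = class_weight_mode
        self.class_weight = class_weight
        self.wce_mode = wce_mode
        self.boundary_normalize = boundary_normalize
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.early_stopping_patience = early_stopping_patience
        self.scheduler_factor = scheduler_factor
        self.scheduler_patience = scheduler_patience
        self.max_steps = max_steps
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.random_state = random_state

    # -- construction helpers -----------------------------------------
    def _build_model(self) -> RaNet:
        if self.preset == "thin":
            enc = EncoderConfig.thin(dilation_rate=self.dilation_rate,
                                     keep_prob=self.keep_prob)
        elif self.preset == "paper":
            enc = EncoderConfig(dilation_rate=self.dilation_rate,
                                keep_prob=self.keep_prob)
        else:
            raise ValueError(f"unknown preset {self.preset!r}")
        msaf = MSAFConfig(transition_activation=self.msaf_transition,
                          apply_to_deepest=self.msaf_on_deepest)
        return RaNet(enc, msaf, seed=self.random_state)

    def _loss_weights(self) -> LossWeights:
        return LossWeights(
            lambda_dice=self.lambda_dice, lambda_wce=self.lambda_wce,
            lambda_boundary=self.lambda_boundary, epsilon=self.epsilon,
            class_weight_mode=self.class_weight_mode,
            class_weight=self.class_weight, wce_mode=self.wce_mode,
            boundary_normalize=self.boundary_normalize)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            early_stopping_patience=self.early_stopping_patience,
            scheduler_factor=self.scheduler_factor,
            scheduler_patience=self.scheduler_patience,
            max_steps=self.max_steps, threshold=self.threshold,
            seed=self.random_state)

    # -- estimator API -------------------------------------------------
    def fit(self, X, y, validation_data=None):
        """Train on (n, H, W) slices and masks.

        ``validation_data=(X_val, y_val)`` overrides the internal
        ``validation_fraction`` split.
        """
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X and y must be matching (n, H, W) stacks")
        if validation_data is not None:
            Xt, yt = X, y
            Xv, yv = validation_data
        elif self.validation_fraction > 0:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(X))
            n_val = max(1, round(len(X) * self.validation_fraction))
            if n_val >= len(X):
                raise ValueError("validation_fraction leaves no training data")
            val_idx, tr_idx = order[:n_val], order[n_val:]
            Xt, yt, Xv, yv = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
        else:
            Xt, yt, Xv, yv = X, y, X, y

        self.model_ = self._build_model()
        self.history_ = fit_model(self.model_, Xt, yt, Xv, yv,
                                  self._train_config(), self._loss_weights())
        self.n_iter_ = len(self.history_.epochs)
        self.best_epoch_ = self.history_.best_epoch
        self.input_shape_ = X.shape[1:]
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("this RaNetSegmenter is not fitted yet")

    def predict(self, X) -> np.ndarray:
        """Binary masks of shape (n, H, W)."""
        self._check_fitted()
        return predict_masks(self.model_, X, threshold=self.threshold,
                             batch_size=self.batch_size)

    def predict_proba(self, X) -> np.ndarray:
        """Foreground probability maps of shape (n, H, W)."""
        self._check_fitted()
        return predict_proba(self.model_, X, batch_size=self.batch_size)

    def predict_uncertainty(self, image, T: int = 20, seed: int = 0):
        """Monte-Carlo-dropout mean probability and per-pixel variance
        for one slice."""
        self._check_fitted()
        return mc_dropout_predict(self.model_, image, T=T, seed=seed)

    def score(self, X, y) -> float:
        """Mean Dice similarity over the stack."""
        self._check_fitted()
        report = evaluate(self.model_, X, y, threshold=self.threshold,
                          batch_size=self.batch_size)
        return report.mean("dsc")

    def evaluate(self, X, y):
        """Full metrics report (DSC, IoU, accuracy, sensitivity,
        specificity; per item and aggregated)."""
        self._check_fitted()
        return evaluate(self.model_, X, y, threshold=self.threshold,
                        batch_size=self.batch_size)

    # -- persistence ---------------------------------------------------
    def save_checkpoint(self, path):
        self._check_fitted()
        self.model_.save_checkpoint(path)
        return path

    def load_checkpoint(self, path):
        """Attach weights from a checkpoint (architecture must match the
        current parameters)."""
        self.model_ = self._build_model()
        self.model_.load_checkpoint(path)
        return self
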