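"""Scikit-learn-style estimator facade over the segmentation pipeline.

``VolumeSegmenter`` wraps model construction, training and sliding-window
inference behind the familiar ``fit`` / ``predict`` / ``score`` surface so
the pipeline composes with sklearn model-selection utilities.  ``X`` is a
list of :class:`~volseg.io.Volume` (or ``(H, W, D, C)`` arrays) and ``y`` a
list of :class:`~volseg.io.LabelMap` (or integer arrays).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .decoder import SegmentationResult
from .encoder import EncoderConfig
from .io import LabelMap, Volume
from .metrics import evaluate
from .model import ModelConfig, SegmentationModel
from .runtime import AugmentParams, TrainConfig, sliding_window_predict, train

__all__ = ["VolumeSegmenter"]


def _as_volume(x) -> Volume:
    return x if isinstance(x, Volume) else Volume(data=np.asarray(x))


def _as_labelmap(y, num_classes) -> LabelMap:
    if isinstance(y, LabelMap):
        return y
    return LabelMap(labels=np.asarray(y), num_classes=num_classes)


class VolumeSegmenter(BaseEstimator):
    """Fit a Fourier-mixing encoder–decoder segmenter on labelled volumes.

    Parameters mirror the encoder/training configuration; fitted state
    lives in ``model_`` and ``history_``.

    Examples
    --------
    >>> seg = VolumeSegmenter(stage_channels=(8, 16, 32, 64), max_epochs=5)
    >>> seg.fit([vol.data for vol in vols], [lm.labels for lm in lms])
    >>> labels = seg.predict([vols[0].data])[0]
    """

    def __init__(self, num_classes: int = 2, in_channels: int = 1,
                 patch_size: int = 2,
                 stage_channels: tuple[int, ...] = (48, 96, 192, 384),
                 blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2),
                 heads: tuple[int, ...] = (3, 6, 12, 24),
                 mixing_mode: str = "afno_3d",
                 base_input_shape: tuple[int, int, int] = (64, 64, 64),
                 learning_rate: float = 1e-4, weight_decay: float = 0.01,
                 max_epochs: int = 150, max_steps: int | None = None,
                 early_stop_patience: int = 20, batch_size: int = 2,
                 augment: bool = True, seed: int = 0,
                 window: tuple[int, int, int] | None = (64, 64, 64),
                 overlap: float = 0.5):
        self.num_classes = num_classes
        self.in_channels = in_channels
        self.patch_size = patch_size
        self.stage_channels = stage_channels
        self.blocks_per_stage = blocks_per_stage
        self.heads = heads
        self.mixing_mode = mixing_mode
        self.base_input_shape = base_input_shape
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.max_steps = max_steps
        self.early_stop_patience = early_stop_patience
        self.batch_size = batch_size
        self.augment = augment
        self.seed = seed
        self.window = window
        self.overlap = overlap

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y):
        enc = EncoderConfig(
            patch_size=self.patch_size,
            stage_channels=tuple(self.stage_channels),
            blocks_per_stage=tuple(self.blocks_per_stage),
            heads=tuple(self.heads),
            mixing_mode=self.mixing_mode,
            base_input_shape=tuple(self.base_input_shape),
        )
        cfg = ModelConfig(encoder=enc, in_channels=self.in_channels,
                          num_classes=self.num_classes, init_seed=self.seed)
        self.model_ = SegmentationModel(cfg)
        dataset = [(_as_volume(x), _as_labelmap(t, self.num_classes))
                   for x, t in zip(X, y)]
        tc = TrainConfig(
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            max_epochs=self.max_epochs, max_steps=self.max_steps,
            early_stop_patience=self.early_stop_patience,
            batch_size=self.batch_size, seed=self.seed,
            augment=AugmentParams() if self.augment else None,
        )
        self.model_, self.history_ = train(self.model_, dataset, tc)
        return self

    def _predict_one(self, x) -> SegmentationResult:
        vol = _as_volume(x)
        if self.window is not None and any(
                s > w for s, w in zip(vol.spatial_shape, self.window)):
            return sliding_window_predict(self.model_, vol,
                                          window=self.window,
                                          overlap=self.overlap)
        return self.model_.predict(vol)

    def predict(self, X) -> list[np.ndarray]:
        """Per-volume argmax label arrays."""
        self._check_fitted()
        return [self._predict_one(x).labels.labels for x in X]

    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-volume ``(H, W, D, K)`` probability arrays."""
        self._check_fitted()
        return [self._predict_one(x).probabilities for x in X]

    def score(self, X, y) -> float:
        """Mean foreground Dice over the given volumes."""
        self._check_fitted()
        dices = []
        for x, t in zip(X, y):
            lm = _as_labelmap(t, self.num_classes)
            pred = self._predict_one(x).labels
            dices.append(evaluate(pred, lm).mean_dice)
        return float(np.mean(dices))

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
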