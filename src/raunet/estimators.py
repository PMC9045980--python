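"""scikit-learn style estimators wrapping the segmentation pipeline.

``UNetSegmenter`` fits one network (plain U-Net or the Recurrent Attention
U-Net) to slices and binary masks; ``TwoStageSegmenter`` fits the full
ROI-then-tumor cascade.  Both follow the sklearn contract: constructor
arguments are hyperparameters stored verbatim, ``fit`` learns and sets
trailing-underscore attributes, and ``get_params``/``set_params``/``clone``
work, so the estimators compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .evaluation import confusion_counts
from .nets import NetworkSpec, forward
from .objectives import TverskyConfig
from .phantom import CaseRecord, zscore_normalize
from .pipeline import (
    Checkpoint,
    RoiApplication,
    TrainConfig,
    apply_roi,
    predict_case,
    train_stage,
)

__all__ = ["TwoStageSegmenter", "UNetSegmenter"]


def _check_images(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 3:
        raise ValueError(f"X must be (n_slices, H, W), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _check_masks(y, X) -> np.ndarray:
    y = np.asarray(y)
    if y.shape != X.shape:
        raise ValueError(f"y shape {y.shape} does not match X shape {X.shape}")
    if not np.all(np.isin(np.unique(y), (0, 1))):
        raise ValueError("y must be binary {0,1} masks")
    return y.astype(np.uint8)


def _as_cases(X, masks_list, slices_per_case=1):
    """Wrap slice arrays into single-slice CaseRecords for the pipeline."""
    cases = []
    for i in range(X.shape[0]):
        roi = masks_list[0][i] if masks_list[0] is not None else np.ones_like(masks_list[1][i])
        tum = masks_list[1][i] if masks_list[1] is not None else np.zeros_like(roi, dtype=np.uint8)
        tum = (tum & roi).astype(np.uint8)
        cases.append(
            CaseRecord(
                case_id=f"sample_{i:05d}",
                slices=[X[i]],
                roi_masks=[roi.astype(np.uint8)],
                tumor_masks=[tum],
            )
        )
    return cases


def _dice(pred, gt) -> float:
    c = confusion_counts(pred, gt)
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 1.0


class UNetSegmenter(BaseEstimator):
    """Single-network semantic segmenter with a fit/predict interface.

    Parameters
    ----------
    variant:
        "unet" (conv-block decoder) or "ra_unet" (dense residual encoder
        modules + recurrent attention decoder).
    base_channels:
        Width of the first encoder stage; the ladder is base * (1,2,4,8,16).
    alpha, beta:
        Tversky weights for false positives / false negatives.
    learning_rate, epochs, batch_size, lookahead_k, lookahead_alpha:
        Optimization protocol (Adam wrapped in Lookahead).
    random_state:
        Seeds initialization and data order; fits are reproducible.
    """

    def __init__(
        self,
        variant: str = "ra_unet",
        base_channels: int = 8,
        attention_iterations: int = 2,
        alpha: float = 0.3,
        beta: float = 0.7,
        learning_rate: float = 1e-3,
        epochs: int = 30,
        batch_size: int = 4,
        lookahead_k: int = 5,
        lookahead_alpha: float = 0.5,
        random_state: int = 0,
    ):
        self.variant = variant
        self.base_channels = base_channels
        self.attention_iterations = attention_iterations
        self.alpha = alpha
        self.beta = beta
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.lookahead_k = lookahead_k
        self.lookahead_alpha = lookahead_alpha
        self.random_state = random_state

    def _train_config(self, stage: str) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lookahead_k=self.lookahead_k,
            lookahead_alpha=self.lookahead_alpha,
            loss=TverskyConfig(alpha=self.alpha, beta=self.beta),
            seed=self.random_state,
            stage=stage,
            teacher_forcing=False,
        )

    def fit(self, X, y):
        """Fit to slices X (n, H, W) and binary masks y of the same shape."""
        X = _check_images(X)
        y = _check_masks(y, X)
        stage = "roi" if self.variant == "unet" else "tumor"
        cases = _as_cases(X, (y, y) if stage == "roi" else (None, y))
        spec = NetworkSpec(
            base_channels=self.base_channels,
            variant=self.variant,
            attention_iterations=self.attention_iterations,
        )
        ckpt = train_stage(cases, spec, self._train_config(stage))
        self.checkpoint_ = ckpt
        self.model_ = ckpt.build_model()
        self.history_ = ckpt.history
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this segmenter has not been fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probability for each slice."""
        self._require_fitted()
        X = _check_images(X)
        return np.stack([forward(self.model_, zscore_normalize(x)).foreground for x in X])

    def predict(self, X) -> np.ndarray:
        """Binary masks (threshold 0.5 on the foreground probability)."""
        return (self.predict_proba(X) > 0.5).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-slice Dice similarity coefficient."""
        y = _check_masks(y, _check_images(X))
        preds = self.predict(X)
        return float(np.mean([_dice(p, g) for p, g in zip(preds, y)]))


class TwoStageSegmenter(BaseEstimator):
    """ROI-then-tumor cascade: a U-Net crops attention, an RA-U-Net segments.

    ``fit`` expects ``y`` of shape (n, 2, H, W): channel 0 the breast-ROI
    mask, channel 1 the tumor mask (tumor must lie inside the ROI).
    """

    def __init__(
        self,
        base_channels: int = 8,
        attention_iterations: int = 2,
        alpha: float = 0.3,
        beta: float = 0.7,
        learning_rate: float = 1e-3,
        roi_epochs: int = 10,
        tumor_epochs: int = 30,
        batch_size: int = 4,
        lookahead_k: int = 5,
        lookahead_alpha: float = 0.5,
        roi_mode: str = "mask",
        roi_margin: int = 16,
        random_state: int = 0,
    ):
        self.base_channels = base_channels
        self.attention_iterations = attention_iterations
        self.alpha = alpha
        self.beta = beta
        self.learning_rate = learning_rate
        self.roi_epochs = roi_epochs
        self.tumor_epochs = tumor_epochs
        self.batch_size = batch_size
        self.lookahead_k = lookahead_k
        self.lookahead_alpha = lookahead_alpha
        self.roi_mode = roi_mode
        self.roi_margin = roi_margin
        self.random_state = random_state

    def fit(self, X, y):
        X = _check_images(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0], 2, X.shape[1], X.shape[2]):
            raise ValueError(f"y must be (n, 2, H, W) [roi, tumor], got {y.shape}")
        roi = _check_masks(y[:, 0], X)
        tumor = _check_masks(y[:, 1], X)
        cases = _as_cases(X, (roi, tumor))
        spec = NetworkSpec(
            base_channels=self.base_channels,
            attention_iterations=self.attention_iterations,
        )

        def cfg(stage, epochs):
            return TrainConfig(
                learning_rate=self.learning_rate,
                epochs=epochs,
                batch_size=self.batch_size,
                lookahead_k=self.lookahead_k,
                lookahead_alpha=self.lookahead_alpha,
                loss=TverskyConfig(alpha=self.alpha, beta=self.beta),
                seed=self.random_state,
                stage=stage,
                roi_margin=self.roi_margin,
            )

        self.roi_checkpoint_ = train_stage(cases, spec, cfg("roi", self.roi_epochs))
        self.tumor_checkpoint_ = train_stage(cases, spec, cfg("tumor", self.tumor_epochs))
        self.roi_application_ = RoiApplication(mode=self.roi_mode, margin=self.roi_margin)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict(self, X) -> np.ndarray:
        """Binary tumor masks in the original slice frame."""
        if not hasattr(self, "tumor_checkpoint_"):
            raise RuntimeError("this segmenter has not been fitted yet")
        X = _check_images(X)
        out = []
        for x in X:
            case = CaseRecord(
                case_id="predict",
                slices=[x],
                roi_masks=[np.ones(x.shape, dtype=np.uint8)],
                tumor_masks=[np.zeros(x.shape, dtype=np.uint8)],
            )
            out.append(
                predict_case(case, self.roi_checkpoint_, self.tumor_checkpoint_, self.roi_application_)[0]
            )
        return np.stack(out)

    def score(self, X, y) -> float:
        """Mean per-slice tumor Dice; ``y`` is (n, 2, H, W) or (n, H, W)."""
        y = np.asarray(y)
        tumor = y[:, 1] if y.ndim == 4 else y
        preds = self.predict(X)
        return float(np.mean([_dice(p, g.astype(np.uint8)) for p, g in zip(preds, tumor)]))
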