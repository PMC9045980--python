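"""Two-stage training and inference orchestration.

Stage 1 trains a plain U-Net to delineate the breast ROI; stage 2 trains the
Recurrent Attention U-Net on ROI-masked (or cropped) slices to segment the
tumor.  Both stages share one protocol: per-slice z-scoring, Tversky loss
(alpha = 0.3, beta = 0.7), Adam (lr = 1e-3, betas 0.9/0.999, eps 1e-8)
wrapped by Lookahead (k = 5, alpha_slow = 0.5), batch size 4, and seeded
data order and initialization so a (config, seed) pair fully determines the
checkpoint.  Checkpoint selection keeps the best validation-DSC epoch when a
validation set is supplied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import distance_transform_edt

from ._tensor import Tensor
from .evaluation import confusion_counts
from .nets import DIVISIBILITY, NetworkSpec, UNet, forward
from .objectives import TverskyConfig, one_hot, tversky_loss_batch
from .phantom import CaseRecord, expand_with_augmentation, zscore_normalize

__all__ = [
    "Adam",
    "Checkpoint",
    "Lookahead",
    "RoiApplication",
    "RoiTransform",
    "TrainConfig",
    "apply_roi",
    "load_checkpoint",
    "lookahead_update",
    "mask_with_roi",
    "predict_case",
    "predict_single_stage",
    "save_checkpoint",
    "train_stage",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    lookahead_k: int = 5
    lookahead_alpha: float = 0.5
    loss: TverskyConfig = field(default_factory=TverskyConfig)
    seed: int = 0
    stage: str = "tumor"
    teacher_forcing: bool = True
    augment_multiplier: int = 1
    roi_margin: int = 16

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lookahead_k < 1:
            raise ValueError("lookahead_k must be >= 1")
        if not 0.0 < self.lookahead_alpha <= 1.0:
            raise ValueError("lookahead_alpha must lie in (0, 1]")
        if self.stage not in ("roi", "tumor"):
            raise ValueError(f"stage must be 'roi' or 'tumor', got {self.stage!r}")


@dataclass
class RoiApplication:
    """How the stage-1 ROI is applied before stage 2."""

    mode: str = "mask"
    margin: int = 16
    threshold: float = 0.5

    def __post_init__(self):
        if self.mode not in ("mask", "crop"):
            raise ValueError(f"mode must be 'mask' or 'crop', got {self.mode!r}")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class RoiTransform:
    """Record of the ROI application, invertible on predicted masks."""

    mode: str
    shape: tuple
    r0: int = 0
    c0: int = 0
    crop_h: int = 0
    crop_w: int = 0

    def inverse_map(self, mask: np.ndarray) -> np.ndarray:
        """Map a stage-2 mask back to the original slice frame."""
        if self.mode == "mask":
            return mask
        out = np.zeros(self.shape, dtype=mask.dtype)
        out[self.r0 : self.r0 + self.crop_h, self.c0 : self.c0 + self.crop_w] = mask[
            : self.crop_h, : self.crop_w
        ]
        return out


# -- optimization --------------------------------------------------------------


def lookahead_update(fast_weights, slow_weights, k: int, alpha_slow: float, step: int):
    """Lookahead synchronization rule.

    Every k inner steps: slow <- slow + alpha_slow * (fast - slow) and the
    fast weights restart from the new slow weights; other steps leave both
    untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if step % k != 0:
        return fast_weights, slow_weights
    new_slow = [s + alpha_slow * (f - s) for f, s in zip(fast_weights, slow_weights)]
    new_fast = [s.copy() for s in new_slow]
    return new_fast, new_slow


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


class Lookahead:
    """Wraps an inner optimizer with slow weights synchronized every k steps."""

    def __init__(self, inner: Adam, k: int = 5, alpha_slow: float = 0.5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.inner = inner
        self.k = k
        self.alpha_slow = alpha_slow
        self.slow = [p.data.copy() for p in inner.params]
        self.step_count = 0

    def step(self):
        self.inner.step()
        self.step_count += 1
        fast = [p.data for p in self.inner.params]
        fast, self.slow = lookahead_update(fast, self.slow, self.k, self.alpha_slow, self.step_count)
        for p, f in zip(self.inner.params, fast):
            p.data = f


# -- checkpoints ---------------------------------------------------------------


@dataclass
class Checkpoint:
    state: dict
    spec: NetworkSpec
    config: TrainConfig
    history: dict
    stage: str

    def build_model(self) -> UNet:
        model = UNet(self.spec, seed=self.config.seed)
        try:
            model.load_state_dict(self.state)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"checkpoint/spec mismatch: {exc}") from exc
        return model


CHECKPOINT_VERSION = 1


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "stage": ckpt.stage,
        "spec": asdict(ckpt.spec),
        "config": {**asdict(ckpt.config), "loss": asdict(ckpt.config.loss)},
        "history": ckpt.history,
    }
    arrays = {f"param/{k}": v for k, v in ckpt.state.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")}
    cfg_d = meta["config"]
    cfg_d["loss"] = TverskyConfig(**cfg_d["loss"])
    return Checkpoint(
        state=state,
        spec=NetworkSpec(**meta["spec"]),
        config=TrainConfig(**cfg_d),
        history=meta["history"],
        stage=meta["stage"],
    )


# -- ROI application -----------------------------------------------------------


def _dilate(mask: np.ndarray, margin: int) -> np.ndarray:
    if margin <= 0 or not mask.any():
        return mask.astype(bool)
    return distance_transform_edt(~mask.astype(bool)) <= margin


def mask_with_roi(image: np.ndarray, roi: np.ndarray, margin: int = 16) -> np.ndarray:
    """Blank everything outside the (dilated) ROI and re-standardize."""
    roi_d = _dilate(np.asarray(roi) > 0, margin)
    out = np.array(image, dtype=np.float64)
    outside = ~roi_d
    if outside.any() and roi_d.any():
        out[outside] = np.median(out[outside])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return zscore_normalize(out)


def apply_roi(image: np.ndarray, roi_prob, app: RoiApplication):
    """Apply a stage-1 ROI prediction to a z-scored slice.

    Returns the stage-2 input slice and the :class:`RoiTransform` needed to
    map stage-2 predictions back to the original frame.  An empty ROI
    prediction falls back to the whole image with a warning — a case is never
    silently dropped.
    """
    image = np.asarray(image)
    fg = roi_prob.foreground if hasattr(roi_prob, "foreground") else np.asarray(roi_prob)
    if fg.shape != image.shape:
        raise ValueError(f"image/ROI shape mismatch: {image.shape} vs {fg.shape}")
    roi = fg > app.threshold
    if not roi.any():
        warnings.warn("empty ROI prediction: falling back to the whole image", stacklevel=2)
        roi = np.ones_like(roi)

    if app.mode == "mask":
        return mask_with_roi(image, roi, app.margin), RoiTransform(mode="mask", shape=image.shape)

    roi_d = _dilate(roi, app.margin)
    rr, cc = np.nonzero(roi_d)
    r0, r1 = int(rr.min()), int(rr.max()) + 1
    c0, c1 = int(cc.min()), int(cc.max()) + 1
    crop = image[r0:r1, c0:c1]
    ch, cw = crop.shape
    ph = (DIVISIBILITY - ch % DIVISIBILITY) % DIVISIBILITY
    pw = (DIVISIBILITY - cw % DIVISIBILITY) % DIVISIBILITY
    padded = np.pad(crop, ((0, ph), (0, pw)), mode="edge")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        padded = zscore_normalize(padded)
    tf = RoiTransform(mode="crop", shape=image.shape, r0=r0, c0=c0, crop_h=ch, crop_w=cw)
    return padded, tf


# -- training ------------------------------------------------------------------


def _stage_dataset(cases, stage: str, teacher_forcing: bool, roi_margin: int):
    X, Y = [], []
    for case in cases:
        masks = case.roi_masks if stage == "roi" else case.tumor_masks
        for img, target, roi in zip(case.slices, masks, case.roi_masks):
            z = zscore_normalize(img)
            if stage == "tumor" and teacher_forcing:
                z = mask_with_roi(z, roi, roi_margin)
            X.append(z.astype(np.float32))
            Y.append(one_hot(target))
    return np.stack(X)[:, None], np.stack(Y)


def _mean_dsc(model: UNet, X: np.ndarray, Y: np.ndarray) -> float:
    scores = []
    for i in range(X.shape[0]):
        out = model(X[i : i + 1])
        pred = (out.data[0, 0] > 0.5).astype(np.uint8)
        gt = Y[i, 0].astype(np.uint8)
        c = confusion_counts(pred, gt)
        denom = 2 * c.tp + c.fp + c.fn
        scores.append(2 * c.tp / denom if denom else 1.0)
    return float(np.mean(scores))


def train_stage(cases, spec: NetworkSpec, cfg: TrainConfig, val_cases=None) -> Checkpoint:
    """Train one stage and return its checkpoint.

    Data order, augmentation and weight init all derive from ``cfg.seed``.
    If ``val_cases`` is given, per-epoch validation DSC is logged and the
    best-validation weights are retained; otherwise the final weights are.
    """
    if not cases:
        raise ValueError("empty training dataset")
    H, W = np.asarray(cases[0].slices[0]).shape
    if H % DIVISIBILITY or W % DIVISIBILITY:
        raise ValueError(f"slice dims must be divisible by {DIVISIBILITY}, got {H}x{W}")

    rng = np.random.default_rng(cfg.seed)
    if cfg.augment_multiplier > 1:
        cases = expand_with_augmentation(
            cases, cfg.augment_multiplier, seed=int(rng.integers(2**31 - 1))
        )
    X, Y = _stage_dataset(cases, cfg.stage, cfg.teacher_forcing, cfg.roi_margin)
    Xv = Yv = None
    if val_cases:
        Xv, Yv = _stage_dataset(val_cases, cfg.stage, cfg.teacher_forcing, cfg.roi_margin)

    variant = "unet" if cfg.stage == "roi" else "ra_unet"
    spec = NetworkSpec(**{**spec.__dict__, "variant": variant})
    model = UNet(spec, seed=cfg.seed)
    opt = Lookahead(
        Adam(model.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps),
        k=cfg.lookahead_k,
        alpha_slow=cfg.lookahead_alpha,
    )

    n = X.shape[0]
    history = {"train_loss": [], "val_dsc": []}
    best_dsc, best_state = -1.0, None
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            out = model(Tensor(X[idx]))
            loss = tversky_loss_batch(out, Y[idx], cfg.loss)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if Xv is not None:
            dsc = _mean_dsc(model, Xv, Yv)
            history["val_dsc"].append(dsc)
            if dsc > best_dsc:
                best_dsc, best_state = dsc, model.state_dict()

    state = best_state if best_state is not None else model.state_dict()
    return Checkpoint(state=state, spec=spec, config=cfg, history=history, stage=cfg.stage)


# -- inference -----------------------------------------------------------------


def predict_case(case: CaseRecord, roi_ckpt: Checkpoint, tumor_ckpt: Checkpoint, app: RoiApplication | None = None):
    """Full two-stage prediction: binary tumor masks aligned with the input.

    Per slice: z-score -> ROI U-Net -> mask/crop -> RA-U-Net -> threshold
    0.5 -> inverse-map to the original frame.
    """
    app = app or RoiApplication()
    roi_model = roi_ckpt.build_model()
    tumor_model = tumor_ckpt.build_model()
    out = []
    for img in case.slices:
        z = zscore_normalize(img)
        roi_out = forward(roi_model, z)
        stage2_in, tf = apply_roi(z, roi_out, app)
        tumor_out = forward(tumor_model, stage2_in)
        out.append(tf.inverse_map(tumor_out.mask(0.5)))
    return out


def predict_single_stage(case: CaseRecord, ckpt: Checkpoint):
    """Stage-2 network applied directly to the full frame (no ROI cascade)."""
    model = ckpt.build_model()
    return [forward(model, zscore_normalize(img)).mask(0.5) for img in case.slices]
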