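"""Network assembly: the ROI U-Net and the Recurrent Attention U-Net.

Both nets are five-stage encoder/decoder models at half the classic U-Net
width: the encoder channel ladder is base * (1, 2, 4, 8, 16), i.e.
32-64-128-256-512 at the default base of 32 against the classic 64-1024.
Downsampling is 2x2 max pooling (four times, so input dims must be divisible
by 16), upsampling is a 2x2 stride-2 transposed convolution, and every skip
connection concatenates encoder and decoder maps of identical spatial size.
The head is a 1x1 convolution to two classes followed by a per-pixel softmax
(channel 0 = foreground/lesion, channel 1 = background).

The ``ra_unet`` variant appends a dense residual module to encoder stages
2-5 (the fifth being the bottleneck); the module output feeds both the
pooling path and the skip connection.  Every decoder conv-block pair is
replaced by a recurrent attention module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Conv2d, ConvTranspose2d, Module
from ._tensor import Tensor, concat, max_pool2d, softmax_channels
from .blocks import ConvBlock, DenseResidualModule, RecurrentAttentionModule

__all__ = [
    "NetworkSpec",
    "SegmentationOutput",
    "UNet",
    "build_ra_unet",
    "build_unet",
    "forward",
]

N_POOLINGS = 4
DIVISIBILITY = 2**N_POOLINGS


@dataclass
class NetworkSpec:
    """Architecture hyperparameters shared by both stages."""

    base_channels: int = 32
    depth: int = 5
    in_channels: int = 1
    out_classes: int = 2
    variant: str = "unet"
    attention_iterations: int = 2

    def __post_init__(self):
        if self.depth != 5:
            raise ValueError("only the five-stage (four-pooling) layout is supported")
        if self.variant not in ("unet", "ra_unet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.base_channels < 2 or self.base_channels % 2:
            raise ValueError("base_channels must be an even integer >= 2")

    @property
    def ladder(self):
        return tuple(self.base_channels * (2**i) for i in range(self.depth))


@dataclass
class SegmentationOutput:
    """Per-pixel class probabilities; channel order (lesion, non-lesion)."""

    probabilities: np.ndarray  # (H, W, 2)

    def __post_init__(self):
        p = self.probabilities
        if p.ndim != 3 or p.shape[-1] != 2:
            raise ValueError(f"probabilities must be (H, W, 2), got {p.shape}")

    @property
    def foreground(self) -> np.ndarray:
        return self.probabilities[..., 0]

    def mask(self, threshold: float = 0.5) -> np.ndarray:
        return (self.probabilities[..., 0] > threshold).astype(np.uint8)


class UNet(Module):
    """Five-stage U-Net, optionally with dense-residual + recurrent attention."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        ladder = spec.ladder
        ra = spec.variant == "ra_unet"

        enc = []
        c_in = spec.in_channels
        for c in ladder:
            enc.append(ConvBlock(c_in, c, rng=rng))
            enc.append(ConvBlock(c, c, rng=rng))
            c_in = c
        self.enc = enc

        # Dense residual modules close encoder stages 2..5 (incl. bottleneck).
        self.dense = [DenseResidualModule(c, rng=rng) for c in ladder[1:]] if ra else []

        ups, dec = [], []
        for c in reversed(ladder[:-1]):
            ups.append(ConvTranspose2d(2 * c, c, rng=rng))
            if ra:
                dec.append(RecurrentAttentionModule(2 * c, iterations=spec.attention_iterations, rng=rng))
            else:
                dec.append(ConvBlock(2 * c, c, rng=rng))
                dec.append(ConvBlock(c, c, rng=rng))
        self.ups = ups
        self.dec = dec
        self.head = Conv2d(ladder[0], spec.out_classes, 1, rng=rng)

    # -- forward --------------------------------------------------------------

    def _check_input(self, x: np.ndarray):
        if not np.all(np.isfinite(x)):
            raise ValueError("network input contains non-finite values")
        H, W = x.shape[-2:]
        if H % DIVISIBILITY or W % DIVISIBILITY:
            raise ValueError(
                f"spatial dims must be divisible by {DIVISIBILITY} "
                f"(four pooling levels), got {H}x{W}"
            )

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        self._check_input(x.data)
        ra = self.spec.variant == "ra_unet"
        skips = []
        y = x
        for stage in range(self.spec.depth):
            y = self.enc[2 * stage](y)
            y = self.enc[2 * stage + 1](y)
            if ra and stage >= 1:
                y = self.dense[stage - 1](y)
            if stage < self.spec.depth - 1:
                skips.append(y)
                y = max_pool2d(y)
        for i, skip in enumerate(reversed(skips)):
            y = self.ups[i](y)
            y = concat([y, skip], axis=1)
            if ra:
                y = self.dec[i](y)
            else:
                y = self.dec[2 * i](y)
                y = self.dec[2 * i + 1](y)
        return softmax_channels(self.head(y))


def build_unet(spec: NetworkSpec | None = None, seed: int = 0) -> UNet:
    """Stage-1 breast-ROI network: the plain (PReLU/GN) U-Net."""
    spec = spec or NetworkSpec()
    if spec.variant != "unet":
        spec = NetworkSpec(**{**spec.__dict__, "variant": "unet"})
    return UNet(spec, seed=seed)


def build_ra_unet(spec: NetworkSpec | None = None, seed: int = 0) -> UNet:
    """Stage-2 tumor network: U-Net + dense residual + recurrent attention."""
    spec = spec or NetworkSpec(variant="ra_unet")
    if spec.variant != "ra_unet":
        spec = NetworkSpec(**{**spec.__dict__, "variant": "ra_unet"})
    return UNet(spec, seed=seed)


def forward(model: UNet, image: np.ndarray) -> SegmentationOutput:
    """Run one 2-D slice through a model and return class probabilities."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {image.shape}")
    out = model(image[None, None].astype(np.float32, copy=False))
    probs = np.transpose(out.data[0], (1, 2, 0))
    return SegmentationOutput(probabilities=probs)
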