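"""Building blocks of the Recurrent Attention U-Net.

Three constructs live here:

* ``ConvBlock`` — convolution -> group normalization -> PReLU, the basic unit
  used throughout both networks (normalization can be switched off, which is
  useful for receptive-field probes).
* ``DenseResidualModule`` — a cascade of three dilated residual units with
  dilation rates (1, 2, 3).  Unit ``t`` squeezes the N input channels to N/2
  with a 1x1 conv block, applies a 3x3 dilated conv block, restores N channels
  with a 1x1 conv + GN (no PReLU), and emits
  ``x_{t+1} = PReLU(x_1 + ... + x_t + x_t^3)`` — every earlier unit *input*
  is accumulated, which densifies gradient flow and removes the gridding
  holes an isolated dilated kernel would leave in the receptive field.
* ``RecurrentAttentionModule`` — the decoder block.  A first conv block halves
  the concatenated channels to N; then for L iterations a GRU consumes the
  globally max-pooled feature vector together with its running hidden state
  (length N/2, initialized to zero), the hidden state is projected to N
  channel weights alpha in (0,1) via a learned linear map and a sigmoid, and
  the block output is ``y_l = PReLU(x_l + x_l * alpha_l)`` with channel-wise
  broadcasting.  Iteration l >= 2 feeds y_{l-1} through a channel-preserving
  conv block.
"""

from __future__ import annotations

import numpy as np

from ._nn import Conv2d, GroupNorm, GRUCell, Linear, Module, PReLU
from ._tensor import Tensor, prelu, sigmoid, spatial_max

__all__ = [
    "ConvBlock",
    "DenseResidualModule",
    "RecurrentAttentionModule",
    "conv_block",
    "dense_residual_forward",
    "dilated_kernel_extent",
    "global_max_pool",
    "gru_step",
    "recurrent_attention_forward",
]


def dilated_kernel_extent(k: int, d: int) -> int:
    """Spatial extent of a k x k kernel dilated at rate d.

    Inserting d - 1 zeros between taps expands the kernel to
    ``k + (k - 1) * (d - 1)`` pixels per side: 3 -> 3, 5, 7 at d = 1, 2, 3.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got k={k}")
    if d < 1:
        raise ValueError(f"dilation rate must be >= 1, got d={d}")
    return k + (k - 1) * (d - 1)


class ConvBlock(Module):
    """Convolution -> GroupNorm -> PReLU with 'same' zero padding."""

    def __init__(self, in_channels, out_channels, kernel_size=3, dilation=1, norm=True, activation=True, rng=None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, dilation=dilation, rng=rng)
        self.norm = GroupNorm(out_channels) if norm else None
        self.act = PReLU(out_channels) if activation else None

    def forward(self, x):
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        if self.act is not None:
            y = self.act(y)
        return y


def conv_block(x, block: ConvBlock):
    """Functional form of :class:`ConvBlock` for a prebuilt block."""
    return block(x)


class _DenseResidualUnit(Module):
    """One residual unit: 1x1 squeeze, 3x3 dilated, 1x1 expand (GN, no PReLU)."""

    def __init__(self, channels, dilation, rng=None):
        super().__init__()
        if channels % 2:
            raise ValueError(f"dense residual unit needs an even channel count, got {channels}")
        mid = channels // 2
        self.squeeze = ConvBlock(channels, mid, kernel_size=1, rng=rng)
        self.dilated = ConvBlock(mid, mid, kernel_size=3, dilation=dilation, rng=rng)
        self.expand = ConvBlock(mid, channels, kernel_size=1, activation=False, rng=rng)

    def forward(self, x):
        return self.expand(self.dilated(self.squeeze(x)))


class DenseResidualModule(Module):
    """Cascade of three dilated residual units with dense input accumulation."""

    DILATIONS = (1, 2, 3)

    def __init__(self, channels, rng=None):
        super().__init__()
        if channels % 2:
            raise ValueError(f"channel count must be even, got {channels}")
        self.channels = channels
        self.units = [_DenseResidualUnit(channels, d, rng=rng) for d in self.DILATIONS]
        self.acts = [PReLU(channels) for _ in self.DILATIONS]

    def forward(self, x):
        inputs = [x]  # x_1 ... x_t
        for unit, act in zip(self.units, self.acts):
            xt3 = unit(inputs[-1])
            s = inputs[0]
            for prev in inputs[1:]:
                s = s + prev
            inputs.append(act(s + xt3))
        return inputs[-1]  # x_4


def dense_residual_forward(x, module: DenseResidualModule):
    """Functional form of :class:`DenseResidualModule`."""
    return module(x)


def global_max_pool(x):
    """Compress (N, C, H, W) to (N, C): the per-channel spatial maximum."""
    if isinstance(x, Tensor):
        return spatial_max(x)
    return np.asarray(x).reshape(x.shape[0], x.shape[1], -1).max(axis=-1)


def gru_step(cell: GRUCell, x_pooled, h):
    """One GRU update h -> h' from a pooled feature vector of length N.

    The hidden state has length N/2; see :class:`raunet._nn.GRUCell` for the
    gate equations.
    """
    if x_pooled.shape[-1] != 2 * cell.hidden_size:
        raise ValueError(
            f"pooled vector length {x_pooled.shape[-1]} does not match "
            f"2 * hidden size = {2 * cell.hidden_size}"
        )
    if h.shape[-1] != cell.hidden_size:
        raise ValueError(f"hidden length {h.shape[-1]} != {cell.hidden_size}")
    return cell(x_pooled, h)


class RecurrentAttentionModule(Module):
    """GRU-driven channel attention applied L times in a decoder stage."""

    def __init__(self, in_channels, iterations=2, rng=None):
        super().__init__()
        if iterations < 1:
            raise ValueError(f"attention iterations must be >= 1, got {iterations}")
        if in_channels % 4:
            raise ValueError("in_channels must be divisible by 4 (halved twice)")
        self.iterations = iterations
        self.out_channels = n = in_channels // 2
        blocks = [ConvBlock(in_channels, n, rng=rng)]
        blocks += [ConvBlock(n, n, rng=rng) for _ in range(iterations - 1)]
        self.blocks = blocks
        self.gru = GRUCell(n, n // 2, rng=rng)
        self.proj = Linear(n // 2, n, rng=rng)
        self.acts = [PReLU(n) for _ in range(iterations)]

    def forward(self, x):
        batch = x.shape[0]
        h = Tensor(np.zeros((batch, self.out_channels // 2), dtype=x.data.dtype))
        y = x
        for l in range(self.iterations):
            xl = self.blocks[l](y)
            h = self.gru(spatial_max(xl), h)
            alpha = sigmoid(self.proj(h))  # (batch, N) in (0, 1)
            alpha4 = alpha.reshape(batch, self.out_channels, 1, 1)
            y = prelu(xl + xl * alpha4, self.acts[l].slope)
        return y


def recurrent_attention_forward(x_concat, module: RecurrentAttentionModule):
    """Functional form of :class:`RecurrentAttentionModule`."""
    return module(x_concat)
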