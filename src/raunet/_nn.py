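"""Layer and module abstractions on top of the autograd engine.

Modules own named parameters, compose hierarchically, and serialize to flat
``state_dict`` mappings of numpy arrays.  Initialization follows He fan-in
scaling with the PReLU gain sqrt(2 / (1 + a^2)) and slope a = 0.25.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from ._tensor import (
    Tensor,
    conv2d,
    conv_transpose2d,
    group_norm,
    matmul,
    prelu,
    sigmoid,
    tanh,
)

PRELU_SLOPE_INIT = 0.25
DEFAULT_DTYPE = np.float32


def he_prelu_std(fan_in: int, slope: float = PRELU_SLOPE_INIT) -> float:
    """Std of the fan-in normal init rescaled for a PReLU nonlinearity."""
    return float(np.sqrt(2.0 / ((1.0 + slope**2) * fan_in)))


class Module:
    """Base class: tracks parameters and child modules by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return OrderedDict((k, p.data.copy()) for k, p in self.named_parameters())

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(
                f"state dict mismatch; missing={sorted(missing)[:3]} extra={sorted(extra)[:3]}"
            )
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for layer '{k}': {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def astype(self, dtype):
        """Cast all parameters in place (e.g. float64 for gradient checks)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(arr) -> Tensor:
    return Tensor(np.asarray(arr, dtype=DEFAULT_DTYPE), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, dilation=1, bias=True, rng=None):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd to preserve spatial dims")
        rng = rng or np.random.default_rng()
        self.dilation = int(dilation)
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, he_prelu_std(fan_in), size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = _param(w)
        self.bias = _param(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2d(Module):
    """2x2 stride-2 learned upsampler."""

    def __init__(self, in_channels, out_channels, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels  # each output pixel sees one input pixel per tap
        w = rng.normal(0.0, he_prelu_std(fan_in), size=(in_channels, out_channels, 2, 2))
        self.weight = _param(w)
        self.bias = _param(np.zeros(out_channels))

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias)


def gn_groups(channels: int, preferred: int = 8) -> int:
    """Group count: min(8, C), falling back to 1 when C is not divisible."""
    g = min(preferred, channels)
    return g if channels % g == 0 else 1


class GroupNorm(Module):
    def __init__(self, channels, groups=None, eps=1e-5):
        super().__init__()
        self.groups = gn_groups(channels) if groups is None else groups
        if channels % self.groups:
            raise ValueError("channels must be divisible by group count")
        self.eps = eps
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))

    def forward(self, x):
        return group_norm(x, self.gamma, self.beta, self.groups, self.eps)


class PReLU(Module):
    def __init__(self, channels, init=PRELU_SLOPE_INIT):
        super().__init__()
        self.slope = _param(np.full(channels, init))

    def forward(self, x):
        return prelu(x, self.slope)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = _param(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = _param(np.zeros(out_features))

    def forward(self, x):
        return matmul(x, self.weight) + self.bias.reshape(1, -1)


class GRUCell(Module):
    """Standard gated recurrent unit (reset/update/candidate gates).

    r = sigmoid(W_ir x + b_ir + W_hr h + b_hr)
    z = sigmoid(W_iz x + b_iz + W_hz h + b_hz)
    n = tanh(W_in x + b_in + r * (W_hn h + b_hn))
    h' = (1 - z) * n + z * h

    Biases start at zero, so the all-zero configuration gives h' = 0.
    """

    def __init__(self, input_size, hidden_size, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.hidden_size = hidden_size
        bound = 1.0 / np.sqrt(hidden_size)
        self.w_ih = _param(rng.uniform(-bound, bound, size=(input_size, 3 * hidden_size)))
        self.w_hh = _param(rng.uniform(-bound, bound, size=(hidden_size, 3 * hidden_size)))
        self.b_ih = _param(np.zeros(3 * hidden_size))
        self.b_hh = _param(np.zeros(3 * hidden_size))

    def forward(self, x, h):
        H = self.hidden_size
        gi = matmul(x, self.w_ih) + self.b_ih.reshape(1, -1)
        gh = matmul(h, self.w_hh) + self.b_hh.reshape(1, -1)
        r = sigmoid(gi[:, :H] + gh[:, :H])
        z = sigmoid(gi[:, H : 2 * H] + gh[:, H : 2 * H])
        n = tanh(gi[:, 2 * H :] + r * gh[:, 2 * H :])
        return (1.0 - z) * n + z * h
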