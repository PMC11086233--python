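"""Neural-network building blocks on top of the autodiff core.

Modules follow the usual container pattern: parameters are
``Tensor(requires_grad=True)`` attributes, ``parameters()`` walks the module
tree, and ``train()`` / ``eval()`` toggle a mode flag that the CAS modules
consult (label-weighted versus prediction-weighted channel reweighting).
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Tensor,
    as_tensor,
    conv1d,
    leaky_relu,
    matmul,
    pnorm_dist,
)

__all__ = ["Module", "Conv1d", "GroupNorm", "LeakyReLU", "Linear", "PNormDistLayer"]


class Module:
    """Base class: parameter discovery, mode switching, gradient clearing."""

    def __init__(self):
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for mod in (self, *self.modules()):
            for value in mod.__dict__.values():
                if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
                    seen.add(id(value))
                    yield value

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x):
        return conv1d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    """Group normalization with an optional validity mask.

    With a mask [N, W] the per-group statistics are computed over valid
    positions only, so that the amount of zero padding appended to a record
    cannot leak into the normalised features (padding invariance).
    """

    def __init__(self, num_groups, num_channels, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("channels must divide evenly into groups")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)

    def forward(self, x, mask: np.ndarray | None = None):
        n, c, w = x.shape
        g = self.num_groups
        xg = x.reshape((n, g, c // g, w))
        if mask is None:
            mu = xg.mean(axis=(2, 3), keepdims=True)
            var = ((xg - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        else:
            m = np.asarray(mask, dtype=np.float64)[:, None, None, :]  # [N,1,1,W]
            counts = m.sum(axis=3, keepdims=True) * (c // g)
            mu = (xg * m).sum(axis=(2, 3), keepdims=True) / counts
            var = (((xg - mu) * m) ** 2).sum(axis=(2, 3), keepdims=True) / counts
        xhat = (xg - mu) * ((var + self.eps) ** -0.5)
        xhat = xhat.reshape((n, c, w))
        gamma = self.gamma.reshape((1, c, 1))
        beta = self.beta.reshape((1, c, 1))
        return xhat * gamma + beta


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return leaky_relu(x, self.slope)


class Linear(Module):
    def __init__(self, in_features, out_features, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(1.0 / in_features)
        self.weight = Tensor(
            rng.uniform(-scale, scale, size=(in_features, out_features)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return matmul(as_tensor(x), self.weight) + self.bias


class PNormDistLayer(Module):
    """Layer of distance neurons: out_i = ||x - w_i||_p + b_i.

    At ``p=inf`` (the default, used at evaluation) every neuron — and hence
    the layer — is a 1-Lipschitz map under the l-infinity norm.  A finite
    ``p`` is the smooth surrogate used while training.
    """

    def __init__(self, in_features, out_features, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.p = np.inf
        self.weight = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(in_features), size=(out_features, in_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return pnorm_dist(as_tensor(x), self.weight, self.bias, p=self.p)
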