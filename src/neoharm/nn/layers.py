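"""Network building blocks on top of the autograd backend.

Convolution weights use Kaiming-style initialization seeded from an explicit
`numpy.random.Generator`, so identical specs and seeds give identical
networks.  Parameters default to float32.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "LeakyReLU",
    "AvgPool2",
    "MaxPool2",
    "Sequential",
]


class Module:
    """Base class: anything with parameters and a forward call."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.array(s, dtype=p.data.dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.weight = Tensor(_kaiming(rng, (c_out, c_in, k, k, k), c_in * k**3),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose3d(Module):
    """3^3 transposed convolution doubling the spatial grid (stride 2)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_kaiming(rng, (c_in, c_out, 3, 3, 3), c_in * 27),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose3d(self.weight, self.bias, stride=2)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization; affine parameters optional."""

    def __init__(self, channels: int, affine: bool = False, eps: float = 1e-5):
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=np.float32),
                                requires_grad=True)
            self.beta = Tensor(np.zeros((1, channels, 1, 1, 1), dtype=np.float32),
                               requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        y = x.instance_norm(self.eps)
        if self.affine:
            y = y * self.gamma + self.beta
        return y


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class AvgPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.avg_pool2()


class MaxPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.max_pool2()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
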