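"""Network architectures: segmentation/generator U-Net and PatchGAN discriminator.

The segmentation network, the image-translation generator and the cortical
parcellation network all share one encoder-decoder architecture: five
encoding-decoding levels with 16, 32, 64, 128 and 256 channels, 3^3
convolutions (stride 1) with instance normalization and LeakyReLU, a 2^3
average pool after the first encoder block and 2^3 max pools below, and 3^3
transposed convolutions on the way up.  The segmenter ends in a channel
softmax (probability maps), the generator in a Tanh (single channel in
(-1, 1)).

The discriminator is a 3D PatchGAN: 4^3 stride-2 convolution blocks with
64, 128, 256, 512 and 1 channels, emitting a grid of patch logits.

A `width_multiplier` shrinks all channel counts proportionally so the models
train on a CPU at 32-64 voxel grids; the architecture is otherwise unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import (
    AvgPool2,
    Conv3d,
    ConvTranspose3d,
    InstanceNorm3d,
    LeakyReLU,
    MaxPool2,
    Module,
    Sequential,
    Tensor,
    concat,
)

__all__ = [
    "UNetSpec",
    "DiscSpec",
    "UNet3d",
    "PatchDiscriminator",
    "build_segmenter",
    "build_generator",
    "build_discriminator",
    "collect_decoder_features",
]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture parameters of the encoder-decoder networks."""

    levels: int = 5
    channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    out_channels: int = 7
    head: str = "softmax"  # softmax | tanh | none
    negative_slope: float = 0.01
    width_multiplier: float = 1.0
    convs_per_block: int = 1
    final_kernel: int = 3  # kernel of the output head convolution
    norm_affine: bool = False

    def __post_init__(self):
        if len(self.channels) != self.levels:
            raise ValueError("len(channels) must equal levels")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must be in (0, 1]")
        if self.head not in ("softmax", "tanh", "none"):
            raise ValueError(f"unknown head {self.head!r}")

    def scaled_channels(self) -> tuple[int, ...]:
        return tuple(max(1, round(c * self.width_multiplier)) for c in self.channels)


@dataclass(frozen=True)
class DiscSpec:
    """PatchGAN discriminator parameters."""

    blocks: int = 5
    channels: tuple[int, ...] = (64, 128, 256, 512, 1)
    negative_slope: float = 0.01
    width_multiplier: float = 1.0
    norm_affine: bool = False

    def __post_init__(self):
        if self.channels[-1] != 1:
            raise ValueError("last discriminator block must have 1 channel")
        if len(self.channels) != self.blocks:
            raise ValueError("len(channels) must equal blocks")

    def scaled_channels(self) -> tuple[int, ...]:
        inner = tuple(max(1, round(c * self.width_multiplier)) for c in self.channels[:-1])
        return inner + (1,)


def _conv_block(c_in: int, c_out: int, spec: UNetSpec, rng) -> Sequential:
    mods: list[Module] = []
    c = c_in
    for _ in range(spec.convs_per_block):
        mods += [
            Conv3d(c, c_out, k=3, stride=1, padding=1, rng=rng),
            InstanceNorm3d(c_out, affine=spec.norm_affine),
            LeakyReLU(spec.negative_slope),
        ]
        c = c_out
    return Sequential(*mods)


class UNet3d(Module):
    """Encoder-decoder with skip connections; see module docstring."""

    def __init__(self, spec: UNetSpec, in_channels: int = 1, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.spec = spec
        ch = spec.scaled_channels()
        L = spec.levels
        self.enc = []
        c_prev = in_channels
        for i in range(L):
            self.enc.append(_conv_block(c_prev, ch[i], spec, rng))
            c_prev = ch[i]
        # first down-sampling uses average pooling, deeper ones max pooling
        self.pools = [AvgPool2() if i == 0 else MaxPool2() for i in range(L - 1)]
        self.ups = []
        self.dec = []
        for i in range(L - 2, -1, -1):
            self.ups.append(ConvTranspose3d(ch[i + 1], ch[i], rng=rng))
            self.dec.append(_conv_block(2 * ch[i], ch[i], spec, rng))
        fk = spec.final_kernel
        self.final = Conv3d(ch[0], spec.out_channels, k=fk, stride=1,
                            padding=fk // 2, rng=rng)

    def _check_shape(self, x: Tensor) -> None:
        div = 2 ** (self.spec.levels - 1)
        for s in x.shape[2:]:
            if s % div:
                raise ValueError(
                    f"input spatial dims {x.shape[2:]} must be divisible by {div}"
                )

    def forward(self, x: Tensor, return_features: bool = False):
        self._check_shape(x)
        L = self.spec.levels
        skips = []
        h = x
        for i in range(L - 1):
            h = self.enc[i](h)
            skips.append(h)
            h = self.pools[i](h)
        h = self.enc[L - 1](h)
        feats = [h]  # deepest decoder-arm level (bottleneck output)
        for j, i in enumerate(range(L - 2, -1, -1)):
            h = self.ups[j](h)
            h = concat([skips[i], h], axis=1)
            h = self.dec[j](h)
            feats.append(h)
        y = self.final(h)
        if self.spec.head == "softmax":
            y = y.softmax(axis=1)
        elif self.spec.head == "tanh":
            y = y.tanh()
        if return_features:
            return y, feats
        return y


class PatchDiscriminator(Module):
    """PatchGAN: stride-2 4^3 conv blocks ending in a 1-channel logit grid.

    Each block halves the spatial grid (odd sizes are right-padded first, so
    the output is ceil(n/2)).  When the input grid is too small for the
    requested depth, the block count is reduced to the largest B with
    2^B <= min spatial dim; the channel progression is truncated accordingly.
    """

    def __init__(self, spec: DiscSpec, in_channels: int = 1,
                 input_shape: tuple[int, int, int] | None = None, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.spec = spec
        n_blocks = spec.blocks
        if input_shape is not None:
            m = min(input_shape)
            if m < 2:
                raise ValueError("input too small for any stride-2 block")
            n_blocks = min(n_blocks, int(math.floor(math.log2(m))))
            n_blocks = max(n_blocks, 1)
        ch = spec.scaled_channels()
        ch = ch[: n_blocks - 1] + (1,)
        self.n_blocks = n_blocks
        self.blocks = []
        c_prev = in_channels
        for bi, c in enumerate(ch):
            mods: list[Module] = [Conv3d(c_prev, c, k=4, stride=2, padding=1, rng=rng)]
            if bi < len(ch) - 1:
                mods += [InstanceNorm3d(c, affine=spec.norm_affine),
                         LeakyReLU(spec.negative_slope)]
            self.blocks.append(Sequential(*mods))
            c_prev = c

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for blk in self.blocks:
            pads = tuple((0, s % 2) for s in h.shape[2:])
            h = h.pad3d_asym(pads)
            if min(h.shape[2:]) < 2:
                raise ValueError("input exhausted before final discriminator block")
            h = blk(h)
        return h


def build_segmenter(spec: UNetSpec | None = None, in_channels: int = 1,
                    seed: int = 0) -> UNet3d:
    """Tissue (or parcel) segmentation U-Net with a softmax head."""
    spec = spec or UNetSpec()
    if spec.head != "softmax":
        spec = UNetSpec(**{**spec.__dict__, "head": "softmax"})
    return UNet3d(spec, in_channels=in_channels, seed=seed)


def build_generator(spec: UNetSpec | None = None, seed: int = 0) -> UNet3d:
    """Image-translation U-Net: single Tanh channel in (-1, 1)."""
    spec = spec or UNetSpec(out_channels=1, head="tanh")
    if spec.head != "tanh" or spec.out_channels != 1:
        spec = UNetSpec(**{**spec.__dict__, "head": "tanh", "out_channels": 1})
    return UNet3d(spec, in_channels=1, seed=seed)


def build_discriminator(spec: DiscSpec | None = None, in_channels: int = 1,
                        input_shape: tuple[int, int, int] | None = None,
                        seed: int = 0) -> PatchDiscriminator:
    spec = spec or DiscSpec()
    return PatchDiscriminator(spec, in_channels=in_channels,
                              input_shape=input_shape, seed=seed)


def collect_decoder_features(segmenter: UNet3d, x: Tensor) -> Tensor:
    """Stack all decoder-arm feature maps at the second-deepest resolution.

    Each decoder level's output (bottleneck included) is trilinearly resampled
    to the spatial shape of the second-deepest level and concatenated along
    channels; the result feeds the latent-space domain classifier.
    """
    _, feats = segmenter.forward(x, return_features=True)
    ref_shape = feats[1].shape[2:]  # second-deepest decoder level
    resized = [f if f.shape[2:] == ref_shape else f.resize_trilinear(ref_shape)
               for f in feats]
    return concat(resized, axis=1)
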