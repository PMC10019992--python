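"""VGG-16-style convolutional backbone exposing the five block outputs.

The taps are the last convolution of each block (conv1-2, conv2-2, conv3-3,
conv4-3, conv5-3), grouped into low-level (blocks 1-2, strides 1 and 2) and
high-level (blocks 3-5, strides 4, 8, 16).  Max pooling (2x2, ceil mode)
follows blocks 1-4, so every tap obeys H_i = ceil(H / stride_i).

A ``width_multiplier`` scales the standard block widths (64, 128, 256, 512,
512) down to a CPU-trainable size; channel counts are rounded and floored at
8.  Weights are He-initialized from a seeded generator — there is no
pretrained initialization in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Tensor

VGG_BLOCK_WIDTHS = (64, 128, 256, 512, 512)
VGG_BLOCK_DEPTHS = (2, 2, 3, 3, 3)
BLOCK_STRIDES = (1, 2, 4, 8, 16)
MIN_INPUT_SIZE = 32

# standard pretrained-VGG normalization constants
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


def block_widths(width_multiplier: float) -> tuple[int, ...]:
    if not 0.0 < width_multiplier <= 1.0:
        raise ValueError(f"width_multiplier must be in (0, 1], got {width_multiplier}")
    return tuple(max(8, round(c * width_multiplier)) for c in VGG_BLOCK_WIDTHS)


@dataclass
class FeatureBundle:
    """Backbone activations split into low- and high-level groups."""

    low: list  # block-1, block-2 taps (Tensor), strides 1, 2
    high: list  # block-3..5 taps, strides 4, 8, 16
    strides: tuple[int, ...]
    width_multiplier: float

    @property
    def maps(self):
        return list(self.low) + list(self.high)


def normalize_image(pixels: np.ndarray) -> Tensor:
    """uint8 HWC RGB -> normalized float NCHW tensor (batch of one)."""
    x = pixels.astype(np.float32) / 255.0
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return Tensor(x.transpose(2, 0, 1)[None])


class VGGBackbone:
    """Five conv blocks; returns all five taps as a FeatureBundle."""

    def __init__(self, width_multiplier: float = 1.0, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.width_multiplier = float(width_multiplier)
        widths = block_widths(width_multiplier)
        self.blocks = []
        cin = 3
        for width, depth in zip(widths, VGG_BLOCK_DEPTHS):
            convs = []
            for _ in range(depth):
                convs.append(_nn.Conv2d(cin, width, 3, rng))
                cin = width
            self.blocks.append(convs)
        self.widths = widths

    def params(self):
        return [p for block in self.blocks for conv in block for p in conv.params()]

    def named_params(self):
        out = {}
        for bi, block in enumerate(self.blocks, start=1):
            for ci, conv in enumerate(block, start=1):
                out[f"backbone.block{bi}.conv{ci}.w"] = conv.w
                out[f"backbone.block{bi}.conv{ci}.b"] = conv.b
        return out

    def forward(self, x: Tensor) -> FeatureBundle:
        h, w = x.shape[2], x.shape[3]
        if h < MIN_INPUT_SIZE or w < MIN_INPUT_SIZE:
            raise ValueError(
                f"input must be at least {MIN_INPUT_SIZE}x{MIN_INPUT_SIZE}, got {h}x{w}"
            )
        taps = []
        for bi, block in enumerate(self.blocks):
            for conv in block:
                x = _nn.relu(conv(x))
            taps.append(x)
            if bi < 4:  # pool after blocks 1-4 only
                x = _nn.maxpool2x2(x)
        return FeatureBundle(
            low=taps[:2], high=taps[2:], strides=BLOCK_STRIDES,
            width_multiplier=self.width_multiplier,
        )

    def __call__(self, pixels: np.ndarray) -> FeatureBundle:
        return self.forward(normalize_image(pixels))


def extract_features(image, width_multiplier: float = 1.0,
                     backbone: VGGBackbone | None = None) -> FeatureBundle:
    """Run the backbone on an ImageSample (or raw HWC uint8 array).

    With no ``backbone`` supplied, a fresh seeded one is built, so the call
    is deterministic for fixed arguments.
    """
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    if backbone is None:
        backbone = VGGBackbone(width_multiplier, np.random.default_rng(0))
    return backbone(pixels)
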