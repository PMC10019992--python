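"""Feature fusion: multi-scale atrous blocks (MSMR), spatial attention on
low-level features, channel attention on high-level features, alignment to a
common stride-8 grid, and an original-image residual.

The fused map is the elementwise sum of 1x1-projected, bilinearly resampled
per-tap pathways; when enabled, a 1x1 projection of the normalized input
image is added on the same grid, so the network literally learns a residual
on top of the raw image.

Ablation presets mirror the published strategy ladder:

========  =============================  ==============
preset    feature pathway                postprocessing
========  =============================  ==============
p2pnet    H                              off
update1   H                              on
update2   H + L                          on
update3   H + L + MSMR                   on
update4   H + SAL + MSMR                 on
update5   H + SAL + MSMR + OI            on
update6   CAH + SAL + MSMR + OI          on
========  =============================  ==============

(H/L: high/low-level features; SAL: spatially attended low-level features;
CAH: channel-attended high-level features; OI: original-image residual.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Tensor
from .backbone import FeatureBundle, normalize_image


@dataclass
class FusionConfig:
    dilation_rates: list = field(default_factory=lambda: [1, 3, 5, 7])
    use_low: bool = False
    use_high: bool = True
    use_msmr: bool = False
    use_spatial_attention: bool = False
    use_channel_attention: bool = False
    use_original_image: bool = False
    fused_channels: int = 256
    fusion_stride: int = 8
    spatial_kernel: int = 7
    channel_reduction: int = 16

    def __post_init__(self):
        rates = list(self.dilation_rates)
        if not rates:
            raise ValueError("dilation_rates must be nonempty")
        if any(r < 1 for r in rates):
            raise ValueError(f"dilation rates must be >= 1, got {rates}")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError(f"dilation rates must be strictly increasing, got {rates}")
        if not (self.use_low or self.use_high or self.use_spatial_attention):
            raise ValueError("fusion config selects no feature maps")
        self.dilation_rates = rates

    @property
    def low_selected(self) -> bool:
        # SAL implies the low-level pathway is present (in attended form)
        return self.use_low or self.use_spatial_attention


_PRESET_FLAGS = {
    "p2pnet": {},
    "update1": {},
    "update2": {"use_low": True},
    "update3": {"use_low": True, "use_msmr": True},
    "update4": {"use_low": True, "use_msmr": True, "use_spatial_attention": True},
    "update5": {"use_low": True, "use_msmr": True, "use_spatial_attention": True,
                "use_original_image": True},
    "update6": {"use_low": True, "use_msmr": True, "use_spatial_attention": True,
                "use_original_image": True, "use_channel_attention": True},
}

# whether duplicate-merging postprocessing is on by default for each preset
PRESET_POSTPROCESSING = {name: name != "p2pnet" for name in _PRESET_FLAGS}

PRESET_NAMES = tuple(_PRESET_FLAGS)


def preset_config(name: str, **overrides) -> FusionConfig:
    """Build the FusionConfig for a named ablation preset."""
    try:
        flags = _PRESET_FLAGS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESET_FLAGS)}"
        ) from None
    return FusionConfig(**{**flags, **overrides})


def effective_receptive_field(kernel: int, dilation: int) -> int:
    """Span of a dilated kernel: k + (k-1)(d-1)."""
    return kernel + (kernel - 1) * (dilation - 1)


class MSMRBlock:
    """Parallel 3x3 atrous branches (one per dilation rate), concatenated and
    projected back to the input channel count.

    Branches and projection are linear; the surrounding pathway applies the
    nonlinearity.  With a single rate and an identity-initialized projection
    the block reduces exactly to one plain (dilated) 3x3 convolution.
    """

    def __init__(self, channels: int, rates, rng):
        if any(r < 1 for r in rates):
            raise ValueError(f"dilation rates must be >= 1, got {list(rates)}")
        self.rates = list(rates)
        self.branches = [_nn.Conv2d(channels, channels, 3, rng, dilation=r)
                         for r in self.rates]
        self.project = _nn.Conv2d(channels * len(self.rates), channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        outs = [conv(x) for conv in self.branches]
        cat = outs[0] if len(outs) == 1 else _nn.concat(outs, axis=1)
        return self.project(cat)

    def params(self):
        return [p for c in self.branches for p in c.params()] + self.project.params()


def msmr_block(feature: Tensor, rates, rng=None) -> Tensor:
    """Functional form: apply a freshly initialized MSMR block."""
    rng = rng if rng is not None else np.random.default_rng(0)
    feature = feature if isinstance(feature, Tensor) else Tensor(feature)
    return MSMRBlock(feature.shape[1], rates, rng)(feature)


class SpatialAttention:
    """Channel-pooled (mean & max) statistics -> conv -> sigmoid gate in
    [0, 1] per location; the input is multiplied by the gate.

    The statistics map is replicate-padded before the convolution so a
    spatially constant input yields a spatially constant gate (no border
    artifact from zero padding)."""

    def __init__(self, rng, kernel: int = 7):
        self.kernel = kernel
        self.conv = _nn.Conv2d(2, 1, kernel, rng)

    def attention_map(self, x: Tensor) -> Tensor:
        stats = _nn.concat([_nn.channel_mean(x), _nn.channel_max(x)], axis=1)
        padded = _nn.pad_edge(stats, self.kernel // 2)
        return _nn.sigmoid(
            _nn.conv2d(padded, self.conv.w, self.conv.b, padding=0))

    def __call__(self, x: Tensor) -> Tensor:
        return _nn.mul(x, self.attention_map(x))

    def params(self):
        return self.conv.params()


class ChannelAttention:
    """Squeeze-and-excitation gate: global average pool -> bottleneck ->
    sigmoid per-channel weights in [0, 1]."""

    def __init__(self, channels: int, rng, reduction: int = 16):
        hidden = max(1, channels // max(1, reduction))
        self.down = _nn.Conv2d(channels, hidden, 1, rng)
        self.up = _nn.Conv2d(hidden, channels, 1, rng)

    def channel_weights(self, x: Tensor) -> Tensor:
        squeezed = _nn.global_avg_pool(x)
        return _nn.sigmoid(self.up(_nn.relu(self.down(squeezed))))

    def __call__(self, x: Tensor) -> Tensor:
        return _nn.mul(x, self.channel_weights(x))

    def params(self):
        return self.down.params() + self.up.params()


def spatial_attention(feature, rng=None, kernel: int = 7) -> Tensor:
    rng = rng if rng is not None else np.random.default_rng(0)
    feature = feature if isinstance(feature, Tensor) else Tensor(feature)
    return SpatialAttention(rng, kernel)(feature)


def channel_attention(feature, rng=None, reduction: int = 16) -> Tensor:
    rng = rng if rng is not None else np.random.default_rng(0)
    feature = feature if isinstance(feature, Tensor) else Tensor(feature)
    return ChannelAttention(feature.shape[1], rng, reduction)(feature)


class FusionModule:
    """Per-tap MSMR + attention, 1x1 projection, alignment to the fusion
    grid, summation, and the optional original-image residual."""

    def __init__(self, tap_channels, config: FusionConfig, rng):
        self.config = config
        c = config.fused_channels
        self.low_channels = tap_channels[:2]
        self.high_channels = tap_channels[2:]
        self.msmr_low, self.msmr_high = [], []
        self.proj_low, self.proj_high = [], []
        if config.use_msmr:
            if config.low_selected:
                self.msmr_low = [MSMRBlock(ch, config.dilation_rates, rng)
                                 for ch in self.low_channels]
            self.msmr_high = [MSMRBlock(ch, config.dilation_rates, rng)
                              for ch in self.high_channels]
        self.spatial = (SpatialAttention(rng, config.spatial_kernel)
                        if config.use_spatial_attention else None)
        self.channel = ([ChannelAttention(ch, rng, config.channel_reduction)
                         for ch in self.high_channels]
                        if config.use_channel_attention else None)
        if config.low_selected:
            self.proj_low = [_nn.Conv2d(ch, c, 1, rng) for ch in self.low_channels]
        if config.use_high:
            self.proj_high = [_nn.Conv2d(ch, c, 1, rng) for ch in self.high_channels]
        self.image_proj = (_nn.Conv2d(3, c, 1, rng)
                           if config.use_original_image else None)

    def params(self):
        ps = []
        for group in (self.msmr_low, self.msmr_high, self.proj_low, self.proj_high):
            for m in group:
                ps.extend(m.params())
        if self.spatial is not None:
            ps.extend(self.spatial.params())
        if self.channel is not None:
            for m in self.channel:
                ps.extend(m.params())
        if self.image_proj is not None:
            ps.extend(self.image_proj.params())
        return ps

    def fuse(self, bundle: FeatureBundle, image=None) -> Tensor:
        cfg = self.config
        # fusion grid size from the stride-1 input dimensions
        ref = bundle.low[0]
        h, w = ref.shape[2], ref.shape[3]
        grid = (math.ceil(h / cfg.fusion_stride), math.ceil(w / cfg.fusion_stride))

        fused = None
        if cfg.low_selected:
            for i, tap in enumerate(bundle.low):
                x = tap
                if cfg.use_msmr:
                    x = _nn.relu(self.msmr_low[i](x))
                if self.spatial is not None:
                    x = self.spatial(x)
                x = _nn.resize_bilinear(self.proj_low[i](x), grid)
                fused = x if fused is None else _nn.add(fused, x)
        if cfg.use_high:
            for i, tap in enumerate(bundle.high):
                x = tap
                if cfg.use_msmr:
                    x = _nn.relu(self.msmr_high[i](x))
                if self.channel is not None:
                    x = self.channel[i](x)
                x = _nn.resize_bilinear(self.proj_high[i](x), grid)
                fused = x if fused is None else _nn.add(fused, x)
        if self.image_proj is not None:
            if image is None:
                raise ValueError("use_original_image requires the input image")
            img = image if isinstance(image, Tensor) else normalize_image(
                image.pixels if hasattr(image, "pixels") else np.asarray(image))
            fused = _nn.add(fused, self.image_proj(_nn.resize_bilinear(img, grid)))
        return fused

    __call__ = fuse


def fuse(bundle: FeatureBundle, image, config: FusionConfig, rng=None) -> Tensor:
    """Functional fusion with a freshly initialized (seeded) module."""
    rng = rng if rng is not None else np.random.default_rng(0)
    tap_channels = [m.shape[1] for m in bundle.maps]
    return FusionModule(tap_channels, config, rng).fuse(bundle, image)
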