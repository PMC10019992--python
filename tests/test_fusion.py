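"""MSMR blocks, attention gates, fusion pathway and ablation presets."""

import math

import numpy as np
import pytest

import seedpoint as sp
from seedpoint import _nn
from seedpoint._nn import Tensor
from seedpoint.fusion import MSMRBlock, SpatialAttention, ChannelAttention


def _feature(shape, seed=0):
    return Tensor(np.random.default_rng(seed).normal(0, 1, shape))


def test_msmr_preserves_spatial_shape():
    x = _feature((1, 6, 16, 16))
    block = MSMRBlock(6, [1, 3, 5, 7], np.random.default_rng(0))
    out = block(x)
    assert out.data.shape == (1, 6, 16, 16)


def test_msmr_rejects_invalid_rate():
    with pytest.raises(ValueError):
        MSMRBlock(4, [0, 3], np.random.default_rng(0))
    with pytest.raises(ValueError):
        sp.FusionConfig(dilation_rates=[1, 3, 3])
    with pytest.raises(ValueError):
        sp.FusionConfig(dilation_rates=[])


def test_effective_receptive_field_of_dilated_kernel():
    # 3x3 kernel at dilation 7 spans 3 + 2*6 = 15 pixels
    assert sp.effective_receptive_field(3, 7) == 15
    assert sp.effective_receptive_field(3, 1) == 3


def test_msmr_single_rate_identity_projection_equals_plain_conv():
    """With one branch and an identity 1x1 projection, the block reduces to
    the branch's plain 3x3 convolution (independent direct instantiation)."""
    rng = np.random.default_rng(3)
    c = 5
    block = MSMRBlock(c, [1], np.random.default_rng(1))
    block.project.w.data = np.eye(c, dtype=np.float32).reshape(c, c, 1, 1)
    block.project.b.data[:] = 0
    x = _feature((1, c, 10, 10), seed=4)
    direct = _nn.conv2d(x, block.branches[0].w, block.branches[0].b)
    np.testing.assert_allclose(block(x).data, direct.data, rtol=1e-5, atol=1e-5)


def test_spatial_attention_bounds_and_gating():
    x = _feature((1, 4, 9, 9), seed=5)
    att = SpatialAttention(np.random.default_rng(0))
    amap = att.attention_map(x).data
    assert amap.shape == (1, 1, 9, 9)
    assert (amap >= 0).all() and (amap <= 1).all()
    # spatially constant input -> spatially constant attention
    const = Tensor(np.ones((1, 4, 7, 7), dtype=np.float32) * 2.0)
    amap_c = att.attention_map(const).data
    assert np.ptp(amap_c) < 1e-6
    # multiplicative gate: zero input stays zero
    zero = Tensor(np.zeros((1, 4, 7, 7), dtype=np.float32))
    assert np.all(att(zero).data == 0)


def test_channel_attention_bounds_permutation_and_gating():
    rng = np.random.default_rng(6)
    c = 8
    att = ChannelAttention(c, np.random.default_rng(0), reduction=4)
    x = _feature((1, c, 6, 6), seed=7)
    w = att.channel_weights(x).data.ravel()
    assert (w >= 0).all() and (w <= 1).all()
    # permuting input channels with correspondingly permuted weights permutes w
    perm = rng.permutation(c)
    att_p = ChannelAttention(c, np.random.default_rng(0), reduction=4)
    att_p.down.w.data = att.down.w.data[:, perm]
    att_p.up.w.data = att.up.w.data[perm]
    att_p.up.b.data = att.up.b.data[perm]
    xp = Tensor(x.data[:, perm])
    wp = att_p.channel_weights(xp).data.ravel()
    np.testing.assert_allclose(wp, w[perm], rtol=1e-5, atol=1e-6)
    zero = Tensor(np.zeros((1, c, 5, 5), dtype=np.float32))
    assert np.all(att(zero).data == 0)


@pytest.mark.parametrize("preset", sp.PRESET_NAMES)
def test_every_preset_constructs_and_fuses(preset, small_image):
    cfg = sp.preset_config(preset, fused_channels=16)
    bundle = sp.extract_features(small_image, width_multiplier=0.125)
    fused = sp.fuse(bundle, small_image, cfg)
    assert fused.data.shape == (1, 16, 8, 8)
    assert np.isfinite(fused.data).all()


def test_fusion_output_shape_independent_of_flags(small_image):
    """Spatial size depends only on input size and fusion stride."""
    bundle = sp.extract_features(small_image, width_multiplier=0.125)
    shapes = set()
    for preset in sp.PRESET_NAMES:
        cfg = sp.preset_config(preset, fused_channels=16)
        shapes.add(sp.fuse(bundle, small_image, cfg).data.shape)
    assert shapes == {(1, 16, 8, 8)}


def test_original_image_residual_with_zero_projection_is_noop(small_image):
    bundle = sp.extract_features(small_image, width_multiplier=0.125)
    tap_channels = [m.shape[1] for m in bundle.maps]
    from seedpoint.fusion import FusionModule

    cfg_on = sp.preset_config("update5", fused_channels=16)
    rng_state = np.random.default_rng(9)
    mod = FusionModule(tap_channels, cfg_on, rng_state)
    with_oi = mod.fuse(bundle, small_image).data
    mod.image_proj.w.data[:] = 0
    mod.image_proj.b.data[:] = 0
    zeroed = mod.fuse(bundle, small_image).data
    cfg_off = sp.preset_config("update4", fused_channels=16)
    # rebuild identically-seeded module without OI: same weights for shared parts
    mod_off = FusionModule(tap_channels, cfg_off, np.random.default_rng(9))
    without = mod_off.fuse(bundle, small_image).data
    np.testing.assert_allclose(zeroed, without, rtol=1e-5, atol=1e-6)


def test_fusion_grid_follows_stride_for_odd_sizes():
    rng = np.random.default_rng(11)
    image = rng.integers(0, 256, (100, 68, 3), dtype=np.uint8)
    bundle = sp.extract_features(image, width_multiplier=0.125)
    fused = sp.fuse(bundle, image, sp.preset_config("update6", fused_channels=8))
    assert fused.data.shape[2:] == (math.ceil(100 / 8), math.ceil(68 / 8))


def test_config_selecting_no_maps_is_rejected():
    with pytest.raises(ValueError, match="no feature maps"):
        sp.FusionConfig(use_low=False, use_high=False)
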