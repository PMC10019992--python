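"""The synthetic dot-annotated image generator."""

import json

import numpy as np
import pytest

import seedpoint as sp
from seedpoint.synthetic import generate_sample


def _config(**kw):
    base = dict(image_size=(96, 96), seeds_per_image=(5, 5), rng_seed=3)
    base.update(kw)
    return sp.SynthConfig(**base)


def test_fixed_count_no_overlap_yields_exact_annotation():
    cfg = _config(overlap_level=0.0, distractor_rate=0.0)
    sample, records = generate_sample(cfg, 0)
    assert sample.annotation.count == 5
    pts = sample.annotation.points
    assert (pts[:, 0] >= 0).all() and (pts[:, 0] < 96).all()
    assert (pts[:, 1] >= 0).all() and (pts[:, 1] < 96).all()
    assert sample.pixels.dtype == np.uint8 and sample.pixels.shape == (96, 96, 3)


def test_generation_is_deterministic():
    cfg = _config(distractor_rate=0.5)
    a, rec_a = generate_sample(cfg, 7)
    b, rec_b = generate_sample(cfg, 7)
    np.testing.assert_array_equal(a.pixels, b.pixels)
    np.testing.assert_array_equal(a.annotation.points, b.annotation.points)
    assert rec_a == rec_b


def test_different_indices_differ():
    cfg = _config()
    a, _ = generate_sample(cfg, 0)
    b, _ = generate_sample(cfg, 1)
    assert not np.array_equal(a.pixels, b.pixels)


def test_count_conservation_against_metadata():
    """Annotated points == rendered seed blobs with visible fraction >= 0.1."""
    cfg = _config(seeds_per_image=(15, 25), overlap_level=0.8, rng_seed=5)
    for index in range(5):
        sample, records = generate_sample(cfg, index)
        visible_seeds = [r for r in records
                         if r.kind == "seed"
                         and r.visible_fraction >= cfg.occlusion_visibility_threshold]
        assert sample.annotation.count == len(visible_seeds)
        annotated = {r.center for r in records if r.annotated}
        assert annotated == {tuple(p) for p in sample.annotation.points}


def test_heavy_overlap_hides_seeds_below_visibility_threshold():
    """With enough tightly packed seeds, some fall below 10% visibility and
    are recorded in metadata but excluded from the annotation."""
    cfg = _config(seeds_per_image=(60, 60), overlap_level=1.0,
                  seed_radius_mean=9.0, rng_seed=1)
    found_hidden = False
    for index in range(8):
        sample, records = generate_sample(cfg, index)
        hidden = [r for r in records if r.kind == "seed" and not r.annotated]
        if hidden:
            found_hidden = True
            assert all(r.visible_fraction < cfg.occlusion_visibility_threshold
                       for r in hidden)
            assert sample.annotation.count < len(
                [r for r in records if r.kind == "seed"])
            break
    assert found_hidden, "packing never occluded a seed below threshold"


def test_distractors_change_pixels_but_not_annotations():
    quiet = _config(distractor_rate=0.0, rng_seed=9)
    noisy = _config(distractor_rate=2.0, rng_seed=9)
    a, rec_a = generate_sample(quiet, 0)
    b, rec_b = generate_sample(noisy, 0)
    assert not any(r.kind == "distractor" for r in rec_a)
    assert any(r.kind == "distractor" for r in rec_b)
    assert not any(r.annotated for r in rec_b if r.kind == "distractor")
    np.testing.assert_array_equal(a.annotation.points, b.annotation.points)
    assert not np.array_equal(a.pixels, b.pixels)


def test_generate_dataset_split_manifest_and_roundtrip(tmp_path):
    cfg = _config(seeds_per_image=(3, 8))
    out = tmp_path / "ds"
    train, test = sp.generate_dataset(cfg, 10, split=(0.5, 0.5), out_dir=out)
    assert len(train) == 5 and len(test) == 5
    assert {s.image_id for s in train}.isdisjoint({s.image_id for s in test})

    manifest = json.loads((out / "manifest.json").read_text())
    total = sum(v["count"] for v in manifest["images"].values())
    assert total == sum(s.annotation.count for s in train + test)

    # reload through annotations_io and compare counts exactly
    reloaded = sp.load_dataset(out / "train" / "images",
                               out / "train" / "annotations.csv")
    assert [s.annotation.count for s in reloaded] == \
        [s.annotation.count for s in sorted(train, key=lambda s: s.image_id)]

    with pytest.raises(FileExistsError):
        sp.generate_dataset(cfg, 4, out_dir=out)
    # regeneration with overwrite reproduces identical annotations
    train2, _ = sp.generate_dataset(cfg, 10, split=(0.5, 0.5), out_dir=out,
                                    overwrite=True)
    for s1, s2 in zip(train, train2):
        np.testing.assert_array_equal(s1.annotation.points, s2.annotation.points)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)


def test_bad_split_rejected(tmp_path):
    with pytest.raises(ValueError):
        sp.generate_dataset(_config(), 4, split=(0.6, 0.6), out_dir=tmp_path / "x")


def test_config_validation():
    with pytest.raises(ValueError):
        _config(occlusion_visibility_threshold=0.0)
    with pytest.raises(ValueError):
        _config(overlap_level=1.5)
    with pytest.raises(ValueError):
        _config(distractor_rate=-0.1)
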