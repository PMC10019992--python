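"""Synthetic dot-annotated "plant" images.

The generator reproduces the statistical hazards of field imagery of
seed-bearing plants rather than their appearance: variable per-image seed
counts, accession-dependent seed-size variation (a per-image size factor on
top of per-seed noise), heavy seed overlap, textured background, and
unannotated distractor seeds in the left/right margins standing in for
neighboring plants that appear in pixels but never in labels.

Seeds are anti-aliased shaded ellipses drawn back-to-front; later blobs
overdraw earlier ones.  A seed is annotated only if at least
``occlusion_visibility_threshold`` of its area survives overdrawing
(default 0.1 — the one-tenth-visible annotation policy).  Every blob,
annotated or not, is recorded in per-image metadata for diagnostics.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import ImageSample, PointAnnotation, save_annotations, save_image


@dataclass
class SynthConfig:
    image_size: tuple = (256, 256)  # (H, W)
    seeds_per_image: tuple = (20, 80)  # inclusive range
    seed_radius_mean: float = 6.0  # px, population mean
    seed_radius_accession_sd: float = 1.5  # per-image ("accession") spread
    seed_radius_noise_sd: float = 0.8  # per-seed spread
    overlap_level: float = 0.3  # fraction of seeds placed within one diameter
    distractor_rate: float = 0.15  # unannotated margin seeds per annotated seed
    occlusion_visibility_threshold: float = 0.1
    background_texture: float = 0.5  # 0 = flat, 1 = strong clutter
    margin_fraction: float = 0.12  # width of each distractor strip
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.occlusion_visibility_threshold <= 1.0:
            raise ValueError("occlusion_visibility_threshold must be in (0, 1]")
        if not 0.0 <= self.overlap_level <= 1.0:
            raise ValueError("overlap_level must be in [0, 1]")
        if self.distractor_rate < 0:
            raise ValueError("distractor_rate must be >= 0")


@dataclass
class BlobRecord:
    center: tuple
    radius: float
    annotated: bool
    visible_fraction: float
    kind: str  # "seed" or "distractor"


def _render_background(rng, h, w, texture):
    base = np.array([0.36, 0.33, 0.24]) + rng.normal(0, 0.03, 3)
    img = np.broadcast_to(base, (h, w, 3)).copy()
    if texture > 0:
        # coarse mottling: low-res noise bilinearly upsampled
        gh, gw = max(2, h // 16), max(2, w // 16)
        coarse = rng.normal(0, 0.10 * texture, (gh, gw, 3))
        ys = np.clip((np.arange(h) + 0.5) * gh / h - 0.5, 0, gh - 1)
        xs = np.clip((np.arange(w) + 0.5) * gw / w - 0.5, 0, gw - 1)
        y0 = np.floor(ys).astype(int); y1 = np.minimum(y0 + 1, gh - 1)
        x0 = np.floor(xs).astype(int); x1 = np.minimum(x0 + 1, gw - 1)
        fy = (ys - y0)[:, None, None]; fx = (xs - x0)[None, :, None]
        up = (coarse[y0][:, x0] * (1 - fy) * (1 - fx)
              + coarse[y0][:, x1] * (1 - fy) * fx
              + coarse[y1][:, x0] * fy * (1 - fx)
              + coarse[y1][:, x1] * fy * fx)
        img += up
        # fine grain plus a few stem-like streaks
        img += rng.normal(0, 0.03 * texture, (h, w, 3))
        for _ in range(int(6 * texture)):
            x = rng.uniform(0, w)
            slope = rng.uniform(-0.4, 0.4)
            width = rng.uniform(1.0, 2.5)
            xs_line = x + slope * np.arange(h)
            dist = np.abs(np.arange(w)[None, :] - xs_line[:, None])
            streak = np.clip(1.0 - dist / width, 0, 1)
            img += streak[..., None] * np.array([0.05, 0.06, 0.02]) * texture
    return np.clip(img, 0, 1)


def _draw_blob(img, label, blob_id, cx, cy, r, rng):
    """Draw one shaded ellipse; returns its full (pre-occlusion) pixel area."""
    h, w = label.shape
    aspect = rng.uniform(0.75, 1.0)
    theta = rng.uniform(0, math.pi)
    rx, ry = r, r * aspect
    pad = int(math.ceil(r)) + 2
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return 0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / rx
    v = (-dx * st + dy * ct) / ry
    dd = np.sqrt(u * u + v * v)
    alpha = np.clip((1.0 - dd) / 0.15, 0, 1)  # anti-aliased rim
    inside = dd <= 1.0
    if not inside.any():
        return 0
    base = np.array([0.78, 0.68, 0.38]) + rng.normal(0, 0.04, 3)
    shading = (1.0 - 0.45 * dd)[..., None]
    # small specular highlight offset toward the upper left
    hl = np.exp(-(((u + 0.3) ** 2 + (v + 0.3) ** 2) / 0.18))[..., None]
    color = np.clip(base * shading + 0.25 * hl, 0, 1)
    a = alpha[..., None]
    img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - a) + color * a
    label[y0:y1, x0:x1][inside] = blob_id
    return int(inside.sum())


def generate_sample(config: SynthConfig, index: int):
    """Render one image; returns (ImageSample, [BlobRecord, ...]).

    Deterministic in (config.rng_seed, index).  Seeds that cannot be placed
    within the attempt budget are dropped and the recorded count reflects
    what was actually rendered.

    Distractors draw from random streams independent of the seed streams, so
    changing ``distractor_rate`` changes pixels but never the annotations.
    """
    def stream(tag):
        return np.random.default_rng(
            np.random.SeedSequence([config.rng_seed, index, tag]))

    rng_bg, rng_seeds, rng_distract, rng_draw_s, rng_draw_d = (
        stream(0), stream(1), stream(2), stream(3), stream(4))
    h, w = config.image_size
    img = _render_background(rng_bg, h, w, config.background_texture)
    label = np.zeros((h, w), dtype=np.int32)

    lo, hi = config.seeds_per_image
    n_seeds = int(rng_seeds.integers(lo, hi + 1))
    # accession effect: one size factor per image
    accession_r = max(
        2.0, rng_seeds.normal(config.seed_radius_mean, config.seed_radius_accession_sd)
    )
    margin = max(4, int(config.margin_fraction * w))

    # --- distractors in the margin strips (rendered first, never annotated)
    blobs = []
    n_distract = int(rng_distract.poisson(config.distractor_rate * n_seeds))
    for _ in range(n_distract):
        r = max(1.5, rng_distract.normal(accession_r, config.seed_radius_noise_sd))
        side = rng_distract.integers(0, 2)
        cx = (rng_distract.uniform(2, margin) if side == 0
              else rng_distract.uniform(w - margin, w - 2))
        cy = rng_distract.uniform(2, h - 2)
        blobs.append((cx, cy, r, "distractor"))

    # --- annotated seeds in the central zone, with controlled overlap
    placed = []
    x_lo, x_hi = margin + 2, w - margin - 2
    for _ in range(n_seeds):
        r = max(1.5, rng_seeds.normal(accession_r, config.seed_radius_noise_sd))
        pos = None
        for _attempt in range(50):
            if placed and rng_seeds.random() < config.overlap_level:
                ax, ay, ar = placed[int(rng_seeds.integers(0, len(placed)))]
                ang = rng_seeds.uniform(0, 2 * math.pi)
                dist = rng_seeds.uniform(0.3, 1.0) * (r + ar)
                cx, cy = ax + dist * math.cos(ang), ay + dist * math.sin(ang)
            else:
                cx = rng_seeds.uniform(x_lo, x_hi)
                cy = rng_seeds.uniform(2 + r, h - 2 - r)
            if x_lo <= cx <= x_hi and 0 < cy < h:
                pos = (cx, cy)
                break
        if pos is None:
            continue  # truthfully dropped
        placed.append((pos[0], pos[1], r))
        blobs.append((pos[0], pos[1], r, "seed"))

    # --- rasterize in z-order (distractors first, then seeds as placed)
    full_area = np.zeros(len(blobs), dtype=np.int64)
    for i, (cx, cy, r, kind) in enumerate(blobs):
        draw_rng = rng_draw_d if kind == "distractor" else rng_draw_s
        full_area[i] = _draw_blob(img, label, i + 1, cx, cy, r, draw_rng)

    visible = np.bincount(label.ravel(), minlength=len(blobs) + 1)[1:]
    records, points = [], []
    for i, (cx, cy, r, kind) in enumerate(blobs):
        frac = float(visible[i] / full_area[i]) if full_area[i] else 0.0
        annotated = (
            kind == "seed"
            and frac >= config.occlusion_visibility_threshold
            and 0 <= cx < w and 0 <= cy < h
        )
        if annotated:
            points.append((cx, cy))
        records.append(BlobRecord((float(cx), float(cy)), float(r),
                                  annotated, frac, kind))

    image_id = f"synth_{index:05d}"
    pixels = (img * 255).round().astype(np.uint8)
    annotation = PointAnnotation(image_id, np.asarray(points, dtype=np.float64))
    return ImageSample(image_id, pixels, annotation), records


def generate_samples(config: SynthConfig, n_images: int, start_index: int = 0):
    """Generate a list of samples (in-memory convenience)."""
    out = []
    for i in range(start_index, start_index + n_images):
        sample, _ = generate_sample(config, i)
        out.append(sample)
    return out


def generate_dataset(config: SynthConfig, n_images: int, split=(0.5, 0.5),
                     out_dir="synthetic_dataset", overwrite: bool = False):
    """Render a train/test dataset to disk in the package's native formats.

    Layout: ``<out_dir>/{train,test}/images/*.png`` plus
    ``annotations.csv`` per split and a ``manifest.json`` recording the
    config, the split, and per-image counts for exact regeneration.
    """
    if not math.isclose(split[0] + split[1], 1.0, abs_tol=1e-9):
        raise ValueError(f"split fractions must sum to 1, got {split}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (use overwrite)")

    n_train = int(round(n_images * split[0]))
    splits = {"train": range(0, n_train), "test": range(n_train, n_images)}
    manifest = {
        "config": dataclasses.asdict(config),
        "n_images": n_images,
        "split": list(split),
        "images": {},
    }
    datasets = {}
    for name, indices in splits.items():
        split_dir = out_dir / name
        (split_dir / "images").mkdir(parents=True, exist_ok=True)
        samples = []
        for i in indices:
            sample, _ = generate_sample(config, i)
            save_image(sample.pixels, split_dir / "images" / f"{sample.image_id}.png")
            samples.append(sample)
            manifest["images"][sample.image_id] = {
                "split": name, "count": sample.annotation.count,
            }
        save_annotations(samples, split_dir / "annotations.csv")
        datasets[name] = samples
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return datasets["train"], datasets["test"]
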