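"""The full point-based seed counter: backbone -> fusion -> heads, plus
checkpoint serialization.

The network is fully convolutional, so any image at least 32 px on a side —
including uncropped field-scale images — runs unchanged; the proposal count
scales with the stride-8 grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .annotations import MergedPrediction
from .backbone import VGGBackbone, normalize_image
from .fusion import FusionConfig, FusionModule, preset_config
from .heads import PointHeads, ProposalSet, decode
from .postprocess import merge_points

CHECKPOINT_VERSION = "seedpoint-checkpoint-1"


@dataclass
class ModelConfig:
    preset: str = "update6"
    width_multiplier: float = 1.0
    fused_channels: int = 256
    head_channels: int = 256
    stride: int = 8
    points_per_cell: int = 4
    score_threshold: float = 0.5
    nominal_seed_diameter: float = 12.0  # px; merge radius defaults to half
    fusion_overrides: dict = field(default_factory=dict)
    rng_seed: int = 0

    @property
    def merge_radius(self) -> float:
        return 0.5 * self.nominal_seed_diameter

    def fusion_config(self) -> FusionConfig:
        return preset_config(
            self.preset,
            fused_channels=self.fused_channels,
            fusion_stride=self.stride,
            **self.fusion_overrides,
        )


class SeedCounter:
    """End-to-end network producing a ProposalSet per image."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        self.backbone = VGGBackbone(config.width_multiplier, rng)
        self.fusion = FusionModule(list(self.backbone.widths),
                                   config.fusion_config(), rng)
        self.heads = PointHeads(config.fused_channels, config.head_channels,
                                config.points_per_cell, rng)

    # -- parameters -------------------------------------------------------
    def params(self):
        return (self.backbone.params() + self.fusion.params()
                + self.heads.params())

    def backbone_params(self):
        return self.backbone.params()

    def head_params(self):
        return self.fusion.params() + self.heads.params()

    # -- inference / training forward -------------------------------------
    def forward(self, pixels: np.ndarray) -> ProposalSet:
        x = normalize_image(pixels)
        bundle = self.backbone.forward(x)
        fused = self.fusion.fuse(bundle, image=x)
        h, w = pixels.shape[:2]
        return self.heads.predict(fused, (h, w), self.config.stride)

    __call__ = forward

    def predict_points(self, pixels: np.ndarray, image_id: str = "",
                       score_threshold: float | None = None,
                       merge_radius: float | None = None,
                       merge: bool = True) -> MergedPrediction:
        """Full inference: forward, decode, optional duplicate merging."""
        thr = (self.config.score_threshold if score_threshold is None
               else score_threshold)
        radius = self.config.merge_radius if merge_radius is None else merge_radius
        with _nn.no_grad():
            proposals = self.forward(pixels)
        pts = decode(proposals, thr)
        if merge and radius > 0:
            merged = merge_points(pts, radius, image_id=image_id)
            return merged
        return MergedPrediction(image_id, pts, 0.0, len(pts))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _named_params(model: SeedCounter) -> dict:
    names = dict(model.backbone.named_params())
    for i, p in enumerate(model.fusion.params()):
        names[f"fusion.p{i}"] = p
    for i, p in enumerate(model.heads.params()):
        names[f"heads.p{i}"] = p
    return names


def save_checkpoint(model: SeedCounter, path, extra: dict | None = None) -> None:
    """Single-archive checkpoint: named weights + embedded config + version."""
    arrays = {name: p.data for name, p in _named_params(model).items()}
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "extra": extra or {},
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> SeedCounter:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"incompatible checkpoint: found version {meta.get('version')!r}, "
                f"this build reads {CHECKPOINT_VERSION!r}"
            )
        config = ModelConfig(**meta["config"])
        model = SeedCounter(config)
        named = _named_params(model)
        for name, param in named.items():
            if name not in archive:
                raise ValueError(f"checkpoint missing parameter {name!r}")
            stored = archive[name]
            if stored.shape != param.data.shape:
                raise ValueError(
                    f"checkpoint parameter {name!r} has shape {stored.shape}, "
                    f"model expects {param.data.shape}"
                )
            param.data = stored.astype(np.float32)
    return model
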