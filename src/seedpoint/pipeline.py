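"""Configuration-driven training, inference, evaluation and ablation.

Training iterates single-image steps (batch size 1 — the simplest correct
choice for variable-size images): forward pass, Hungarian matching of
proposals to ground-truth dots, combined classification/regression loss,
Adam update.  Everything is seeded; the same config and seed reproduce a
run bit-for-bit on one device.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .annotations import ImageSample, MergedPrediction
from .evaluation import count_mae, evaluate
from .fusion import PRESET_NAMES, PRESET_POSTPROCESSING
from .matching import hungarian_match, match_cost, point_loss
from .model import ModelConfig, SeedCounter, load_checkpoint, save_checkpoint


@dataclass
class RunConfig:
    """Everything needed to reproduce a training/evaluation run."""

    preset: str = "update6"
    width_multiplier: float = 1.0
    fused_channels: int = 256
    head_channels: int = 256
    stride: int = 8
    points_per_cell: int = 4
    score_threshold: float = 0.5
    nominal_seed_diameter: float = 12.0
    merge_radius: float | None = None  # default: half the nominal diameter
    merge: bool | None = None  # default: the preset's postprocessing column
    # loss
    tau: float = 0.5
    lambda_reg: float = 2e-4
    negative_weight: float = 0.5
    # optimizer
    learning_rate: float = 1e-4
    backbone_learning_rate: float = 1e-5
    epochs: int = 30
    # bookkeeping
    rng_seed: int = 0
    device: str = "cpu"
    localization_tau: float | None = None

    def __post_init__(self):
        if self.preset not in PRESET_NAMES:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {PRESET_NAMES}")

    def resolved_merge_radius(self) -> float:
        return (0.5 * self.nominal_seed_diameter
                if self.merge_radius is None else self.merge_radius)

    def resolved_merge(self) -> bool:
        return (PRESET_POSTPROCESSING[self.preset]
                if self.merge is None else self.merge)

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            preset=self.preset,
            width_multiplier=self.width_multiplier,
            fused_channels=self.fused_channels,
            head_channels=self.head_channels,
            stride=self.stride,
            points_per_cell=self.points_per_cell,
            score_threshold=self.score_threshold,
            nominal_seed_diameter=self.nominal_seed_diameter,
            rng_seed=self.rng_seed,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)


@dataclass
class TrainResult:
    model: SeedCounter
    history: list  # dicts: epoch, mean_cls, mean_reg, mean_total, val_mae
    checkpoint_path: Path | None
    initial_loss: float
    final_loss: float


def build_model(config: RunConfig) -> SeedCounter:
    return SeedCounter(config.model_config())


def train(config: RunConfig, train_samples: list[ImageSample],
          val_samples: list[ImageSample] | None = None,
          out_dir=None, log_every: int = 0,
          val_every: int = 5) -> TrainResult:
    """Train a model; returns it with the loss history.

    When ``out_dir`` is given, writes ``training_log.csv`` (epoch, step,
    cls, reg, total), ``run_config.yaml``, and the best-validation-MAE
    checkpoint ``best.npz`` (final weights in ``final.npz``).
    """
    if not train_samples:
        raise ValueError("training dataset is empty")
    model = build_model(config)
    from ._nn import Adam

    opt = Adam([
        (model.backbone_params(), config.backbone_learning_rate),
        (model.head_params(), config.learning_rate),
    ])
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 7]))

    out_dir = Path(out_dir) if out_dir is not None else None
    log_rows = []
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "run_config.yaml")

    history = []
    best_mae = math.inf
    best_path = None
    initial_loss = None
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(train_samples))
        cls_sum = reg_sum = tot_sum = 0.0
        for step, idx in enumerate(order):
            sample = train_samples[idx]
            proposals = model.forward(sample.pixels)
            cost = match_cost(proposals, sample.annotation, tau=config.tau)
            if not np.isfinite(cost).all():
                raise FloatingPointError(
                    f"non-finite proposals at epoch {epoch} step {step} "
                    f"(image {sample.image_id!r}); training diverged")
            match = hungarian_match(cost)
            loss = point_loss(proposals, sample.annotation, match,
                              lambda_reg=config.lambda_reg,
                              negative_weight=config.negative_weight)
            if not math.isfinite(loss.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {step} "
                    f"(image {sample.image_id!r}): cls={loss.classification_loss} "
                    f"reg={loss.regression_loss}")
            if initial_loss is None:
                initial_loss = loss.total
            opt.zero_grad()
            loss.total_tensor.backward()
            opt.step()
            cls_sum += loss.classification_loss
            reg_sum += loss.regression_loss
            tot_sum += loss.total
            log_rows.append([epoch, step, loss.classification_loss,
                             loss.regression_loss, loss.total])
            if log_every and step % log_every == 0:
                print(f"epoch {epoch} step {step}: total={loss.total:.4f}")

        n = len(order)
        row = {"epoch": epoch, "mean_cls": cls_sum / n, "mean_reg": reg_sum / n,
               "mean_total": tot_sum / n, "val_mae": None}
        run_val = val_samples and (
            epoch % val_every == val_every - 1 or epoch == config.epochs - 1)
        if run_val:
            preds = predict(model, val_samples,
                            merge=config.resolved_merge(),
                            merge_radius=config.resolved_merge_radius())
            row["val_mae"] = count_mae(
                [p.merged_count for p in preds],
                [s.annotation.count for s in val_samples])
            if out_dir is not None and row["val_mae"] < best_mae:
                best_mae = row["val_mae"]
                best_path = out_dir / "best.npz"
                save_checkpoint(model, best_path,
                                extra={"epoch": epoch, "val_mae": best_mae})
        history.append(row)

    final_loss = history[-1]["mean_total"]
    checkpoint_path = None
    if out_dir is not None:
        checkpoint_path = out_dir / "final.npz"
        save_checkpoint(model, checkpoint_path,
                        extra={"epochs": config.epochs})
        with open(out_dir / "training_log.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "step", "cls", "reg", "total"])
            writer.writerows(log_rows)
        if best_path is None:
            best_path = checkpoint_path
    return TrainResult(model, history, checkpoint_path,
                       float(initial_loss), float(final_loss))


def predict(model, images, merge_radius: float | None = None,
            score_threshold: float | None = None,
            merge: bool = True) -> list[MergedPrediction]:
    """Run the full pipeline on a list of ImageSamples (or a checkpoint path)."""
    if not isinstance(model, SeedCounter):
        model = load_checkpoint(model)
    out = []
    for sample in images:
        out.append(model.predict_points(
            sample.pixels, image_id=sample.image_id,
            score_threshold=score_threshold,
            merge_radius=merge_radius, merge=merge))
    return out


def evaluate_model(model, samples, merge: bool = True,
                   merge_radius: float | None = None,
                   score_threshold: float | None = None,
                   localization_tau: float | None = None):
    """Predict and score against the samples' own annotations."""
    preds = predict(model, samples, merge_radius=merge_radius,
                    score_threshold=score_threshold, merge=merge)
    pred_map = {p.image_id: p.points for p in preds}
    gt_map = {s.image_id: s.annotation.points for s in samples}
    radius = merge_radius
    if radius is None and isinstance(model, SeedCounter):
        radius = model.config.merge_radius
    tau = localization_tau if localization_tau is not None else (radius or 5.0)
    return evaluate(pred_map, gt_map, tau=tau)


def run_ablation(base_config: RunConfig, presets,
                 train_samples, test_samples, out_csv=None) -> list[dict]:
    """Train each preset once and evaluate with and without merging.

    Returns rows of (preset, postprocessing, mae, r_squared) in the ablation
    table's layout: one row per preset x {merge off, merge on}.
    """
    rows = []
    for preset in presets:
        cfg = dataclasses.replace(base_config, preset=preset)
        result = train(cfg, train_samples, val_samples=None)
        for merge in (False, True):
            report = evaluate_model(
                result.model, test_samples, merge=merge,
                merge_radius=cfg.resolved_merge_radius(),
                score_threshold=cfg.score_threshold)
            rows.append({
                "preset": preset,
                "postprocessing": "+" if merge else "-",
                "mae": report.mae,
                "r_squared": report.r_squared,
            })
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["preset", "postprocessing", "mae", "r_squared"])
            writer.writeheader()
            writer.writerows(rows)
    return rows


def load_ablation_table(path) -> list[dict]:
    with open(path, newline="") as fh:
        return [
            {"preset": r["preset"], "postprocessing": r["postprocessing"],
             "mae": float(r["mae"]), "r_squared": float(r["r_squared"])}
            for r in csv.DictReader(fh)
        ]
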