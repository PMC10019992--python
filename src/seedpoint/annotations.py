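"""Reading and writing images, dot annotations, and predicted point sets.

The native annotation formats are deliberately minimal:

* CSV with header ``image_id,x,y`` — one row per annotated seed;
* JSON mapping ``image_id`` to a list of ``[x, y]`` pairs.

Coordinates are 0-based pixels, x rightward and y downward, sub-pixel values
allowed (a point at a pixel center has .0 coordinates under this convention).
Predictions are CSV with header ``image_id,x,y,score``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


@dataclass
class PointAnnotation:
    """Per-image seed coordinates; the training label and eval ground truth."""

    image_id: str
    points: np.ndarray  # (n, 2) float64, columns x, y

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = np.empty((0, 2), dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(
                f"points for {self.image_id!r} must be (n, 2), got {pts.shape}"
            )
        self.points = pts

    @property
    def count(self) -> int:
        return len(self.points)


@dataclass
class ImageSample:
    """An RGB image with an optional annotation (absent at inference)."""

    image_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    annotation: Optional[PointAnnotation] = None

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MergedPrediction:
    """Postprocessed point set: the final counted / localized seeds."""

    image_id: str
    points: np.ndarray  # (n, 3): x, y, score
    merge_radius: float
    raw_count: int

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = np.empty((0, 3), dtype=np.float64)
        self.points = pts

    @property
    def merged_count(self) -> int:
        return len(self.points)


def _read_annotation_csv(path: Path) -> dict[str, list[tuple[float, float]]]:
    table: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["image_id", "x", "y"]:
            raise ValueError(
                f"{path}: expected CSV header 'image_id,x,y', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                x, y = float(row[1]), float(row[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinate: {exc}") from None
            table.setdefault(row[0].strip(), []).append((x, y))
    return table


def _read_annotation_json(path: Path) -> dict[str, list[tuple[float, float]]]:
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top-level JSON must be an object")
    table = {}
    for image_id, pts in raw.items():
        parsed = []
        for i, pt in enumerate(pts):
            if len(pt) != 2:
                raise ValueError(f"{path}: {image_id!r} point {i} is not an [x, y] pair")
            parsed.append((float(pt[0]), float(pt[1])))
        table[image_id] = parsed
    return table


def load_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_dataset(image_dir, annotation_file) -> list[ImageSample]:
    """Load every image in ``image_dir`` with its annotation rows.

    Images with no annotation rows get an empty point list.  An annotated
    ``image_id`` with no matching image file is a hard error.  Ordering is
    lexicographic by image id, stable across runs.
    """
    image_dir = Path(image_dir)
    annotation_file = Path(annotation_file)
    if annotation_file.suffix.lower() == ".json":
        table = _read_annotation_json(annotation_file)
    else:
        table = _read_annotation_csv(annotation_file)

    images = {}
    for path in sorted(image_dir.iterdir()):
        if path.suffix.lower() in IMAGE_EXTENSIONS:
            images[path.stem] = path

    missing = sorted(set(table) - set(images))
    if missing:
        raise FileNotFoundError(
            f"annotated image id(s) with no image file in {image_dir}: "
            + ", ".join(repr(m) for m in missing)
        )

    samples = []
    for image_id in sorted(images):
        pixels = load_image(images[image_id])
        pts = np.asarray(table.get(image_id, []), dtype=np.float64)
        if pts.size == 0:
            pts = np.empty((0, 2))
        h, w = pixels.shape[:2]
        bad = (pts[:, 0] < 0) | (pts[:, 0] >= w) | (pts[:, 1] < 0) | (pts[:, 1] >= h)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"{image_id!r}: point ({pts[i, 0]}, {pts[i, 1]}) outside "
                f"[0, {w}) x [0, {h})"
            )
        samples.append(
            ImageSample(image_id, pixels, PointAnnotation(image_id, pts))
        )
    return samples


def save_predictions(preds: list[MergedPrediction], out_file) -> None:
    """Write predictions as CSV ``image_id,x,y,score`` (6-decimal coords)."""
    out_file = Path(out_file)
    with open(out_file, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y", "score"])
        for pred in preds:
            for x, y, s in pred.points:
                writer.writerow([pred.image_id, f"{x:.6f}", f"{y:.6f}", f"{s:.6f}"])


def load_predictions(in_file) -> dict[str, np.ndarray]:
    """Read a predictions CSV back into {image_id: (n, 3) array}."""
    in_file = Path(in_file)
    table: dict[str, list] = {}
    with open(in_file, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:4]] != ["image_id", "x", "y", "score"]:
            raise ValueError(
                f"{in_file}: expected CSV header 'image_id,x,y,score', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 4:
                raise ValueError(f"{in_file}:{lineno}: expected 4 columns")
            table.setdefault(row[0], []).append(
                (float(row[1]), float(row[2]), float(row[3]))
            )
    return {k: np.asarray(v, dtype=np.float64) for k, v in table.items()}


def save_annotations(samples: list[ImageSample], out_file) -> None:
    """Write annotation CSV for a list of samples (generator output)."""
    with open(Path(out_file), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y"])
        for s in samples:
            if s.annotation is None:
                continue
            for x, y in s.annotation.points:
                writer.writerow([s.image_id, f"{x:.6f}", f"{y:.6f}"])


def save_image(pixels: np.ndarray, path) -> None:
    Image.fromarray(pixels).save(Path(path))
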