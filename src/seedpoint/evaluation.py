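"""Scoring predicted point sets against ground truth.

Counting quality is the primary metric: per-image absolute error and its
mean (MAE), plus the squared Pearson correlation (R^2) between predicted and
true counts across images.  Localization quality — precision/recall/F1 of a
one-to-one Hungarian matching at a distance threshold tau — is an auxiliary
metric for synthetic experiments; the underlying study assessed localization
visually only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


def count_mae(pred_counts, gt_counts) -> float:
    """Mean absolute per-image counting error."""
    pred = np.asarray(pred_counts, dtype=np.float64)
    gt = np.asarray(gt_counts, dtype=np.float64)
    if pred.shape != gt.shape or pred.ndim != 1:
        raise ValueError(f"count lists must match in length, got {pred.shape} vs {gt.shape}")
    if len(pred) == 0:
        raise ValueError("count lists must be nonempty")
    return float(np.abs(pred - gt).mean())


def count_r2(pred_counts, gt_counts) -> float:
    """Squared Pearson correlation of predicted vs. ground-truth counts.

    NaN (with a warning) when fewer than two images or zero variance.
    """
    pred = np.asarray(pred_counts, dtype=np.float64)
    gt = np.asarray(gt_counts, dtype=np.float64)
    if pred.shape != gt.shape or pred.ndim != 1:
        raise ValueError(f"count lists must match in length, got {pred.shape} vs {gt.shape}")
    if len(pred) < 2 or np.var(gt) == 0 or np.var(pred) == 0:
        warnings.warn("R^2 undefined: fewer than 2 images or zero count variance")
        return float("nan")
    r = np.corrcoef(pred, gt)[0, 1]
    return float(r * r)


def localization_prf(pred, gt, tau: float) -> tuple[float, float, float]:
    """Precision/recall/F1 of one-to-one matched points within distance tau.

    Predictions are matched to ground truth by minimum-cost Hungarian
    assignment on Euclidean distance; matched pairs at distance <= tau are
    true positives.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    pred = np.asarray(pred, dtype=np.float64).reshape(-1, 2) if len(pred) else np.empty((0, 2))
    gt = np.asarray(gt, dtype=np.float64).reshape(-1, 2) if len(gt) else np.empty((0, 2))
    if len(pred) == 0 and len(gt) == 0:
        return 1.0, 1.0, 1.0
    if len(pred) == 0 or len(gt) == 0:
        # empty pred vs nonempty gt (or vice versa): no true positives
        precision = 1.0 if len(pred) == 0 and len(gt) == 0 else 0.0
        return (precision, 0.0, 0.0) if len(pred) == 0 else (0.0, 1.0, 0.0)
    dist = cdist(pred, gt)
    rows, cols = linear_sum_assignment(dist)
    tp = int((dist[rows, cols] <= tau).sum())
    precision = tp / len(pred)
    recall = tp / len(gt)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


@dataclass
class EvalReport:
    per_image_abs_error: list
    mae: float
    r_squared: float
    localization: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(predictions, ground_truth, tau: float = 5.0) -> EvalReport:
    """Build a full report from aligned prediction / ground-truth mappings.

    ``predictions``: {image_id: (n, >=2) array}; ``ground_truth``:
    {image_id: (m, 2) array}.  Every ground-truth image must have an entry
    in predictions (possibly empty).
    """
    ids = sorted(ground_truth)
    pred_counts, gt_counts, errors = [], [], []
    precisions, recalls, f1s = [], [], []
    for image_id in ids:
        gt_pts = np.asarray(ground_truth[image_id], dtype=np.float64).reshape(-1, 2) \
            if len(ground_truth[image_id]) else np.empty((0, 2))
        pr = predictions.get(image_id, np.empty((0, 2)))
        pr = np.asarray(pr, dtype=np.float64)
        pr_pts = pr[:, :2] if pr.size else np.empty((0, 2))
        pred_counts.append(len(pr_pts))
        gt_counts.append(len(gt_pts))
        errors.append(abs(len(pr_pts) - len(gt_pts)))
        p, r, f = localization_prf(pr_pts, gt_pts, tau)
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2 = count_r2(pred_counts, gt_counts) if len(ids) >= 2 else float("nan")
    return EvalReport(
        per_image_abs_error=[float(e) for e in errors],
        mae=count_mae(pred_counts, gt_counts),
        r_squared=r2,
        localization={
            "tau": tau,
            "precision": float(np.mean(precisions)),
            "recall": float(np.mean(recalls)),
            "f1": float(np.mean(f1s)),
        },
    )
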