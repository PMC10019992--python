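"""One-to-one Hungarian assignment of proposals to ground-truth points and
the combined classification + regression training objective.

The cost of pairing proposal i with ground-truth point j is

    cost[i, j] = ||decoded_i - gt_j||_2  -  tau * score_i

so confident proposals are preferred at equal distance.  Matching runs only
in the training path: it needs labels, so it is inapplicable at inference
(duplicate suppression there is the postprocessing module's job).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from . import _nn
from ._nn import Tensor
from .annotations import PointAnnotation
from .heads import ProposalSet


@dataclass
class MatchResult:
    pairs: list  # (proposal_index, gt_index), one per ground-truth point
    unmatched_proposals: np.ndarray
    total_cost: float


@dataclass
class LossBreakdown:
    classification_loss: float
    regression_loss: float
    total: float
    total_tensor: Optional[Tensor] = None  # present when inputs carry gradients


def match_cost(proposals: ProposalSet, gt: PointAnnotation, tau: float = 0.5) -> np.ndarray:
    """(n_proposals, n_gt) cost matrix; empty-but-shaped for degenerate input."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    decoded = proposals.decoded()
    gt_pts = np.asarray(gt.points, dtype=np.float64)
    if len(decoded) == 0 or len(gt_pts) == 0:
        return np.zeros((len(decoded), len(gt_pts)))
    dist = cdist(decoded, gt_pts)
    return dist - tau * proposals.scores_np[:, None]


def hungarian_match(cost: np.ndarray) -> MatchResult:
    """Exact minimum-cost assignment covering every ground-truth column."""
    cost = np.asarray(cost, dtype=np.float64)
    n_prop, n_gt = cost.shape
    if n_prop < n_gt:
        raise ValueError(
            f"insufficient proposals: {n_prop} rows for {n_gt} ground-truth columns"
        )
    if n_gt == 0:
        return MatchResult([], np.arange(n_prop), 0.0)
    rows, cols = linear_sum_assignment(cost)
    order = np.argsort(cols)
    pairs = [(int(rows[i]), int(cols[i])) for i in order]
    matched = {r for r, _ in pairs}
    unmatched = np.array([i for i in range(n_prop) if i not in matched])
    return MatchResult(pairs, unmatched, float(cost[rows, cols].sum()))


def point_loss(proposals: ProposalSet, gt: PointAnnotation, match: MatchResult,
               lambda_reg: float = 2e-4, negative_weight: float = 0.5) -> LossBreakdown:
    """Binary cross-entropy on confidences plus mean squared distance over
    matched pairs; ``total = cls + lambda_reg * reg``.

    Matched proposals are the positive class; unmatched ones are negatives,
    down-weighted by ``negative_weight`` in the weighted-mean normalization.
    """
    n = len(proposals)
    targets = np.zeros(n, dtype=np.float32)
    weights = np.full(n, float(negative_weight), dtype=np.float32)
    matched_idx = np.array([r for r, _ in match.pairs], dtype=np.intp)
    if len(matched_idx):
        targets[matched_idx] = 1.0
        weights[matched_idx] = 1.0

    if proposals.score_logits is not None:
        logits = proposals.score_logits
    else:
        s = np.clip(proposals.scores_np, 1e-7, 1 - 1e-7)
        logits = Tensor(np.log(s / (1 - s)))
    cls = _nn.bce_with_logits(logits, targets, weights)

    if len(matched_idx):
        gt_idx = np.array([c for _, c in match.pairs], dtype=np.intp)
        offsets = proposals.offsets
        if not isinstance(offsets, Tensor):
            offsets = Tensor(offsets)
        matched_off = _nn.take(offsets, matched_idx)
        target_off = (np.asarray(gt.points)[gt_idx]
                      - proposals.reference_points[matched_idx])
        diff = _nn.add(matched_off, Tensor(-target_off.astype(np.float32)))
        # mean over pairs of squared Euclidean distance
        reg = _nn.mul_scalar(_nn.mean_all(_nn.mul(diff, diff)), 2.0)
    else:
        reg = Tensor(np.float32(0.0))

    total = _nn.add(cls, _nn.mul_scalar(reg, float(lambda_reg)))
    return LossBreakdown(
        classification_loss=float(cls.data),
        regression_loss=float(reg.data),
        total=float(total.data),
        total_tensor=total,
    )
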