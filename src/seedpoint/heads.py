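"""Dense reference-point grid and the two prediction branches.

Each cell of the stride-``s`` grid carries K candidate points.  The
regression branch predicts a pixel offset (dx, dy) per candidate; the
classification branch predicts a confidence score per candidate.  The final
point is reference + offset — points may land outside the image and are
clipped only at decode/export time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _nn
from ._nn import Tensor


def generate_reference_points(height: int, width: int, stride: int, k: int) -> np.ndarray:
    """Reference points for every grid cell, row-major, K per cell.

    For perfect-square K the points form a sqrt(K) x sqrt(K) sub-grid within
    the cell; otherwise they sit evenly on the cell diagonal.  K = 1 is the
    cell center.
    """
    if height <= 0 or width <= 0:
        raise ValueError(f"image dimensions must be positive, got {height}x{width}")
    if stride < 1 or k < 1:
        raise ValueError(f"stride and k must be >= 1, got stride={stride}, k={k}")
    rows = math.ceil(height / stride)
    cols = math.ceil(width / stride)
    g = int(math.isqrt(k))
    if g * g == k:
        sub = np.array([((cx + 0.5) / g, (cy + 0.5) / g)
                        for cy in range(g) for cx in range(g)])
    else:
        t = (np.arange(k) + 0.5) / k
        sub = np.stack([t, t], axis=1)
    pts = np.empty((rows, cols, k, 2), dtype=np.float64)
    cell_x = np.arange(cols)[None, :, None] * stride
    cell_y = np.arange(rows)[:, None, None] * stride
    pts[..., 0] = cell_x + sub[None, None, :, 0] * stride
    pts[..., 1] = cell_y + sub[None, None, :, 1] * stride
    return pts.reshape(-1, 2)


@dataclass
class ProposalSet:
    """Raw network output: the dense grid with offsets and scores.

    ``offsets``/``scores`` may be autograd tensors (training) or plain
    arrays; ``decoded()`` always returns NumPy.
    """

    reference_points: np.ndarray  # (P, 2)
    offsets: object  # (P, 2) Tensor or ndarray
    scores: object  # (P,) Tensor or ndarray, in [0, 1]
    stride: int
    points_per_cell: int
    image_hw: tuple[int, int]
    score_logits: Optional[object] = None  # (P,) Tensor, training path

    @property
    def offsets_np(self) -> np.ndarray:
        o = self.offsets
        return np.asarray(o.data if isinstance(o, Tensor) else o, dtype=np.float64)

    @property
    def scores_np(self) -> np.ndarray:
        s = self.scores
        return np.asarray(s.data if isinstance(s, Tensor) else s, dtype=np.float64)

    def __len__(self):
        return len(self.reference_points)

    def decoded(self) -> np.ndarray:
        """reference + offset, unclipped."""
        return self.reference_points + self.offsets_np


class PointHeads:
    """Two small convolutional stacks on the fused map: regression (2K
    channels) and classification (K channels -> sigmoid)."""

    def __init__(self, in_channels: int, head_channels: int, k: int, rng,
                 depth: int = 2):
        self.k = int(k)
        def stack(out_channels):
            convs = []
            cin = in_channels
            for _ in range(depth):
                convs.append(_nn.Conv2d(cin, head_channels, 3, rng))
                cin = head_channels
            convs.append(_nn.Conv2d(cin, out_channels, 1, rng))
            return convs
        self.reg = stack(2 * self.k)
        self.cls = stack(self.k)

    def params(self):
        return [p for c in self.reg + self.cls for p in c.params()]

    def _run(self, convs, x):
        for conv in convs[:-1]:
            x = _nn.relu(conv(x))
        return convs[-1](x)

    def predict(self, fused: Tensor, image_hw: tuple[int, int], stride: int) -> ProposalSet:
        h, w = image_hw
        gh, gw = fused.shape[2], fused.shape[3]
        if gh != math.ceil(h / stride) or gw != math.ceil(w / stride):
            raise ValueError(
                f"fused map {gh}x{gw} does not match stride-{stride} grid for "
                f"a {h}x{w} image"
            )
        k = self.k
        reg = self._run(self.reg, fused)  # (1, 2K, gh, gw)
        logits = self._run(self.cls, fused)  # (1, K, gh, gw)
        # (1, 2K, gh, gw) -> (gh, gw, K, 2) -> (P, 2), matching the row-major
        # cell-then-candidate order of generate_reference_points
        offsets = _nn.reshape(
            _nn.transpose(_nn.reshape(reg, (k, 2, gh, gw)), (2, 3, 0, 1)),
            (gh * gw * k, 2),
        )
        logit_vec = _nn.reshape(
            _nn.transpose(_nn.reshape(logits, (k, gh, gw)), (1, 2, 0)),
            (gh * gw * k,),
        )
        scores = _nn.sigmoid(logit_vec)
        refs = generate_reference_points(h, w, stride, k)
        return ProposalSet(refs, offsets, scores, stride, k, (h, w),
                           score_logits=logit_vec)

    __call__ = predict


def decode(proposals: ProposalSet, score_threshold: float = 0.5) -> np.ndarray:
    """Thresholded, clipped, sorted final points as an (n, 3) x,y,score array.

    Sorted by descending score, ties broken by (y, x).
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score_threshold must be in [0, 1], got {score_threshold}")
    scores = proposals.scores_np
    keep = scores >= score_threshold
    pts = proposals.decoded()[keep]
    sc = scores[keep]
    h, w = proposals.image_hw
    pts = np.column_stack([
        np.clip(pts[:, 0], 0.0, w - 1.0),
        np.clip(pts[:, 1], 0.0, h - 1.0),
        sc,
    ])
    order = np.lexsort((pts[:, 0], pts[:, 1], -pts[:, 2]))
    return pts[order]
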