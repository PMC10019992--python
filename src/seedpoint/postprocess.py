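"""Duplicate-merging postprocessing.

The raw network heavily over-predicts: many high-confidence points crowd
around each true seed.  This stage links every pair of predictions within a
fixed radius (k-d tree range search), takes connected components of the
resulting graph, and replaces each component by its score-weighted centroid
(score = the component's maximum).  Chains merge transitively: if A-B and
B-C are within the radius, A, B, C become one point even when A-C is not.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .annotations import MergedPrediction


def _sort_points(pts: np.ndarray) -> np.ndarray:
    if len(pts) == 0:
        return pts
    order = np.lexsort((pts[:, 0], pts[:, 1], -pts[:, 2]))
    return pts[order]


def merge_points(points, radius: float, image_id: str = "",
                 score_weighted: bool = True) -> MergedPrediction:
    """Collapse fixed-radius connected components to single points.

    ``points`` is an (n, 3) array (or list) of x, y, score.  Radius 0 is the
    identity (no pairs are linked).  Output is sorted by descending score,
    ties broken by (y, x).
    """
    if radius < 0:
        raise ValueError(f"merge radius must be >= 0, got {radius}")
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        return MergedPrediction(image_id, np.empty((0, 3)), radius, 0)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3) x,y,score, got {pts.shape}")
    n = len(pts)
    if radius == 0:
        return MergedPrediction(image_id, _sort_points(pts.copy()), radius, n)

    tree = cKDTree(pts[:, :2])
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)

    merged = np.empty((n_comp, 3))
    for comp in range(n_comp):
        members = pts[labels == comp]
        w = members[:, 2] if score_weighted else np.ones(len(members))
        if w.sum() <= 0:
            w = np.ones(len(members))
        merged[comp, :2] = (members[:, :2] * w[:, None]).sum(axis=0) / w.sum()
        merged[comp, 2] = members[:, 2].max()
    return MergedPrediction(image_id, _sort_points(merged), radius, n)


def merge_points_bruteforce(points, radius: float, image_id: str = "",
                            score_weighted: bool = True) -> MergedPrediction:
    """O(n^2) pairwise-linking reference used to validate the k-d tree path."""
    if radius < 0:
        raise ValueError(f"merge radius must be >= 0, got {radius}")
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        return MergedPrediction(image_id, np.empty((0, 3)), radius, 0)
    n = len(pts)
    if radius == 0:
        return MergedPrediction(image_id, _sort_points(pts.copy()), radius, n)
    # union-find over all pairs within the radius
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d2 = ((pts[:, None, :2] - pts[None, :, :2]) ** 2).sum(-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= radius * radius:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    merged = []
    for root in np.unique(roots):
        members = pts[roots == root]
        w = members[:, 2] if score_weighted else np.ones(len(members))
        if w.sum() <= 0:
            w = np.ones(len(members))
        centroid = (members[:, :2] * w[:, None]).sum(axis=0) / w.sum()
        merged.append([centroid[0], centroid[1], members[:, 2].max()])
    return MergedPrediction(image_id, _sort_points(np.asarray(merged)), radius, n)
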