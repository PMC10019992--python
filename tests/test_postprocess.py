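"""Fixed-radius connected-component merging of duplicate predictions."""

import numpy as np
import pytest

import seedpoint as sp


def test_linked_pair_merges_to_centroid_isolated_point_survives():
    pts = np.array([[0, 0, 0.5], [1, 0, 0.5], [10, 0, 0.5]], dtype=float)
    merged = sp.merge_points(pts, radius=2.0)
    assert merged.merged_count == 2
    coords = sorted(map(tuple, merged.points[:, :2]))
    np.testing.assert_allclose(coords, [(0.5, 0.0), (10.0, 0.0)])
    assert merged.raw_count == 3


def test_radius_zero_is_identity():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(0, 50, (20, 2)), rng.random(20)])
    merged = sp.merge_points(pts, radius=0.0)
    assert merged.merged_count == 20
    assert set(map(tuple, merged.points)) == set(map(tuple, pts))


def test_negative_radius_rejected():
    with pytest.raises(ValueError):
        sp.merge_points(np.zeros((1, 3)), radius=-1.0)


def test_empty_input():
    merged = sp.merge_points(np.empty((0, 3)), radius=2.0)
    assert merged.merged_count == 0 and merged.raw_count == 0


def test_score_weighted_centroid_and_max_score():
    pts = np.array([[0, 0, 1.0], [2, 0, 0.5]])
    merged = sp.merge_points(pts, radius=3.0)
    # centroid pulled toward the higher-score member: (0*1 + 2*0.5) / 1.5
    np.testing.assert_allclose(merged.points[0], [2 / 3, 0.0, 1.0])
    unweighted = sp.merge_points(pts, radius=3.0, score_weighted=False)
    np.testing.assert_allclose(unweighted.points[0], [1.0, 0.0, 1.0])


def test_chained_components_merge_transitively():
    # A-B and B-C within radius, A-C not: all three collapse to one point
    pts = np.array([[0, 0, 1.0], [1.5, 0, 1.0], [3.0, 0, 1.0]])
    merged = sp.merge_points(pts, radius=2.0)
    assert merged.merged_count == 1
    np.testing.assert_allclose(merged.points[0, :2], [1.5, 0.0])


def test_merged_count_monotone_in_radius():
    rng = np.random.default_rng(1)
    pts = np.column_stack([rng.uniform(0, 40, (120, 2)), rng.random(120)])
    counts = [sp.merge_points(pts, r).merged_count
              for r in [0, 0.5, 1, 2, 4, 8, 100]]
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == 1  # everything fuses at a huge radius


def test_merge_is_idempotent_when_outputs_are_separated():
    rng = np.random.default_rng(2)
    pts = np.column_stack([rng.uniform(0, 100, (60, 2)), rng.random(60)])
    once = sp.merge_points(pts, radius=3.0)
    d = np.sqrt(((once.points[:, None, :2] - once.points[None, :, :2]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    if (d > 3.0).all():
        twice = sp.merge_points(once.points, radius=3.0)
        np.testing.assert_allclose(
            np.sort(twice.points, axis=0), np.sort(once.points, axis=0))


def _clustered_points(rng, k, radius, spread_factor=0.45, n_dup=(5, 50)):
    """k cluster centers separated by > 2*radius, each duplicated with
    jitter < radius * spread_factor (well inside r/2)."""
    centers = []
    while len(centers) < k:
        cand = rng.uniform(0, 300, 2)
        if all(np.linalg.norm(cand - c) > 2.2 * radius for c in centers):
            centers.append(cand)
    pts = []
    for c in centers:
        for _ in range(int(rng.integers(*n_dup))):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, spread_factor * radius)
            pts.append([c[0] + rad * np.cos(ang), c[1] + rad * np.sin(ang),
                        rng.uniform(0.5, 1.0)])
    return np.array(centers), np.asarray(pts)


@pytest.mark.parametrize("k", [1, 3, 7, 15])
def test_well_separated_duplicate_clusters_recovered_exactly(k):
    rng = np.random.default_rng(100 + k)
    radius = 4.0
    centers, pts = _clustered_points(rng, k, radius)
    merged = sp.merge_points(pts, radius)
    assert merged.merged_count == k
    # every recovered point within radius/2 of its true center
    d = np.sqrt(((merged.points[:, None, :2] - centers[None]) ** 2).sum(-1))
    assert (d.min(axis=1) < radius / 2).all()


@pytest.mark.parametrize("n", [10, 100, 400])
def test_kdtree_merging_equals_bruteforce(n):
    """The k-d tree accelerates but never changes the clustering."""
    rng = np.random.default_rng(n)
    pts = np.column_stack([rng.uniform(0, 60, (n, 2)), rng.random(n)])
    fast = sp.merge_points(pts, radius=2.5)
    slow = sp.merge_points_bruteforce(pts, radius=2.5)
    assert fast.merged_count == slow.merged_count
    np.testing.assert_allclose(fast.points, slow.points, rtol=1e-9, atol=1e-9)
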