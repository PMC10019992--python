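"""Hungarian matching and the training loss."""

import itertools
import math

import numpy as np
import pytest

import seedpoint as sp
from seedpoint._nn import Adam, Tensor
from seedpoint.heads import PointHeads


def brute_force_assignment_cost(cost):
    """Exhaustive minimum assignment cost (rows >= cols)."""
    n_rows, n_cols = cost.shape
    best = math.inf
    for rows in itertools.permutations(range(n_rows), n_cols):
        best = min(best, sum(cost[r, c] for c, r in enumerate(rows)))
    return best


def _props(refs, offsets, scores, image_hw=(64, 64)):
    return sp.ProposalSet(np.asarray(refs, float), np.asarray(offsets, float),
                          np.asarray(scores, float), 8, 1, image_hw)


def _gt(points):
    return sp.PointAnnotation("img", np.asarray(points, float))


def test_match_cost_is_distance_minus_tau_score():
    props = _props([[0, 0]], [[0, 0]], [1.0])
    gt = _gt([[3.0, 4.0]])
    assert sp.match_cost(props, gt, tau=0.0)[0, 0] == pytest.approx(5.0)
    assert sp.match_cost(props, gt, tau=2.0)[0, 0] == pytest.approx(3.0)


def test_match_cost_degenerate_shapes():
    props = _props(np.zeros((0, 2)), np.zeros((0, 2)), np.zeros(0))
    assert sp.match_cost(props, _gt(np.zeros((0, 2)))).shape == (0, 0)
    some = _props([[0, 0]], [[0, 0]], [0.5])
    assert sp.match_cost(some, _gt(np.zeros((0, 2)))).shape == (1, 0)


def test_hungarian_two_by_two_example():
    result = sp.hungarian_match(np.array([[1.0, 2.0], [3.0, 0.0]]))
    assert result.pairs == [(0, 0), (1, 1)]
    assert result.total_cost == pytest.approx(1.0)


def test_hungarian_single_cell():
    result = sp.hungarian_match(np.array([[5.0]]))
    assert result.pairs == [(0, 0)]
    assert result.total_cost == pytest.approx(5.0)
    assert len(result.unmatched_proposals) == 0


def test_hungarian_rejects_insufficient_proposals():
    with pytest.raises(ValueError, match="insufficient"):
        sp.hungarian_match(np.zeros((2, 3)))


@pytest.mark.parametrize("shape", [(3, 3), (6, 6), (7, 4), (5, 2), (7, 7)])
def test_hungarian_equals_bruteforce_on_random_matrices(shape):
    rng = np.random.default_rng(shape[0] * 10 + shape[1])
    for _ in range(20):
        cost = rng.normal(0, 10, shape)
        result = sp.hungarian_match(cost)
        assert result.total_cost == pytest.approx(
            brute_force_assignment_cost(cost), abs=1e-9)
        # pairs cover every column exactly once; partition holds
        assert sorted(c for _, c in result.pairs) == list(range(shape[1]))
        used = {r for r, _ in result.pairs}
        assert used.isdisjoint(result.unmatched_proposals)
        assert len(used) + len(result.unmatched_proposals) == shape[0]


def test_loss_empty_ground_truth_pushes_scores_down():
    props = _props([[0, 0], [8, 0]], np.zeros((2, 2)), [0.5, 0.5])
    match = sp.hungarian_match(sp.match_cost(props, _gt(np.zeros((0, 2)))))
    loss = sp.point_loss(props, _gt(np.zeros((0, 2))), match)
    assert loss.regression_loss == 0.0
    assert loss.classification_loss > 0


def test_loss_zero_distance_pair_contributes_no_regression():
    props = _props([[8, 8]], [[0, 0]], [0.9])
    gt = _gt([[8.0, 8.0]])
    match = sp.hungarian_match(sp.match_cost(props, gt))
    loss = sp.point_loss(props, gt, match)
    assert loss.regression_loss == pytest.approx(0.0, abs=1e-10)


def test_classification_loss_hand_computed_bce():
    """Scores 0.5, one matched of two proposals, equal weights:
    (-log 0.5 - log 0.5) / 2 = -log 0.5."""
    props = _props([[0, 0], [8, 8]], np.zeros((2, 2)), [0.5, 0.5])
    gt = _gt([[0.0, 0.0]])
    match = sp.hungarian_match(sp.match_cost(props, gt))
    loss = sp.point_loss(props, gt, match, negative_weight=1.0)
    assert loss.classification_loss == pytest.approx(-math.log(0.5), rel=1e-5)


def test_total_is_cls_plus_lambda_reg():
    props = _props([[0, 0], [8, 8]], [[1.0, 1.0], [0, 0]], [0.7, 0.3])
    gt = _gt([[4.0, 4.0]])
    match = sp.hungarian_match(sp.match_cost(props, gt))
    lam = 0.01
    loss = sp.point_loss(props, gt, match, lambda_reg=lam)
    assert loss.total == pytest.approx(
        loss.classification_loss + lam * loss.regression_loss, rel=1e-5)
    assert loss.classification_loss >= 0 and loss.regression_loss >= 0


def test_one_optimizer_step_decreases_loss_on_toy_problem():
    """Gradient flow end-to-end through heads, matching fixed per step."""
    rng = np.random.default_rng(0)
    heads = PointHeads(4, 8, 2, rng)
    fused = Tensor(rng.normal(0, 1, (1, 4, 4, 4)).astype(np.float32))
    gt = _gt([[10.0, 12.0], [20.0, 25.0]])
    opt = Adam([(heads.params(), 1e-3)])

    def step():
        props = heads.predict(fused, (32, 32), 8)
        match = sp.hungarian_match(sp.match_cost(props, gt))
        return sp.point_loss(props, gt, match, lambda_reg=1e-2)

    first = step()
    opt.zero_grad()
    first.total_tensor.backward()
    opt.step()
    second = step()
    assert second.total < first.total
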