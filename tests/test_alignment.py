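"""Attention maps, Sinkhorn balancing and the alignment-side losses."""

import itertools

import numpy as np
import pytest

from jade import (
    align_loss,
    attention_cost,
    maintain_loss,
    marginal_penalty,
    sinkhorn_normalize,
)
from jade.alignment import t_sinkhorn
from jade._tensor import astensor
from jade.preprocess import pairwise_sqdist


def sinkhorn_oracle(c, n_iters=5000, tol=1e-12):
    """Independent iterative-scaling implementation."""
    n1, n2 = c.shape
    pi = c / c.sum()
    for _ in range(n_iters):
        pi = pi / pi.sum(axis=1, keepdims=True) / n1
        pi = pi / pi.sum(axis=0, keepdims=True) / n2
        err = max(np.abs(pi.sum(1) - 1 / n1).max(), np.abs(pi.sum(0) - 1 / n2).max())
        if err < tol:
            break
    return pi


class TestAttentionCost:
    def test_zero_projection_uniform(self, rng):
        c = attention_cost(rng.random((4, 3)), rng.random((5, 3)), np.zeros((3, 3)))
        assert np.allclose(c.c, 1 / 5)

    def test_single_target_column(self, rng):
        c = attention_cost(rng.random((4, 2)), rng.random((1, 2)), np.eye(2))
        assert np.allclose(c.c, 1.0)

    def test_matches_loop_oracle(self, rng):
        h1, h2 = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        m = rng.normal(size=(3, 3))
        c = attention_cost(h1, h2, m).c
        logits = np.empty((4, 5))
        for i in range(4):
            for j in range(5):
                logits[i, j] = (h1[i] @ m) @ (h2[j] @ m) / 3.0
        expected = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(c, expected, atol=1e-10)

    def test_negative_logits_orientation(self, rng):
        h1, h2 = rng.normal(size=(3, 2)), rng.normal(size=(4, 2))
        m = rng.normal(size=(2, 2))
        pos = attention_cost(h1, h2, m).c
        neg = attention_cost(h1, h2, m, negative_logits=True).c
        # orderings within each row are reversed
        for i in range(3):
            assert np.array_equal(np.argsort(pos[i]), np.argsort(neg[i])[::-1])

    def test_rows_sum_to_one(self, rng):
        c = attention_cost(10 * rng.normal(size=(6, 4)), rng.normal(size=(7, 4)),
                           rng.normal(size=(4, 4)))
        assert np.allclose(c.c.sum(axis=1), 1.0, atol=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            attention_cost(np.array([[np.inf, 0.0]]), np.ones((2, 2)), np.eye(2))


class TestSinkhorn:
    def test_uniform_input_one_iteration(self):
        plan = sinkhorn_normalize(np.full((2, 3), 1 / 3))
        assert plan.converged
        assert np.allclose(plan.pi, 1 / 6)

    def test_matches_independent_oracle(self):
        c = np.array([[2.0, 1.0], [1.0, 2.0]])
        c = c / c.sum(axis=1, keepdims=True)
        plan = sinkhorn_normalize(c, max_iters=500, tol=1e-13)
        assert np.allclose(plan.pi, sinkhorn_oracle(c), atol=1e-12)

    def test_converged_marginals(self, rng):
        c = rng.random((9, 7)) + 0.05
        c /= c.sum(axis=1, keepdims=True)
        plan = sinkhorn_normalize(c, max_iters=500, tol=1e-9)
        assert plan.converged
        assert np.allclose(plan.pi.sum(axis=1), 1 / 9, atol=1e-9)
        assert np.allclose(plan.pi.sum(axis=0), 1 / 7, atol=1e-9)
        assert plan.pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_positivity_and_mass_every_iteration(self, rng):
        c = rng.random((5, 6)) + 1e-3
        for iters in range(1, 8):
            pi = t_sinkhorn(astensor(c / c.sum(1, keepdims=True)), iters).value
            assert (pi > 0).all()
            assert pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            sinkhorn_normalize(np.array([[0.5, 0.5], [0.0, 1.0]]))


class TestMarginalPenalty:
    def test_uniform_columns_zero(self):
        assert marginal_penalty(np.full((3, 4), 1 / 12)) == pytest.approx(0.0)

    def test_degenerate_columns_log2(self):
        pi = np.array([[0.5, 0.0], [0.5, 0.0]])
        assert marginal_penalty(pi) == pytest.approx(np.log(2), abs=1e-12)

    def test_nonnegative_on_random_plans(self, rng):
        for _ in range(20):
            pi = rng.random((4, 5))
            pi /= pi.sum()
            assert marginal_penalty(pi) >= -1e-12

    def test_monotone_decrease_with_iterations(self, rng):
        c = rng.random((8, 6)) + 0.01
        c /= c.sum(axis=1, keepdims=True)
        pens = [marginal_penalty(t_sinkhorn(astensor(c), k).value)
                for k in range(1, 12)]
        assert all(pens[i + 1] <= pens[i] + 1e-12 for i in range(len(pens) - 1))
        assert pens[-1] < 1e-6


class TestMaintainLoss:
    def test_identity_plan_zero(self, rng):
        n = 6
        d = pairwise_sqdist(rng.random((n, 2)), mean_normalize=False)
        assert maintain_loss(np.eye(n) / n, d, d) == pytest.approx(0.0, abs=1e-10)

    def test_matches_loop_oracle(self, rng):
        n1, n2 = 5, 6
        pi = rng.random((n1, n2))
        pi /= pi.sum()
        d1 = pairwise_sqdist(rng.random((n1, 2)), mean_normalize=False)
        d2 = pairwise_sqdist(rng.random((n2, 2)), mean_normalize=False)
        t1 = d1 - n2**2 * pi @ d2 @ pi.T
        t2 = d2 - n1**2 * pi.T @ d1 @ pi
        expected = (np.sqrt((t1**2).sum()) / n1 + np.sqrt((t2**2).sum()) / n2)
        assert maintain_loss(pi, d1, d2) == pytest.approx(expected, abs=1e-9)

    def test_permutation_invariance(self, rng):
        n1, n2 = 5, 4
        pi = rng.random((n1, n2))
        pi /= pi.sum()
        d1 = pairwise_sqdist(rng.random((n1, 2)))
        d2 = pairwise_sqdist(rng.random((n2, 2)))
        p1, p2 = rng.permutation(n1), rng.permutation(n2)
        assert maintain_loss(pi, d1, d2) == pytest.approx(
            maintain_loss(pi[np.ix_(p1, p2)], d1[np.ix_(p1, p1)],
                          d2[np.ix_(p2, p2)]), abs=1e-10)

    def test_zero_iff_isometric_permutation(self, rng):
        # exhaustive over all couplings supported on permutations, n = 4
        n = 4
        coords1 = rng.random((n, 2))
        perm_true = np.array([2, 0, 3, 1])
        coords2 = coords1[np.argsort(perm_true)]  # slice 2 = permuted slice 1
        d1 = pairwise_sqdist(coords1, mean_normalize=False)
        d2 = pairwise_sqdist(coords2, mean_normalize=False)
        for perm in itertools.permutations(range(n)):
            pi = np.zeros((n, n))
            pi[np.arange(n), list(perm)] = 1 / n
            loss = maintain_loss(pi, d1, d2)
            is_isometry = np.allclose(d1, d2[np.ix_(perm, perm)], atol=1e-12)
            if is_isometry:
                assert loss < 1e-9
            else:
                assert loss > 1e-9

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            maintain_loss(np.full((2, 3), 1 / 6), np.zeros((3, 3)), np.zeros((3, 3)))


class TestAlignLoss:
    def test_identity_plan_zero(self, rng):
        n, d = 7, 3
        h = rng.random((n, d))
        assert align_loss(np.eye(n) / n, h, h) == pytest.approx(0.0, abs=1e-10)

    def test_matches_loop_oracle(self, rng):
        n1, n2, d = 4, 5, 3
        pi = rng.random((n1, n2))
        pi /= pi.sum()
        h1, h2 = rng.normal(size=(n1, d)), rng.normal(size=(n2, d))
        t1 = h1 - n2 * pi @ h2
        t2 = h2 - n1 * pi.T @ h1
        expected = np.sqrt((t1**2).sum()) / n1 + np.sqrt((t2**2).sum()) / n2
        assert align_loss(pi, h1, h2) == pytest.approx(expected, abs=1e-10)

    def test_linear_homogeneity(self, rng):
        pi = rng.random((3, 4))
        pi /= pi.sum()
        h1, h2 = rng.normal(size=(3, 2)), rng.normal(size=(4, 2))
        base = align_loss(pi, h1, h2)
        assert align_loss(pi, 3 * h1, 3 * h2) == pytest.approx(3 * base, abs=1e-9)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            align_loss(np.full((2, 2), 0.25), rng.random((2, 3)), rng.random((2, 4)))
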