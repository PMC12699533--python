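"""Clustering, ARI, iLISI, alignment accuracy and marker testing."""

import numpy as np
import pytest

from jade import (
    adjusted_rand_index,
    alignment_accuracy,
    cluster_embeddings,
    ilisi_score,
    marker_gene_test,
)


def two_blobs(n_per=60, d=5, sep=8.0, seed=0):
    """Two blobs along different axes (so they stay distinct after the
    unit-norm scaling the clustering applies)."""
    r = np.random.default_rng(seed)
    c1 = np.zeros(d)
    c1[0] = sep
    c2 = np.zeros(d)
    c2[1] = sep
    a = r.normal(size=(n_per, d)) + c1
    b = r.normal(size=(n_per, d)) + c2
    return np.vstack([a, b]), np.repeat([0, 1], n_per)


class TestClusterEmbeddings:
    def test_separable_blobs_recovered(self):
        x, labels = two_blobs()
        assign = cluster_embeddings(x, k=2, seed=0)
        assert adjusted_rand_index(assign.labels, labels) == 1.0
        assert np.allclose(assign.responsibilities.sum(axis=1), 1.0)

    def test_deterministic(self):
        x, _ = two_blobs(seed=3)
        a = cluster_embeddings(x, k=3, seed=11)
        b = cluster_embeddings(x, k=3, seed=11)
        assert np.array_equal(a.labels, b.labels)

    def test_invalid_k(self):
        x, _ = two_blobs()
        with pytest.raises(ValueError):
            cluster_embeddings(x, k=1)
        with pytest.raises(ValueError):
            cluster_embeddings(x[:3], k=4)


class TestAdjustedRandIndex:
    def test_identical_and_relabeled(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        assert adjusted_rand_index(a, a) == 1.0
        relabeled = np.array(["z", "z", "x", "x", "y", "y"])
        assert adjusted_rand_index(a, relabeled) == 1.0

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 4, 50)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))

    def test_null_distribution_centred_at_zero(self):
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals.append(adjusted_rand_index(r.integers(0, 4, 1000),
                                            r.integers(0, 4, 1000)))
        assert abs(np.mean(vals)) < 0.02

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])


class TestIlisi:
    def test_separated_slices_score_one(self):
        x, ids = two_blobs(n_per=100, sep=50.0)
        assert ilisi_score(x, ids) == pytest.approx(1.0, abs=1e-3)

    def test_randomized_mixing_scores_two(self):
        r = np.random.default_rng(0)
        x = r.normal(size=(400, 4))
        ids = r.integers(0, 2, 400)
        assert ilisi_score(x, ids) == pytest.approx(2.0, abs=0.1)

    def test_range_bounds(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(size=(80, 3))
            ids = np.repeat([0, 1], 40)
            assert 1.0 <= ilisi_score(x, ids) <= 2.0

    def test_rigid_motion_invariance(self, rng):
        x, ids = two_blobs(n_per=50, sep=2.0, seed=4)
        theta = 0.7
        rot = np.eye(5)
        rot[:2, :2] = [[np.cos(theta), -np.sin(theta)],
                       [np.sin(theta), np.cos(theta)]]
        assert ilisi_score(x, ids) == pytest.approx(
            ilisi_score(x @ rot.T + 2.0, ids), abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ilisi_score(np.zeros((10, 2)), np.repeat([0, 1], 5), perplexity=30)


class TestAlignmentAccuracy:
    def test_diagonal_plan_identical_labels(self):
        n = 8
        labels = np.array(list("aabbccdd"))
        acc, table = alignment_accuracy(np.eye(n) / n, labels, labels)
        assert acc == 1.0
        assert table["n_correct"].sum() == n

    def test_uniform_plan_tie_break(self):
        n = 5
        labels = np.array([f"d{i}" for i in range(n)])  # all distinct
        acc, _ = alignment_accuracy(np.full((n, n), 1 / n**2), labels, labels)
        # argmax ties resolve to column 0, so only spot 0 matches itself
        assert acc == pytest.approx(1 / n)

    def test_threshold_forces_unaligned(self):
        n = 4
        labels = np.array(["a"] * n)
        pi = np.full((n, n), 1 / n**2)
        acc, table = alignment_accuracy(pi, labels, labels,
                                        unaligned_threshold=2.0)
        assert acc == 0.0
        assert table["n_unaligned"].sum() == n

    def test_exclude_mode(self):
        pi = np.array([[0.5, 0.0], [0.125, 0.375]])
        labels1 = np.array(["a", "b"])
        labels2 = np.array(["a", "a"])
        # spot 0 aligned & correct; spot 1 aligned & wrong
        acc_wrong, _ = alignment_accuracy(pi, labels1, labels2)
        acc_excl, _ = alignment_accuracy(pi, labels1, labels2,
                                         unaligned_mode="exclude")
        assert acc_wrong == acc_excl == 0.5

    def test_column_permutation_invariance(self, rng):
        n1, n2 = 6, 7
        pi = rng.random((n1, n2))
        pi /= pi.sum()
        l1 = rng.choice(list("ab"), n1)
        l2 = rng.choice(list("ab"), n2)
        perm = rng.permutation(n2)
        acc1, _ = alignment_accuracy(pi, l1, l2)
        acc2, _ = alignment_accuracy(pi[:, perm], l1, l2[perm])
        assert acc1 == acc2


class TestMarkerGeneTest:
    def test_planted_marker_top_ranked(self):
        r = np.random.default_rng(0)
        n, p = 60, 12
        labels = np.repeat(["A", "B", "C"], n // 3)
        expr = r.poisson(3.0, size=(n, p)).astype(float)
        expr[:, 5] = 0.0
        expr[labels == "A", 5] = r.poisson(8.0, size=n // 3) + 1.0
        tables = marker_gene_test(expr, labels, fdr=0.05)
        top_a = tables["A"].iloc[0]
        assert top_a["gene"] == "gene_5"
        assert top_a["padj"] < 0.05

    def test_identical_expression_empty(self):
        expr = np.tile(np.arange(6.0), (30, 1))
        labels = np.repeat(["A", "B"], 15)
        tables = marker_gene_test(expr, labels)
        assert all(len(t) == 0 for t in tables.values())

    def test_null_false_positive_rate(self):
        hits = trials = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            expr = r.normal(size=(40, 20))
            labels = r.permutation(np.repeat(["A", "B"], 20))
            tables = marker_gene_test(expr, labels, fdr=0.05)
            trials += 1
            if any(len(t) > 0 for t in tables.values()):
                hits += 1
        # BH controls the per-domain FDR; family-wise hits stay modest
        assert hits / trials <= 0.15

    def test_too_small_domain(self):
        expr = np.random.default_rng(0).random((5, 4))
        with pytest.raises(ValueError):
            marker_gene_test(expr, np.array(["A", "A", "A", "B", "B"]))
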