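import itertools

import numpy as np
import pytest

import rodsig
from rodsig.cluster import (
    between_set_sc,
    corr_distance,
    corr_distance_matrix,
    silhouette,
    to_newick,
    zscale,
)
from rodsig.intervals import ValidationError


def brute_silhouette(D, labels):
    """Independent double-loop (B - A)/max(A, B) implementation."""
    n = len(labels)
    uniq = sorted(set(labels))
    s = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s.append(0.0)
            continue
        A = sum(D[i][j] for j in own) / len(own)
        B = min(
            sum(D[i][j] for j in range(n) if labels[j] == c)
            / sum(1 for j in range(n) if labels[j] == c)
            for c in uniq if c != labels[i]
        )
        s.append(0.0 if max(A, B) == 0 else (B - A) / max(A, B))
    return s, sum(s) / n


def brute_average_linkage_heights(D):
    """Exhaustive agglomeration recomputing mean pairwise distances."""
    clusters = [[i] for i in range(len(D))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[i][j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


class TestZScale:
    def test_examples(self):
        out = zscale(np.array([[1.0], [2.0], [3.0]]))
        assert out[:, 0] == pytest.approx([-1, 0, 1])
        const = zscale(np.array([[5.0], [5.0], [5.0]]))
        assert (const == 0).all()

    def test_moments_on_random(self):
        rng = np.random.default_rng(1)
        X = rng.normal(3, 7, size=(40, 6))
        Z = zscale(X)
        assert Z.mean(axis=0) == pytest.approx(np.zeros(6), abs=1e-12)
        assert Z.std(axis=0, ddof=1) == pytest.approx(np.ones(6))


class TestCorrDistance:
    def test_examples(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert corr_distance(x, x) == pytest.approx(0.0)
        assert corr_distance(x, -x) == pytest.approx(1.0)
        assert corr_distance([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.5)

    def test_zero_variance_convention(self):
        assert corr_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.5

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=10)
        d = corr_distance(x, y)
        assert corr_distance(3.5 * x + 2, y) == pytest.approx(d)
        assert corr_distance(x, 0.1 * y - 7) == pytest.approx(d)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(8, 5))
        D = corr_distance_matrix(X)
        for i in range(8):
            for j in range(8):
                expected = 0.0 if i == j else corr_distance(X[i], X[j])
                assert D[i, j] == pytest.approx(expected)


class TestSilhouette:
    def test_two_tight_pairs(self):
        pts = np.array([[0, 0], [0, 1], [10, 10], [10, 11]], dtype=float)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = [0, 0, 1, 1]
        per, avg = silhouette(D, labels)
        assert avg == pytest.approx(0.9293, abs=0.003)
        assert per.tolist() == pytest.approx(brute_silhouette(D, labels)[0])

    def test_coincident_points(self):
        D = np.zeros((4, 4))
        _, avg = silhouette(D, [0, 0, 1, 1])
        assert avg == 0.0

    def test_interleaved_points_show_no_structure(self):
        x = np.arange(10, dtype=float)
        D = np.abs(x[:, None] - x[None, :])
        _, avg = silhouette(D, [0, 1] * 5)
        assert avg < 0.2
        assert avg == pytest.approx(brute_silhouette(D, [0, 1] * 5)[1])

    def test_singleton_cluster_convention(self):
        D = np.array([[0, 1, 9.0], [1, 0, 9], [9, 9, 0]])
        per, _ = silhouette(D, [0, 0, 1])
        assert per[2] == 0.0

    def test_single_cluster_is_error(self):
        with pytest.raises(ValidationError):
            silhouette(np.zeros((3, 3)), [0, 0, 0])

    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        for n in (5, 12, 20):
            X = rng.normal(size=(n, 4))
            D = corr_distance_matrix(X)
            labels = rng.integers(0, 3, size=n)
            if len(set(labels.tolist())) < 2:
                labels[0] = (labels[0] + 1) % 3
            per, avg = silhouette(D, labels)
            bper, bavg = brute_silhouette(D, labels.tolist())
            assert per.tolist() == pytest.approx(bper)
            assert avg == pytest.approx(bavg)

    def test_matches_sklearn_when_no_singletons(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(13)
        X = rng.normal(size=(15, 4))
        D = corr_distance_matrix(X)
        labels = np.array([0] * 5 + [1] * 5 + [2] * 5)
        per, _ = silhouette(D, labels)
        ref = silhouette_samples(D, labels, metric="precomputed")
        assert per == pytest.approx(ref)


class TestAverageLinkage:
    def test_perfect_separation(self):
        u, v = [1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 3.0, -2.0]
        X = np.array([u, u, v, v])
        res = rodsig.average_linkage(X, k=2, scale=False)
        labels = res.labels.to_numpy()
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_n_gives_singletons(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        res = rodsig.average_linkage(X, k=6)
        assert len(set(res.labels)) == 6

    def test_k_out_of_range(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValidationError):
            rodsig.average_linkage(X, k=5)

    def test_merge_heights_match_bruteforce(self):
        rng = np.random.default_rng(14)
        for n in (4, 6, 8):
            X = rng.normal(size=(n, 5))
            D = corr_distance_matrix(X)
            res = rodsig.average_linkage(X, k=1, scale=False)
            got = sorted(h for _, _, h in res.merge_history)
            assert got == pytest.approx(brute_average_linkage_heights(D))

    def test_newick_export_contains_all_leaves(self):
        X = np.random.default_rng(2).normal(size=(5, 4))
        res = rodsig.average_linkage(X, k=2)
        nwk = to_newick(res.linkage_matrix, [f"t{i}" for i in range(5)])
        assert nwk.endswith(";")
        assert all(f"t{i}" in nwk for i in range(5))


class TestBetweenSetSC:
    def test_maximal_separation(self):
        u, v = [1.0, 5.0, 2.0, 8.0], [8.0, 1.0, 7.0, 0.0]
        X = np.array([u, u, u, v, v, v]) + np.random.default_rng(3).normal(
            0, 0.01, size=(6, 4)
        )
        sc = between_set_sc(X, [0, 1, 2], [3, 4, 5])
        assert sc > 0.9

    def test_random_split_of_one_cloud_is_structureless(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 13))
        sc = between_set_sc(X, list(range(20)), list(range(20, 40)), scale=False)
        assert abs(sc) < 0.2

    def test_overlap_is_error(self):
        X = np.zeros((4, 4))
        with pytest.raises(ValidationError):
            between_set_sc(X, [0, 1], [1, 2])
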