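import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mitodelim import (
    DistanceMatrix,
    affinity_propagation,
    cluster_all,
    consensus,
    dbscan,
    hierarchical_complete,
    kmeans,
    nmf_cluster,
)
from mitodelim.cluster import ClusterResult


def _dm(d):
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    return DistanceMatrix(
        ids=[f"s{i}" for i in range(n)],
        d=d,
        n_valid=np.full((n, n), 10),
    )


def brute_force_complete_linkage(d, k):
    """Agglomeration oracle: re-scan all cluster pairs at every merge."""
    clusters = [[i] for i in range(d.shape[0])]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                link = max(
                    d[i, j] for i in clusters[a] for j in clusters[b]
                )
                if best is None or link < best[0]:
                    best = (link, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(d.shape[0], dtype=int)
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


class TestKMeans:
    def test_separated_blobs_recovered(self, rng):
        x = np.vstack(
            [rng.normal(0, 0.05, (20, 3)), rng.normal(5, 0.05, (12, 3))]
        )
        truth = [0] * 20 + [1] * 12
        res = kmeans(x, k=2, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert res.k_found == 2

    def test_k_equals_n_zero_sse(self, rng):
        x = rng.normal(size=(6, 2))
        res = kmeans(x, k=6, seed=0)
        assert res.k_found == 6
        assert res.params["inertia"] == pytest.approx(0.0, abs=1e-12)

    def test_k1_centroid_is_mean(self, rng):
        x = rng.normal(size=(10, 2))
        res = kmeans(x, k=1, seed=0)
        assert res.k_found == 1
        expected_sse = ((x - x.mean(axis=0)) ** 2).sum()
        assert res.params["inertia"] == pytest.approx(expected_sse)

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.normal(size=(3, 2)), k=4)


class TestHierarchicalComplete:
    def test_two_zero_blocks(self):
        d = np.full((6, 6), 0.1)
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        res = hierarchical_complete(_dm(d), k=2)
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], res.labels) == 1.0

    def test_k_equals_n_singletons(self):
        d = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        res = hierarchical_complete(_dm(d), k=3)
        assert res.k_found == 3

    def test_four_point_chain(self):
        # hand-enumerated merges: {1,2} then {3,4}, cut at k=2
        d = np.array(
            [[0, 1, 4, 5], [1, 0, 3, 4], [4, 3, 0, 1], [5, 4, 1, 0]],
            dtype=float,
        ) / 10.0
        res = hierarchical_complete(_dm(d), k=2)
        assert adjusted_rand_score([0, 0, 1, 1], res.labels) == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = 8
            raw = rng.uniform(0.01, 0.9, size=(n, n))
            d = np.triu(raw, 1)
            d = d + d.T
            for k in (2, 3, 4):
                expected = brute_force_complete_linkage(d, k)
                got = hierarchical_complete(_dm(d), k=k).labels
                assert adjusted_rand_score(expected, got) == 1.0


class TestNMF:
    def test_block_matrix_rank2(self):
        # exact rank-2 block-diagonal non-negative matrix
        x = np.zeros((6, 6))
        x[:3, :3] = 2.0
        x[3:, 3:] = 3.0
        res = nmf_cluster(x, rank=2, nrun=5, seed=0)
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], res.labels) == 1.0

    def test_rank1_single_cluster(self, rng):
        x = rng.uniform(0.1, 1, size=(5, 4))
        res = nmf_cluster(x, rank=1, nrun=3, seed=0)
        assert res.k_found == 1

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            nmf_cluster(np.array([[1.0, -0.1], [0.2, 0.3]]), rank=1)

    def test_more_restarts_never_worse(self, rng):
        x = rng.uniform(0, 1, size=(10, 8))
        few = nmf_cluster(x, rank=2, nrun=1, seed=0).params["divergence"]
        many = nmf_cluster(x, rank=2, nrun=10, seed=0).params["divergence"]
        assert many <= few + 1e-12


class TestDBSCAN:
    def test_two_dense_groups(self):
        x = np.vstack([np.zeros((25, 2)), np.full((25, 2), 10.0)])
        res = dbscan(x, eps=0.5, min_pts=20)
        assert res.k_found == 2
        assert np.count_nonzero(res.labels == -1) == 0

    def test_all_noise_when_sparse(self):
        x = np.arange(5, dtype=float).reshape(-1, 1) * 10
        res = dbscan(x, eps=0.5, min_pts=2)
        assert np.all(res.labels == -1)
        assert res.k_found == 0

    def test_border_point_joins_core_cluster(self):
        # 1-D: {0, 0.5, 1.0} are core at eps=1/min_pts=3; 1.9 is border,
        # reachable only from the core at 1.0; 10 is noise.
        x = np.array([[0.0], [0.5], [1.0], [1.9], [10.0]])
        res = dbscan(x, eps=1.0, min_pts=3)
        assert res.labels[3] == res.labels[2]
        assert res.labels[4] == -1
        assert res.k_found == 1

    def test_precomputed_matrix_accepted(self, default_dm, default_dataset):
        from mitodelim import scale_matrix

        res = dbscan(scale_matrix(default_dm), eps=0.5, min_pts=20)
        assert (
            adjusted_rand_score(default_dataset.true_labels, res.labels)
            == 1.0
        )


class TestAffinityPropagation:
    def _two_block_similarity(self):
        s = np.full((6, 6), 0.1)
        s[:3, :3] = 0.9
        s[3:, 3:] = 0.9
        np.fill_diagonal(s, 1.0)
        return s

    def test_two_blocks(self):
        res = affinity_propagation(self._two_block_similarity())
        assert res.k_found == 2
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], res.labels) == 1.0

    def test_permutation_equivariance(self):
        s = self._two_block_similarity()
        perm = np.array([3, 0, 4, 1, 5, 2])
        res = affinity_propagation(s)
        res_p = affinity_propagation(s[np.ix_(perm, perm)])
        assert (
            adjusted_rand_score(res.labels[perm], res_p.labels) == 1.0
        )

    def test_single_point(self):
        res = affinity_propagation(np.array([[1.0]]))
        assert res.k_found == 1
        assert res.labels.tolist() == [0]

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            affinity_propagation(np.zeros((2, 3)))


class TestConsensus:
    def _result(self, labels, algorithm="x"):
        return ClusterResult(algorithm=algorithm, labels=np.array(labels))

    def test_five_identical_partitions(self):
        labs = [0, 0, 1, 1, 1]
        res = consensus([self._result(labs, f"a{i}") for i in range(5)])
        assert res.unanimous
        assert res.consensus_labels.tolist() == labs
        assert np.all(res.agreement == 1.0)

    def test_majority_beats_single_flip(self):
        labs = [0, 0, 1, 1, 1]
        flipped = [0, 0, 0, 1, 1]
        results = [self._result(labs, f"a{i}") for i in range(4)]
        results.append(self._result(flipped, "a4"))
        res = consensus(results)
        assert res.consensus_labels.tolist() == labs
        assert not res.unanimous

    def test_label_permutation_invariance(self):
        res = consensus(
            [
                self._result([0, 0, 1, 1], "a"),
                self._result([1, 1, 0, 0], "b"),  # same partition, ids swapped
            ]
        )
        assert res.unanimous
        assert np.all(res.agreement == 1.0)
        assert res.consensus_labels.tolist() == [0, 0, 1, 1]

    def test_noise_points_abstain(self):
        res = consensus(
            [
                self._result([0, 0, 1, 1], "a"),
                self._result([0, 0, 1, 1], "b"),
                self._result([-1, 0, 1, 1], "dbscan"),
            ]
        )
        assert res.consensus_labels.tolist() == [0, 0, 1, 1]

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            consensus([self._result([0, 1]), self._result([0, 1, 1])])


def test_cluster_all_recovers_planted_partition(default_dm, default_dataset):
    """All five algorithms agree with the planted two-group split."""
    cons = cluster_all(default_dm, k=2, seed=1, nmf_nrun=20)
    truth = default_dataset.true_labels
    for res in cons.per_algorithm:
        assert adjusted_rand_score(truth, res.labels) == 1.0, res.algorithm
    assert adjusted_rand_score(truth, cons.consensus_labels) == 1.0
    assert cons.unanimous
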