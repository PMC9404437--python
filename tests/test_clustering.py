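from itertools import combinations

import numpy as np
import pytest

from vocclust import (
    adaptive_affinity_propagation,
    community_detection,
    fuzzy_sweep,
    hdbscan_cluster,
    nmi,
)
from vocclust.clustering import _fcm, _merge_centroids, modularity
from vocclust.errors import InputError, ParameterError
from vocclust.similarity import SimilarityMatrix
from vocclust.transform import RowMatrix


def sim(S, k=3):
    S = np.asarray(S, dtype=float)
    return SimilarityMatrix(S=S, k_used=k, classifier="knn",
                            call_ids=[str(i) for i in range(S.shape[0])])


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def two_triangles():
    """Two disconnected unit-weight triangles on 6 nodes."""
    A = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[a, b] = A[b, a] = 1.0
    return A


class TestCommunityDetection:
    def test_two_triangles_exhaustive_optimum(self):
        A = two_triangles()
        # exhaustive maximum modularity over all partitions of 6 nodes
        best_q = -np.inf
        for part in all_partitions(range(6)):
            labels = np.empty(6, dtype=int)
            for g, block in enumerate(part):
                labels[block] = g
            best_q = max(best_q, modularity(A, labels))
        assert best_q == pytest.approx(0.5)
        S = sim(A + np.eye(6))
        res = community_detection(S)
        assert res.K == 2
        assert res.params["Q"] == pytest.approx(best_q)

    def test_greedy_matches_exhaustive_on_random_block_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(6, 9))
            split = int(rng.integers(2, n - 1))
            truth = np.array([0] * split + [1] * (n - split))
            A = np.zeros((n, n))
            for i, j in combinations(range(n), 2):
                if truth[i] == truth[j]:
                    A[i, j] = A[j, i] = rng.uniform(0.7, 1.0)
                elif rng.random() < 0.15:
                    A[i, j] = A[j, i] = rng.uniform(0.0, 0.1)
            best_q = max(
                modularity(A, np.array([next(g for g, blk in enumerate(part) if i in blk)
                                        for i in range(n)]))
                for part in all_partitions(range(n))
            )
            res = community_detection(sim(A + np.eye(n)))
            assert res.params["Q"] == pytest.approx(best_q)

    def test_modularity_agrees_with_networkx(self, rng):
        import networkx as nx
        n = 10
        A = rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        labels = rng.integers(0, 3, size=n)
        G = nx.from_numpy_array(A)
        communities = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        expected = nx.community.modularity(G, communities, weight="weight")
        assert modularity(A, labels) == pytest.approx(expected)

    def test_complete_uniform_graph_single_community(self):
        A = np.ones((6, 6))
        res = community_detection(sim(A))
        assert res.K == 1
        assert res.params["Q"] == pytest.approx(0.0)

    def test_block_diagonal_perfect_separation(self):
        A = np.zeros((8, 8))
        A[:4, :4] = 1.0
        A[4:, 4:] = 1.0
        res = community_detection(sim(A))
        assert res.K == 2
        np.testing.assert_array_equal(res.labels[:4], res.labels[0])
        np.testing.assert_array_equal(res.labels[4:], res.labels[4])

    def test_all_zero_graph_singletons(self):
        res = community_detection(sim(np.eye(5)))
        assert res.K == 5
        assert "warning" in res.params

    def test_q_bounded(self, rng):
        for _ in range(5):
            A = rng.random((7, 7))
            A = (A + A.T) / 2
            res = community_detection(sim(A))
            assert 0.0 <= res.params["Q"] <= 1.0


def brute_force_ap_partition(S, preference):
    """Optimal exemplar assignment by exhaustive search over exemplar sets."""
    n = S.shape[0]
    best, best_net = None, -np.inf
    for r in range(1, n + 1):
        for ex in combinations(range(n), r):
            ex = list(ex)
            assign = [ex[int(np.argmax(S[i, ex]))] if i not in ex else i
                      for i in range(n)]
            net = sum(preference for _ in ex) + sum(
                S[i, assign[i]] for i in range(n) if i not in ex)
            if net > best_net:
                best_net, best = net, assign
    return np.asarray(best)


class TestAffinityPropagation:
    def test_block_diagonal_two_clusters(self):
        A = np.zeros((8, 8))
        A[:4, :4] = 0.9
        A[4:, 4:] = 0.9
        np.fill_diagonal(A, 1.0)
        res = adaptive_affinity_propagation(sim(A), seed=42)
        assert res.K == 2
        assert nmi(res.labels, [1] * 4 + [2] * 4) == 1.0
        # brute-force net-similarity oracle agrees at a mid preference
        oracle = brute_force_ap_partition(A, preference=float(np.median(A)))
        assert len(np.unique(oracle)) == 2

    def test_mutually_dissimilar_points_all_exemplars_at_high_preference(self):
        from vocclust.clustering import _run_ap
        S = np.eye(6)
        labels = _run_ap(S, preference=0.99, seed=42)
        assert labels is not None
        assert len(np.unique(labels)) == 6

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(8)
        A = rng.random((10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        r1 = adaptive_affinity_propagation(sim(A), seed=42)
        r2 = adaptive_affinity_propagation(sim(A), seed=42)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_stability_table_records_sweep(self):
        A = np.zeros((8, 8))
        A[:4, :4] = 0.9
        A[4:, 4:] = 0.9
        np.fill_diagonal(A, 1.0)
        res = adaptive_affinity_propagation(sim(A), seed=42)
        assert {"preference", "K", "silhouette"} <= set(res.stability_table.columns)
        assert len(res.stability_table) > 10


class TestHDBSCAN:
    def test_two_triples_plus_outlier(self, rng):
        X = np.vstack([
            np.zeros((3, 2)) + 0.01 * rng.standard_normal((3, 2)),
            np.full((3, 2), 10.0) + 0.01 * rng.standard_normal((3, 2)),
            [[100.0, -100.0]],
        ])
        rows = RowMatrix(matrix=X, call_ids=[str(i) for i in range(7)])
        res = hdbscan_cluster(rows)
        assert res.K == 2
        assert res.labels[6] == 0  # outlier discarded as noise
        assert len(set(res.labels[:3])) == 1
        assert len(set(res.labels[3:6])) == 1
        # cross-check grouping against single linkage on mutual-reachability
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        core = np.sort(d, axis=1)[:, 2]  # distance to the 2nd neighbor (minpts=2)
        mreach = np.maximum(np.maximum(core[:, None], core[None, :]), d)
        np.fill_diagonal(mreach, 0.0)
        tree = linkage(squareform(mreach, checks=False), method="single")
        # three groups: the two triples plus the outlier as its own singleton
        flat = fcluster(tree, t=3, criterion="maxclust")
        assert len(set(flat[:3])) == 1 and len(set(flat[3:6])) == 1
        assert nmi(flat[:6], res.labels[:6]) == 1.0
        assert flat[6] not in set(flat[:6])

    def test_identical_points_one_cluster_no_noise(self):
        rows = RowMatrix(matrix=np.zeros((5, 3)), call_ids=list("abcde"))
        res = hdbscan_cluster(rows)
        assert res.K == 1
        assert (res.labels != 0).all()

    def test_clusters_respect_min_size(self, rng):
        X = rng.standard_normal((12, 4))
        rows = RowMatrix(matrix=X, call_ids=[str(i) for i in range(12)])
        res = hdbscan_cluster(rows, minpts=2, minclustsize=2)
        for c in np.unique(res.labels[res.labels > 0]):
            assert (res.labels == c).sum() >= 2

    def test_too_few_calls_rejected(self):
        rows = RowMatrix(matrix=np.zeros((2, 2)), call_ids=["a", "b"])
        with pytest.raises(InputError):
            hdbscan_cluster(rows)


@pytest.fixture(scope="module")
def three_type_rows():
    """Windowed feature rows for 3 easy vocal types x 20 calls."""
    from vocclust import generate_repertoire
    from vocclust.pipeline import ProcedureSpec, _build_inputs
    calls = generate_repertoire(n_types=3, calls_per_type=20, seed=21)
    spec = ProcedureSpec(representation="features", mode="win_pct",
                         method="fuzzy", seed=42)
    rows, _ = _build_inputs(calls, spec)
    return rows, np.array([c.true_label for c in calls])


class TestFuzzy:
    def test_recovers_three_vocal_types(self, three_type_rows):
        rows, truth = three_type_rows
        res = fuzzy_sweep(rows, seed=42)
        assert res.K == 3
        assert nmi(res.labels, truth) == 1.0

    def test_membership_rows_sum_to_one(self, three_type_rows, rng):
        rows, _ = three_type_rows
        X = rows.matrix
        init = X[rng.choice(X.shape[0], 10, replace=False)]
        for mu in (1.1, 1.8, 2.5):
            _, u = _fcm(X, init, mu)
            np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_grid_endpoints_and_bounds(self, three_type_rows):
        rows, _ = three_type_rows
        res = fuzzy_sweep(rows, seed=42)
        mus = res.stability_table["mu"].to_numpy()
        assert mus[0] == pytest.approx(1.1) and mus[-1] == pytest.approx(2.5)
        assert (res.stability_table["K"] <= 15).all()

    def test_decimation_is_monotone(self, three_type_rows):
        rows, _ = three_type_rows
        res = fuzzy_sweep(rows, seed=42)
        ks = res.stability_table["K"].to_numpy()
        assert (np.diff(ks) <= 0).all()

    def test_cmax_must_be_below_n(self):
        rows = RowMatrix(matrix=np.zeros((10, 2)), call_ids=[str(i) for i in range(10)])
        with pytest.raises(ParameterError):
            fuzzy_sweep(rows, cmax=10)

    def test_deterministic_under_fixed_seed(self, three_type_rows):
        rows, _ = three_type_rows
        r1 = fuzzy_sweep(rows, seed=7)
        r2 = fuzzy_sweep(rows, seed=7)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_merge_centroids_transitive(self):
        c = np.array([[0.0], [0.005], [0.009], [5.0]])
        group = _merge_centroids(c, epsilon=0.01)
        assert group[0] == group[1] == group[2]
        assert group[3] != group[0]


class TestParameterRecoveryAcrossMethods:
    def test_cd_and_ap_recover_three_vocal_types(self, three_type_rows):
        from vocclust.similarity import auto_select_k, knn_rank
        rows, truth = three_type_rows
        ranking = knn_rank(rows)
        _, S, _ = auto_select_k(ranking, community_detection)
        cd = community_detection(S)
        assert cd.K == 3 and nmi(cd.labels, truth) == 1.0
        ap_fn = lambda s: adaptive_affinity_propagation(s, seed=42)
        _, S_ap, _ = auto_select_k(ranking, ap_fn)
        ap = ap_fn(S_ap)
        assert ap.K == 3 and nmi(ap.labels, truth) == 1.0


class TestRelabelingInvariance:
    def test_permuted_input_gives_equivalent_partition(self, rng):
        A = np.zeros((9, 9))
        A[:3, :3] = A[3:6, 3:6] = A[6:, 6:] = 0.9
        np.fill_diagonal(A, 1.0)
        res = community_detection(sim(A))
        perm = rng.permutation(9)
        res_p = community_detection(sim(A[np.ix_(perm, perm)]))
        assert nmi(res.labels[perm], res_p.labels) == 1.0
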