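"""Permutation testing, AES, clustering and the adjacency-reduction edit."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from istpower.adjacency_stats import (
    adjacency_clustering,
    aes_distribution,
    aes_matrix,
    aes_z_test,
    estimate_parameters,
    permutation_test,
    reduce_adjacency,
    welch_z_test,
    AESDistribution,
)
from istpower.core import SpatialParameters
from istpower.errors import DegenerateComparisonError, InvalidParameterError
from istpower.labeling_heuristic import generate_ist, heuristic_assign
from conftest import make_tissue


def brute_force_pair_edges(tissue):
    """Edge-by-edge census oracle for the AES numerator."""
    K = tissue.K
    counts = np.zeros((K, K))
    for u, v in tissue.scaffold.graph.edges:
        a, b = tissue.labels[u], tissue.labels[v]
        if a == b:
            counts[a, a] += 1
        else:
            counts[a, b] += 1
            counts[b, a] += 1
    return counts


class TestEstimateParameters:
    def test_single_edge_two_types(self):
        tissue = make_tissue(nx.Graph([(0, 1)]), [0, 1], 2)
        params = estimate_parameters(tissue)
        assert np.allclose(params.p, [0.5, 0.5])
        assert np.allclose(params.H, [[0, 1], [1, 0]])

    def test_monotype_tissue(self):
        tissue = make_tissue(nx.complete_graph(4), [0, 0, 0, 0], 1)
        params = estimate_parameters(tissue)
        assert np.allclose(params.p, [1.0])
        assert np.allclose(params.H, [[1.0]])

    def test_round_trip_recovery(self, scaffold_2k):
        # generate from (p, H), re-estimate, compare entrywise
        H = np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6]])
        target = SpatialParameters(p=[1 / 3, 1 / 3, 1 / 3], H=H)
        tissue = generate_ist(scaffold_2k, target, correction_iters=3000, seed=3)
        est = estimate_parameters(tissue)
        assert np.abs(est.H - H).mean() < 0.05
        assert np.abs(est.p - target.p).max() < 0.05


class TestPermutationTest:
    def test_minimum_attainable_p(self):
        # a perfectly anti-assortative 2-coloring of a cycle: every shuffle
        # is strictly less cross-type adjacent, so p floors at 1/(n+1)
        g = nx.cycle_graph(20)
        tissue = make_tissue(g, [i % 2 for i in range(20)], 2)
        res = permutation_test(tissue, n_trials=100, seed=0)
        assert res.p_enrich.min() >= 1 / 101
        assert res.p_enrich[0, 1] <= 2 / 101
        assert res.p_avoid[0, 0] <= 2 / 101
        assert np.all(res.p_enrich > 0) and np.all(res.p_enrich <= 1)
        assert np.all(res.p_avoid > 0) and np.all(res.p_avoid <= 1)

    def test_alternating_cycle_extremes(self):
        g = nx.cycle_graph(30)
        tissue = make_tissue(g, [i % 2 for i in range(30)], 2)
        res = permutation_test(tissue, n_trials=199, seed=1)
        # cross-type adjacency maximally enriched, same-type maximally avoided
        assert res.p_enrich[0, 1] == res.p_enrich.min()
        assert res.p_avoid[0, 0] == res.p_avoid.min()

    def test_shuffles_preserve_multiset_and_graph(self, scaffold_small):
        params = SpatialParameters.uniform_neighbors(np.array([0.3, 0.7]))
        tissue = heuristic_assign(scaffold_small, params, seed=2)
        edges = sorted(tissue.scaffold.graph.edges)
        res = permutation_test(tissue, n_trials=50, seed=3)
        assert sorted(tissue.scaffold.graph.edges) == edges
        assert res.n_trials == 50

    def test_type_one_error_calibration(self, scaffold_2k):
        # on null ISTs the enrichment test rejects at ~ the nominal rate
        K = 4
        params = SpatialParameters.uniform_neighbors(np.full(K, 1 / K))
        rejections = []
        for seed in range(12):
            tissue = heuristic_assign(scaffold_2k, params, seed=100 + seed)
            res = permutation_test(tissue, n_trials=199, seed=seed)
            rejections.extend((res.p_enrich < 0.05).ravel().tolist())
        rate = np.mean(rejections)
        se = np.sqrt(0.05 * 0.95 / len(rejections))
        assert abs(rate - 0.05) < 3 * se + 1 / 200


class TestAESMatrix:
    def test_complete_bipartite_hand_values(self):
        g = nx.complete_bipartite_graph(2, 2)
        tissue = make_tissue(g, [0, 0, 1, 1], 2)
        m = aes_matrix(tissue)
        # 4 A-B edges, expectation 2 f_A f_B |E| = 2 * .5 * .5 * 4 = 2
        assert m.aes[0, 1] == pytest.approx(1.0)
        assert m.aes[0, 0] == pytest.approx(-1.0)

    def test_matches_brute_force_census(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            n = int(rng.integers(8, 40))
            g = nx.gnp_random_graph(n, 0.3, seed=trial)
            if g.number_of_edges() == 0:
                continue
            K = int(rng.integers(2, 5))
            labels = rng.integers(0, K, n)
            tissue = make_tissue(g, labels, K)
            m = aes_matrix(tissue)
            assert np.array_equal(m.n_edges, brute_force_pair_edges(tissue))

    def test_null_mean_aes_near_zero(self, scaffold_2k):
        # exact permutation mean is 1/(n-1), negligible at this tissue size
        params = SpatialParameters.uniform_neighbors(np.array([0.5, 0.5]))
        tissue = heuristic_assign(scaffold_2k, params, seed=1)
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(1000):
            shuffled = tissue.with_labels(rng.permutation(tissue.labels))
            vals.append(aes_matrix(shuffled).aes[0, 1])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_aes_lower_bound(self, scaffold_small):
        params = SpatialParameters.uniform_neighbors(np.array([0.25, 0.25, 0.5]))
        tissue = heuristic_assign(scaffold_small, params, seed=2)
        m = aes_matrix(tissue)
        assert np.nanmin(m.aes) >= -1.0

    def test_undefined_pair_is_nan(self):
        g = nx.Graph([(0, 1)])
        tissue = make_tissue(g, [0, 0], 2)  # type 1 absent
        m = aes_matrix(tissue)
        assert np.isnan(m.aes[0, 1]) and np.isnan(m.aes[1, 1])
        assert np.isfinite(m.aes[0, 0])


class TestAESDistribution:
    def test_full_fov_degenerates_to_whole_tissue(self, scaffold_small):
        params = SpatialParameters.uniform_neighbors(np.array([0.5, 0.5]))
        tissue = heuristic_assign(scaffold_small, params, seed=3)
        whole = aes_matrix(tissue).aes[0, 1]
        dist = aes_distribution(tissue, (0, 1), 1.0, n_fov=10, seed=4)
        assert np.allclose(dist.samples, whole)
        assert dist.sd == pytest.approx(0.0)
        assert dist.mean == pytest.approx(whole)

    def test_fitted_mean_is_sample_mean(self, scaffold_2k):
        params = SpatialParameters.uniform_neighbors(np.array([0.5, 0.5]))
        tissue = heuristic_assign(scaffold_2k, params, seed=5)
        dist = aes_distribution(tissue, (0, 1), 0.05, n_fov=50, seed=6)
        assert dist.mean == pytest.approx(dist.samples.mean())
        assert dist.sd == pytest.approx(dist.samples.std(ddof=0))

    def test_larger_fovs_tighter_distribution(self, scaffold_2k):
        params = SpatialParameters(p=[0.5, 0.5], H=[[0.8, 0.2], [0.2, 0.8]])
        tissue = generate_ist(scaffold_2k, params, correction_iters=1000, seed=7)
        sds = [
            aes_distribution(tissue, (0, 1), f, n_fov=100, seed=8).sd
            for f in (0.05, 0.075, 0.10)
        ]
        assert sds[0] > sds[2]


class TestAESZTest:
    def test_hand_value(self):
        d1 = AESDistribution(samples=np.zeros(100), mean=1.0, sd=1.0, n=100)
        d2 = AESDistribution(samples=np.zeros(100), mean=0.0, sd=1.0, n=100)
        z, p = aes_z_test(d1, d2)
        assert z == pytest.approx(1 / np.sqrt(0.2), abs=1e-9)
        assert z == pytest.approx(2.236, abs=1e-3)
        assert p == pytest.approx(stats.norm.sf(z))
        assert p == pytest.approx(0.0127, abs=1e-3)

    def test_identical_distributions(self):
        d = AESDistribution(samples=np.zeros(10), mean=0.5, sd=0.2, n=10)
        z, p = aes_z_test(d, d)
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_antisymmetry(self):
        d1 = AESDistribution(samples=np.zeros(30), mean=0.4, sd=0.5, n=30)
        d2 = AESDistribution(samples=np.zeros(30), mean=0.1, sd=0.3, n=30)
        z12, _ = aes_z_test(d1, d2)
        z21, _ = aes_z_test(d2, d1)
        assert z12 == pytest.approx(-z21)

    def test_degenerate_comparison(self):
        d = AESDistribution(samples=np.zeros(10), mean=0.0, sd=0.0, n=10)
        with pytest.raises(DegenerateComparisonError):
            aes_z_test(d, d)

    def test_welch_variant_differs_by_name_not_silently(self):
        d1 = AESDistribution(samples=np.zeros(50), mean=1.0, sd=1.0, n=50)
        d2 = AESDistribution(samples=np.zeros(50), mean=0.0, sd=1.0, n=50)
        z_printed, _ = aes_z_test(d1, d2)
        z_welch, _ = welch_z_test(d1, d2)
        assert z_printed != z_welch  # the two statistics are distinct


class TestAdjacencyClustering:
    def test_identical_profiles_merge_at_zero(self):
        profiles = np.array([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9]])
        Z, _ = adjacency_clustering(profiles)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        profiles = rng.random((6, 8))
        _, labels_a = adjacency_clustering(profiles, n_clusters=2)
        perm = np.array([3, 1, 5, 0, 2, 4])
        _, labels_b = adjacency_clustering(profiles[perm], n_clusters=2)
        # same partition after undoing the permutation
        remapped = np.empty(6, dtype=int)
        remapped[perm] = labels_b
        same = np.array([
            (labels_a[i] == labels_a[j]) == (remapped[i] == remapped[j])
            for i in range(6) for j in range(6)
        ])
        assert same.all()

    def test_separates_structured_from_null_cohort(self, scaffold_small):
        # 25 self-preference ISTs vs 25 null ISTs, clustered on their
        # flattened enrichment p-value profiles
        structured = SpatialParameters(p=[0.5, 0.5], H=[[0.9, 0.1], [0.1, 0.9]])
        null = SpatialParameters.uniform_neighbors(np.array([0.5, 0.5]))
        profiles, truth = [], []
        for i in range(25):
            for params, tag in ((structured, 1), (null, 0)):
                tissue = heuristic_assign(scaffold_small, params, seed=1000 + 10 * i + tag)
                res = permutation_test(tissue, n_trials=99, seed=i)
                profiles.append(
                    np.concatenate([res.p_enrich.ravel(), res.p_avoid.ravel()])
                )
                truth.append(tag)
        _, labels = adjacency_clustering(np.array(profiles), n_clusters=2)
        truth = np.array(truth)
        agree = max(
            np.mean((labels == 1) == (truth == 1)),
            np.mean((labels == 2) == (truth == 1)),
        )
        assert agree >= 0.9

    def test_ragged_profiles_rejected(self):
        with pytest.raises(InvalidParameterError):
            adjacency_clustering([[0.1, 0.2], [0.1]])


class TestReduceAdjacency:
    def test_structured_reduction_hits_target(self, scaffold_2k):
        H = np.array([[0.5, 0.4, 0.1], [0.4, 0.5, 0.1], [0.05, 0.05, 0.9]])
        H = H / H.sum(axis=1, keepdims=True)
        params = SpatialParameters(p=[0.25, 0.25, 0.5], H=H)
        tissue = generate_ist(scaffold_2k, params, correction_iters=2000, seed=5)
        before = aes_matrix(tissue).n_edges[0, 1]
        edited = reduce_adjacency(tissue, (0, 1), 0.37, seed=7)
        after = aes_matrix(edited).n_edges[0, 1]
        assert 0.61 <= after / before <= 0.65
        assert np.array_equal(tissue.type_counts(), edited.type_counts())
        assert sorted(edited.scaffold.graph.edges) == sorted(
            tissue.scaffold.graph.edges
        )

    def test_invalid_reduction_values(self, scaffold_small):
        params = SpatialParameters.uniform_neighbors(np.array([0.5, 0.5]))
        tissue = heuristic_assign(scaffold_small, params, seed=0)
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(InvalidParameterError):
                reduce_adjacency(tissue, (0, 1), bad, seed=0)

    def test_absent_pair_rejected(self):
        tissue = make_tissue(nx.complete_graph(4), [0, 0, 0, 0], 2)
        with pytest.raises(InvalidParameterError):
            reduce_adjacency(tissue, (0, 1), 0.3, seed=0)
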