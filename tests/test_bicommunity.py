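import numpy as np
import pytest

from bimod import (
    BicommunityDetector,
    DirectedGraph,
    PartitionPair,
    bimodularity,
    cluster_edges,
    edge_features,
    extract_bicommunities,
    modularity_matrix,
    recovery_score,
    svd_components,
)

from conftest import random_directed_graph


@pytest.fixture
def four_node_fitted(four_node):
    mm = modularity_matrix(four_node)
    comps = svd_components(mm, 1)
    return four_node, mm, comps


class TestEdgeFeatures:
    def test_four_node_feature_rows(self, four_node_fitted):
        g, mm, comps = four_node_fitted
        fm = edge_features(g, comps, 1)
        r = 1 / np.sqrt(2)
        assert fm.F.shape == (2, 2)
        # row-major edge order: (1->3) then (2->4)
        assert fm.edges.tolist() == [[0, 2], [1, 3]]
        assert np.allclose(fm.F[0], [r, r])
        assert np.allclose(fm.F[1], [-r, -r])

    def test_features_scale_linearly_with_sigma(self, four_node_fitted):
        g, mm, comps = four_node_fitted
        fm = edge_features(g, comps, 1)
        import dataclasses

        doubled = [dataclasses.replace(c, sigma=2 * c.sigma) for c in comps]
        fm2 = edge_features(g, doubled, 1)
        assert np.allclose(fm2.F, 2 * fm.F)

    def test_errors(self, four_node_fitted):
        g, mm, comps = four_node_fitted
        with pytest.raises(ValueError, match="components"):
            edge_features(g, comps, 2)
        empty = DirectedGraph([1], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="no edges"):
            edge_features(empty, comps, 1)


class TestClusterEdges:
    def test_single_cluster(self, four_node_fitted):
        g, mm, comps = four_node_fitted
        fm = edge_features(g, comps, 1)
        assert cluster_edges(fm, 1, random_state=0).tolist() == [1, 1]

    def test_antipodal_edges_separate(self, four_node_fitted):
        g, mm, comps = four_node_fitted
        fm = edge_features(g, comps, 1)
        labels = cluster_edges(fm, 2, random_state=0)
        assert sorted(labels.tolist()) == [1, 2]

    def test_too_many_clusters_rejected(self, four_node_fitted):
        g, mm, comps = four_node_fitted
        fm = edge_features(g, comps, 1)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_edges(fm, 3)

    @pytest.mark.parametrize("seed", range(4))
    def test_labels_partition_edges_and_are_size_ordered(self, seed):
        rng = np.random.default_rng(seed)
        g = random_directed_graph(rng, 15, density=0.4)
        mm = modularity_matrix(g)
        fm = edge_features(g, svd_components(mm, 2), 2)
        labels = cluster_edges(fm, 4, random_state=seed)
        assert labels.shape == (fm.edges.shape[0],)
        assert set(labels) <= {1, 2, 3, 4}
        sizes = [np.sum(labels == k) for k in sorted(set(labels))]
        assert sizes == sorted(sizes, reverse=True)

    def test_determinism_and_reflection_invariance(self, seed=0):
        """Jointly negating a (u_k, v_k) pair is an isometry for k-means."""
        rng = np.random.default_rng(seed)
        g = random_directed_graph(rng, 15, density=0.4)
        comps = svd_components(modularity_matrix(g), 2)
        fm = edge_features(g, comps, 2)
        a = cluster_edges(fm, 3, random_state=7)
        b = cluster_edges(fm, 3, random_state=7)
        assert np.array_equal(a, b)
        import dataclasses

        flipped = [comps[0],
                   dataclasses.replace(comps[1], u=-comps[1].u, v=-comps[1].v)]
        c = cluster_edges(edge_features(g, flipped, 2), 3, random_state=7)
        assert recovery_score(a, c) == pytest.approx(1.0)


class TestExtractBicommunities:
    def test_four_node_clusters(self, four_node_fitted):
        g, mm, comps = four_node_fitted
        labels = np.array([1, 2])
        bcs = extract_bicommunities(g, mm, labels)
        assert len(bcs) == 2
        first = bcs[0]
        assert first.sending in ([1], [2]) and first.qbi == pytest.approx(0.25)
        assert all(b.kind == "directed" for b in bcs)
        assert {b.cluster_id for b in bcs} == {1, 2}
        # per-cluster indices of edge-disjoint blocks add up to the
        # partition-pair bimodularity of the induced mapping
        total = sum(b.qbi for b in bcs)
        induced = bimodularity(g, PartitionPair([1, 2, 2, 1], [2, 1, 1, 2]))
        assert total == pytest.approx(induced) == pytest.approx(0.5)

    def test_self_community_classification(self):
        # all edges inside one node set -> C_out == C_in -> "self"
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 2] = A[2, 0] = 1
        g = DirectedGraph([1, 2, 3], A)
        mm = modularity_matrix(g)
        bcs = extract_bicommunities(g, mm, np.array([1, 1, 1]))
        assert len(bcs) == 1 and bcs[0].kind == "self"
        assert bcs[0].sending == bcs[0].receiving == [1, 2, 3]
        assert all(r == "both" for r in bcs[0].node_roles.values())

    def test_node_roles_and_send_recv_scores(self):
        # edges 1->2, 1->3, 2->3 in one cluster
        A = np.zeros((3, 3))
        A[0, 1] = A[0, 2] = A[1, 2] = 1
        g = DirectedGraph(["a", "b", "c"], A)
        mm = modularity_matrix(g)
        (bc,) = extract_bicommunities(g, mm, np.array([1, 1, 1]))
        assert bc.node_roles == {"a": "sending", "b": "both", "c": "receiving"}
        assert bc.send_recv_score["a"] == pytest.approx(1.0)
        assert bc.send_recv_score["b"] == pytest.approx(0.0)
        assert bc.send_recv_score["c"] == pytest.approx(-1.0)

    def test_label_length_checked(self, four_node_fitted):
        g, mm, _ = four_node_fitted
        with pytest.raises(ValueError, match="labels for"):
            extract_bicommunities(g, mm, np.array([1]))


class TestRecoveryScore:
    def test_identical_labelings(self):
        assert recovery_score([1, 1, 2, 2], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_uninformative_labeling_scores_about_zero(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 4, size=400)
        assert abs(recovery_score(np.ones_like(truth), truth)) <= 1e-9

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            recovery_score([1, 2], [1, 2, 3])


class TestBicommunityDetectorEstimator:
    def test_four_node_end_to_end(self, four_node):
        det = BicommunityDetector(n_components=1, n_clusters=2, random_state=0)
        labels = det.fit_predict(four_node)
        assert sorted(labels.tolist()) == [1, 2]
        assert det.counts_by_kind() == {"self": 0, "directed": 2}
        assert [b.qbi for b in det.bicommunities_] == pytest.approx([0.25, 0.25])
        assert det.top_bicommunities(1)[0].qbi == pytest.approx(0.25)
        assert np.array_equal(det.labels_, det.edge_labels_)

    def test_same_seed_reproduces_labels(self):
        rng = np.random.default_rng(3)
        g = random_directed_graph(rng, 20, density=0.3)
        a = BicommunityDetector(n_clusters=4, random_state=11).fit_predict(g)
        b = BicommunityDetector(n_clusters=4, random_state=11).fit_predict(g)
        assert np.array_equal(a, b)

    def test_weighted_sampling_flag_runs(self):
        rng = np.random.default_rng(4)
        g = random_directed_graph(rng, 12, density=0.4, weighted=True)
        det = BicommunityDetector(n_clusters=3, random_state=0,
                                  weight_samples=True).fit(g)
        assert len(det.bicommunities_) <= 3

    def test_sklearn_param_interface(self):
        det = BicommunityDetector()
        params = det.get_params()
        assert params["n_clusters"] == 8 and params["n_components"] == 2
        det.set_params(n_clusters=3)
        assert det.n_clusters == 3
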