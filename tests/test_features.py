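import math

import networkx as nx
import numpy as np
import pytest

from vgerp import count_feature_grid
from vgerp.features import (
    SINGLE_FEATURES,
    average_clustering,
    ccss,
    channel_network_edges,
    clustering_sequence,
    coloring_number,
    density,
    extract_features,
    global_efficiency,
    graph_index_complexity,
    independence_number,
    local_efficiency,
    make_small_world_ref,
    max_clique,
    max_clique_size,
    maximum_independent_set,
    min_cut_size,
    read_feature_matrix,
    small_worldness,
    tsp_cost,
)


def k4_minus_edge():
    g = nx.complete_graph(4)
    g.remove_edge(0, 1)
    return g


class TestClustering:
    def test_triangle(self):
        assert np.array_equal(clustering_sequence(nx.complete_graph(3)), [1, 1, 1])

    def test_path_endpoints_by_convention(self):
        assert np.array_equal(clustering_sequence(nx.path_graph(3)), [0, 0, 0])

    def test_k4_minus_edge_by_hand(self):
        seq = clustering_sequence(k4_minus_edge())
        # nodes 0,1 have degree 2 with joined neighbors -> C=1;
        # nodes 2,3 have degree 3 and 2 of 3 neighbor pairs joined -> 2/3
        assert seq[0] == seq[1] == pytest.approx(1.0)
        assert seq[2] == seq[3] == pytest.approx(2 / 3)
        assert average_clustering(k4_minus_edge()) == pytest.approx(5 / 6)

    def test_path_average_is_zero(self):
        assert average_clustering(nx.path_graph(5)) == 0.0


class TestEfficiency:
    def test_complete_graph_is_fully_efficient(self):
        assert global_efficiency(nx.complete_graph(6)) == pytest.approx(1.0)

    def test_path3_by_hand(self):
        # ordered pairs: 4 at distance 1, 2 at distance 2 -> (4 + 2*0.5)/6
        assert global_efficiency(nx.path_graph(3)) == pytest.approx(5 / 6)

    def test_single_node_is_zero(self):
        assert global_efficiency(nx.empty_graph(1)) == 0.0

    def test_disconnected_signalled(self):
        with pytest.raises(ValueError):
            global_efficiency(nx.empty_graph(3))

    def test_local_triangle(self):
        assert local_efficiency(nx.complete_graph(3)) == pytest.approx(1.0)

    def test_local_path3_uses_full_graph_distances(self):
        # only the middle node has >= 2 neighbors; its neighbors 0 and 2 are
        # at full-graph distance 2, so it contributes 1/2 -> mean 1/6
        assert local_efficiency(nx.path_graph(3)) == pytest.approx(1 / 6)

    def test_local_edgeless_pair(self):
        assert local_efficiency(nx.empty_graph(2)) == 0.0


class TestSmallWorldness:
    def test_graph_as_its_own_reference_is_one(self):
        from vgerp.features import SmallWorldRef, _avg_path_length, _distances

        g = nx.complete_graph(5)
        ref = SmallWorldRef(g, average_clustering(g),
                            _avg_path_length(_distances(g)), 1.0, 0)
        assert small_worldness(g, ref) == pytest.approx(1.0)

    def test_complete_graph_beats_er_reference(self):
        ref = make_small_world_ref(5, 0.6, seed=1)
        if ref.c_r in (0.0, 1.0):  # need a non-degenerate reference
            ref = make_small_world_ref(5, 0.6, seed=4)
        assert small_worldness(nx.complete_graph(5), ref) > 1.0

    def test_zero_clustering_reference_signalled(self):
        from vgerp.features import SmallWorldRef, _avg_path_length, _distances

        p5 = nx.path_graph(5)
        ref = SmallWorldRef(p5, 0.0, _avg_path_length(_distances(p5)), 0.1, 0)
        with pytest.raises(ValueError):
            small_worldness(nx.complete_graph(5), ref)

    def test_reference_is_reproducible_and_connected(self):
        a = make_small_world_ref(37, 0.3, seed=2)
        b = make_small_world_ref(37, 0.3, seed=2)
        assert nx.utils.graphs_equal(a.graph, b.graph)
        assert nx.is_connected(a.graph)


class TestGIC:
    def test_path_graph_is_zero(self):
        # lambda_max of P_n is exactly 2 cos(pi/(n+1))
        assert graph_index_complexity(nx.path_graph(6)) == pytest.approx(0.0, abs=1e-9)

    def test_complete_graph_is_zero(self):
        # lambda_max = n - 1 makes c = 1
        assert graph_index_complexity(nx.complete_graph(7)) == pytest.approx(0.0, abs=1e-9)

    def test_star_closed_form(self):
        lo = 2 * math.cos(math.pi / 6)
        c = (2 - lo) / (4 - lo)
        assert graph_index_complexity(nx.star_graph(4)) == pytest.approx(4 * c * (1 - c))
        assert graph_index_complexity(nx.star_graph(4)) == pytest.approx(0.41675, abs=1e-4)

    def test_bounded_in_unit_interval_on_connected_graphs(self):
        # the path graph minimises lambda_max among connected graphs, so c
        # (hence GIC) is only guaranteed non-negative for connected input
        from conftest import random_connected_graph

        rng = np.random.default_rng(0)
        for _ in range(50):
            g = random_connected_graph(rng, n_max=12)
            assert 0.0 <= graph_index_complexity(g) <= 1.0


class TestCliqueAndIndependence:
    def test_complete_graph(self):
        assert max_clique_size(nx.complete_graph(5)) == 5
        assert independence_number(nx.complete_graph(5)) == 1

    def test_path(self):
        assert max_clique_size(nx.path_graph(5)) == 2
        assert independence_number(nx.path_graph(5)) == 3

    def test_edgeless(self):
        assert independence_number(nx.empty_graph(5)) == 5
        assert max_clique_size(nx.empty_graph(5)) == 1

    def test_returned_sets_are_verified_and_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            g = nx.gnp_random_graph(12, 0.5, seed=int(rng.integers(2**31)))
            c = max_clique(g)
            assert all(g.has_edge(a, b) for a in c for b in c if a < b)
            i = maximum_independent_set(g)
            assert not any(g.has_edge(a, b) for a in i for b in i if a < b)
            _, omega = nx.max_weight_clique(g, weight=None)
            assert len(c) <= omega

    def test_deterministic(self):
        g = nx.gnp_random_graph(20, 0.4, seed=9)
        assert max_clique(g) == max_clique(g)


class TestTSP:
    def test_complete_unit_metric_costs_n(self):
        assert tsp_cost(nx.complete_graph(4)) == 4

    def test_path_doubles_back(self):
        assert tsp_cost(nx.path_graph(4)) == 6

    def test_single_edge(self):
        assert tsp_cost(nx.path_graph(2)) == 2

    def test_disconnected_signalled(self):
        with pytest.raises(ValueError):
            tsp_cost(nx.empty_graph(3))


class TestDensityCutColoring:
    def test_density_examples(self):
        assert density(nx.complete_graph(5)) == 1.0
        assert density(nx.path_graph(5)) == pytest.approx(0.4)
        assert density(nx.empty_graph(5)) == 0.0

    def test_min_cut_examples(self):
        assert min_cut_size(nx.path_graph(5)) == 1
        assert min_cut_size(nx.complete_graph(4)) == 3
        assert min_cut_size(nx.cycle_graph(6)) == 2

    def test_min_cut_disconnected_signalled(self):
        with pytest.raises(ValueError):
            min_cut_size(nx.empty_graph(4))

    def test_coloring_examples(self):
        assert coloring_number(nx.complete_graph(4)) == 4
        assert coloring_number(nx.path_graph(4)) == 2
        assert coloring_number(nx.empty_graph(5)) == 1


class TestCCSS:
    def test_identical_graphs_give_one(self):
        g = k4_minus_edge()
        assert ccss(g, g) == pytest.approx(1.0)

    def test_constant_sequence_gives_zero_by_convention(self):
        assert ccss(nx.complete_graph(4), k4_minus_edge()) == 0.0

    def test_anticorrelated_sequences_give_one(self):
        a = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        assert ccss(a, b) == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ccss(np.zeros(3), np.zeros(4))


class TestChannelNetwork:
    def test_identical_channels_fully_connected(self):
        g = k4_minus_edge()  # non-degenerate clustering sequence
        assert channel_network_edges([g] * 15, theta=0.25) == 105

    def test_threshold_one_gives_empty_network(self):
        g = k4_minus_edge()
        assert channel_network_edges([g] * 15, theta=1.0) == 0

    def test_pairwise_threshold_count(self):
        # orthonormal zero-mean basis gives exact pairwise |r| = .5, .3, .15:
        # two of three pairs clear theta = 0.25
        f1 = np.array([0.5, -0.5, 0.5, -0.5])
        f2 = np.array([0.5, 0.5, -0.5, -0.5])
        f3 = np.array([0.5, -0.5, -0.5, 0.5])
        a, b, c = f1, 0.5 * f1 + 0.866 * f2, 0.3 * f1 + 0.954 * f3
        assert ccss(a, b) == pytest.approx(0.5, abs=1e-3)
        assert ccss(a, c) == pytest.approx(0.3, abs=1e-3)
        assert ccss(b, c) == pytest.approx(0.15, abs=1e-3)
        assert channel_network_edges([a, b, c], theta=0.25) == 2

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            channel_network_edges([np.zeros(3), np.zeros(4)])


class TestExtractFeatures:
    def test_column_count_small_grid(self, tiny_features):
        # 3 channels x 2 bands x 11 features x 2 conditions + 2x2 CCSS
        assert tiny_features.shape[1] - 1 == count_feature_grid(3, 2, 11, 1, 2)
        assert not tiny_features.drop(columns="group").isna().any().any()

    def test_single_channel_grid_has_no_ccss_columns(self, tiny_cohort):
        from vgerp import preprocess_cohort

        sub = preprocess_cohort(tiny_cohort, bands=["raw"])
        sub.data = sub.data[:, :1, :, :1]
        sub.condition_names = sub.condition_names[:1]
        sub.channel_names = sub.channel_names[:1]
        feats, _ = extract_features(sub)
        assert feats.shape[1] - 1 == 11

    def test_deterministic(self, tiny_averaged):
        a, _ = extract_features(tiny_averaged)
        b, _ = extract_features(tiny_averaged)
        assert a.equals(b)

    def test_bounded_features_stay_in_range(self, tiny_features):
        for feat, lo, hi in [
            ("clustering", 0, 1),
            ("global_efficiency", 0, 1),
            ("local_efficiency", 0, 1),
            ("gic", 0, 1),
            ("density", 0, 1),
        ]:
            cols = [c for c in tiny_features.columns if c.startswith(feat + "__")]
            vals = tiny_features[cols].to_numpy()
            assert vals.min() >= lo and vals.max() <= hi

    def test_affine_invariance_of_features(self, tiny_averaged):
        import copy

        scaled = copy.copy(tiny_averaged)
        scaled.data = 3.0 * tiny_averaged.data + 5.0
        a, _ = extract_features(tiny_averaged)
        b, _ = extract_features(scaled)
        assert np.allclose(a.drop(columns="group"), b.drop(columns="group"))

    def test_csv_round_trip(self, tiny_features, tmp_path):
        path = tmp_path / "features.csv"
        tiny_features.to_csv(path)
        back = read_feature_matrix(path, expected_columns=count_feature_grid(3, 2, 11, 1, 2))
        assert np.allclose(back.drop(columns="group"), tiny_features.drop(columns="group"))


def test_monotone_features_under_edge_addition():
    """Density and global efficiency never decrease when an edge is added.

    (Average clustering is deliberately excluded: the new edge raises the
    endpoints' degree denominators, so it can decrease.)
    """
    rng = np.random.default_rng(8)
    for _ in range(20):
        g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            continue
        non_edges = list(nx.non_edges(g))
        if not non_edges:
            continue
        u, v = non_edges[int(rng.integers(len(non_edges)))]
        g2 = g.copy()
        g2.add_edge(u, v)
        assert density(g2) >= density(g)
        assert global_efficiency(g2) >= global_efficiency(g)
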