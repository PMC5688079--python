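"""Fixed-threshold networks and the metric battery."""

import numpy as np
import pytest

from oracles import (all_graphs, brute_clustering, brute_components,
                     brute_density, brute_path_length, brute_transitivity)
from wiringcost.connectivity import ConnectivityMatrix
from wiringcost.graph_metrics import (METRIC_NAMES, BinaryNetwork,
                                      compute_metrics, condition_difference,
                                      threshold_fixed)


def _conn(values):
    return ConnectivityMatrix(values=np.asarray(values, float),
                              measure="spearman_power")


def _net(adj):
    return BinaryNetwork(adjacency=np.asarray(adj), threshold=0.0)


class TestThresholdFixed:
    def test_mean_plus_population_sd(self):
        # off-diag {0.1, 0.2, 0.9}: mean 0.4, population SD 0.35590 ->
        # tau ~ 0.7559; only the 0.9 edge survives
        v = np.array([[0.0, 0.1, 0.2],
                      [0.1, 0.0, 0.9],
                      [0.2, 0.9, 0.0]])
        B = threshold_fixed(_conn(v))
        mu = (0.1 + 0.2 + 0.9) / 3
        sd = np.sqrt(((0.1 - mu)**2 + (0.2 - mu)**2 + (0.9 - mu)**2) / 3)
        assert B.threshold == pytest.approx(mu + sd)
        assert B.threshold == pytest.approx(0.7559, abs=1e-4)
        assert B.adjacency.sum() == 2  # one undirected edge
        assert B.adjacency[1, 2] == 1
        assert B.rule == "superlevel"

    def test_constant_matrix_gives_complete_graph(self):
        v = 0.4 * (np.ones((4, 4)) - np.eye(4))
        B = threshold_fixed(_conn(v))
        assert B.threshold == pytest.approx(0.4)
        assert B.adjacency.sum() == 12  # complete on 4 nodes

    def test_two_channels_edge_present(self):
        B = threshold_fixed(_conn([[0.0, 0.3], [0.3, 0.0]]))
        assert B.adjacency[0, 1] == 1


class TestComputeMetrics:
    def test_triangle(self):
        m = compute_metrics(_net([[0, 1, 1], [1, 0, 1], [1, 1, 0]]))
        assert m["clustering"] == pytest.approx(1.0)
        assert m["transitivity"] == pytest.approx(1.0)
        assert m["density"] == pytest.approx(1.0)
        assert m["n_components"] == 1
        assert m["char_path_length"] == pytest.approx(1.0)
        assert m["gtom"] == pytest.approx(1.0)
        assert m["matching_index"] == pytest.approx(1.0)

    def test_path_graph_4_nodes(self):
        a = np.zeros((4, 4), int)
        for i in range(3):
            a[i, i + 1] = a[i + 1, i] = 1
        m = compute_metrics(_net(a))
        assert m["char_path_length"] == pytest.approx(10 / 6)
        assert m["clustering"] == 0.0
        assert m["degree"] == pytest.approx(1.5)

    def test_empty_graph_conventions(self):
        m = compute_metrics(_net(np.zeros((5, 5), int)))
        assert m["density"] == 0.0
        assert m["n_components"] == 5
        assert m["degree"] == 0.0
        assert m["char_path_length"] == 0.0
        assert m["unreachable_pairs"] == 10
        assert all(np.isfinite(v) for v in m.values())

    def test_all_metrics_present_and_finite(self):
        rng = np.random.default_rng(0)
        a = (rng.random((7, 7)) > 0.6).astype(int)
        a = ((a + a.T) > 0).astype(int)
        np.fill_diagonal(a, 0)
        m = compute_metrics(_net(a))
        for name in METRIC_NAMES:
            assert name in m and np.isfinite(m[name])
        assert 0 <= m["density"] <= 1
        assert 0 <= m["clustering"] <= 1
        assert 0 <= m["transitivity"] <= 1

    def test_agrees_with_brute_force_on_4_node_graphs(self):
        # exhaustive over all 64 labelled graphs on 4 nodes (the full
        # 1024-graph 5-node sweep runs in the acceptance suite)
        for a in all_graphs(4):
            m = compute_metrics(_net(a))
            cpl, unreach = brute_path_length(a)
            assert m["density"] == pytest.approx(brute_density(a))
            assert m["clustering"] == pytest.approx(brute_clustering(a))
            assert m["transitivity"] == pytest.approx(brute_transitivity(a))
            assert m["n_components"] == len(brute_components(a))
            assert m["char_path_length"] == pytest.approx(cpl)
            assert m["unreachable_pairs"] == unreach

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(1)
        a = (rng.random((6, 6)) > 0.5).astype(int)
        a = ((a + a.T) > 0).astype(int)
        np.fill_diagonal(a, 0)
        perm = rng.permutation(6)
        b = a[np.ix_(perm, perm)]
        ma, mb = compute_metrics(_net(a)), compute_metrics(_net(b))
        for name in METRIC_NAMES:
            assert ma[name] == pytest.approx(mb[name], abs=1e-9), name

    def test_adding_edge_never_hurts_density_or_path_length(self):
        rng = np.random.default_rng(2)
        a = (rng.random((6, 6)) > 0.7).astype(int)
        a = ((a + a.T) > 0).astype(int)
        np.fill_diagonal(a, 0)
        m0 = compute_metrics(_net(a))
        free = [(i, j) for i in range(6) for j in range(i + 1, 6)
                if not a[i, j]]
        for i, j in free[:5]:
            b = a.copy()
            b[i, j] = b[j, i] = 1
            m1 = compute_metrics(_net(b))
            assert m1["density"] >= m0["density"]
            # reachable-pairs convention: new edges can only shorten or
            # newly connect; the mean over reachable pairs may rise when
            # distant pairs join, so compare against the same pair set
            if m0["unreachable_pairs"] == m1["unreachable_pairs"]:
                assert m1["char_path_length"] <= m0["char_path_length"] + 1e-12


class TestConditionDifference:
    def test_identical_vectors_are_zero(self):
        m = compute_metrics(_net([[0, 1], [1, 0]]))
        d = condition_difference(m, m)
        assert all(v == 0.0 for v in d.values())

    def test_sign_convention_ec_minus_eo(self):
        d = condition_difference({"density": 0.5}, {"density": 0.3})
        assert d["density"] == pytest.approx(0.2)

    def test_name_mismatch_rejected(self):
        with pytest.raises(ValueError):
            condition_difference({"density": 1.0}, {"clustering": 1.0})

    def test_cohort_gives_one_point_per_subject(self):
        diffs = [condition_difference({"density": 0.1 * k}, {"density": 0.0})
                 for k in range(11)]
        assert len(diffs) == 11
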