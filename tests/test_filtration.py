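"""Threshold-sweep filtration contracts."""

import numpy as np
import pytest

from wiringcost.connectivity import ConnectivityMatrix
from wiringcost.filtration import (build_threshold_vector, evaluate_curves,
                                   filtrate, filtration_difference)
from wiringcost.graph_metrics import binarize
from wiringcost.wiring import WiringCostMatrix


def _conn(values):
    return ConnectivityMatrix(values=np.asarray(values, float),
                              measure="spearman_power")


def _toy3():
    # pair values: (0,1)=0.2, (0,2)=0.5, (1,2)=0.8
    F = _conn([[0.0, 0.2, 0.5],
               [0.2, 0.0, 0.8],
               [0.5, 0.8, 0.0]])
    D = np.array([[0.0, 10.0, 20.0],
                  [10.0, 0.0, 30.0],
                  [20.0, 30.0, 0.0]])
    return F, D


class TestBuildThresholdVector:
    def test_upper_triangle_multiset(self):
        F = _conn([[0.0, 0.3, 0.7], [0.3, 0.0, 0.7], [0.7, 0.7, 0.0]])
        T = build_threshold_vector(F)
        assert np.allclose(T, [0.3, 0.7, 0.7])
        assert np.allclose(build_threshold_vector(F, deduplicate=True),
                           [0.3, 0.7])

    def test_two_channels_single_threshold(self):
        T = build_threshold_vector(_conn([[0.0, 0.4], [0.4, 0.0]]))
        assert np.allclose(T, [0.4])

    def test_bounds_are_min_and_max_offdiagonal(self):
        rng = np.random.default_rng(0)
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        F = _conn(m)
        T = build_threshold_vector(F)
        off = F.offdiag()
        assert T[0] == off.min() and T[-1] == off.max()


class TestFiltrate:
    def test_toy_hand_enumeration(self):
        """3-channel sweep matches exhaustive hand enumeration."""
        F, D = _toy3()
        fr = filtrate(F, D=D, rule="sublevel")
        assert np.allclose(fr.thresholds, [0.2, 0.5, 0.8])
        # tau=0.2: single edge (0,1): density 1/3, cpl 1, cost 10*0.2
        # tau=0.5: path 1-0-2:      density 2/3, cpl (1+1+2)/3, + 20*0.5
        # tau=0.8: triangle:        density 1, cpl 1, + 30*0.8
        assert np.allclose(fr.curves["density"], [1 / 3, 2 / 3, 1.0])
        assert np.allclose(fr.curves["char_path_length"], [1.0, 4 / 3, 1.0])
        assert np.allclose(fr.curves["clustering"], [0.0, 0.0, 1.0])
        assert np.allclose(fr.curves["wiring_cost"],
                           [2.0, 2.0 + 10.0, 12.0 + 24.0])

    def test_sublevel_family_is_nested(self):
        rng = np.random.default_rng(3)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        F = _conn(m)
        prev = None
        for tau in build_threshold_vector(F):
            adj = binarize(F.values, tau, "sublevel")
            if prev is not None:
                assert np.all(adj >= prev)  # edges only appear
            prev = adj

    def test_density_monotone_components_nonincreasing(self):
        rng = np.random.default_rng(4)
        m = rng.random((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        fr = filtrate(_conn(m), D=np.ones((7, 7)), rule="sublevel")
        assert np.all(np.diff(fr.curves["density"]) >= 0)

    def test_extremes_empty_to_complete(self):
        F, D = _toy3()
        fr = filtrate(F, D=D, rule="sublevel")
        n = 3
        assert fr.curves["density"][-1] == pytest.approx(1.0)  # complete
        # just below the smallest threshold the family is empty
        vals = evaluate_curves(fr, np.array([fr.thresholds[0] - 1e-9]))
        assert vals["density"][0] == 0.0

    def test_wiring_cost_matrix_input(self):
        F, D = _toy3()
        W = WiringCostMatrix(values=D * F.values, measure="spearman_power",
                             band=(8, 12))
        fr = filtrate(W, rule="sublevel")
        # thresholds now live on the cost scale
        assert np.allclose(fr.thresholds, np.sort([2.0, 10.0, 24.0]))
        assert fr.curves["wiring_cost"][-1] == pytest.approx(36.0)

    def test_connectivity_without_distances_rejected(self):
        F, _ = _toy3()
        with pytest.raises(ValueError):
            filtrate(F, D=None)

    def test_step_function_changes_only_at_thresholds(self):
        F, D = _toy3()
        fr = filtrate(F, D=D, rule="sublevel")
        dense = np.linspace(0.1, 0.9, 97)
        vals = evaluate_curves(fr, dense)
        for name, curve in vals.items():
            changes = dense[np.flatnonzero(np.diff(curve) != 0) + 1]
            for c in changes:
                # every change bracket contains a stored threshold
                assert np.any((fr.thresholds > c - (0.8 / 96) - 1e-12)
                              & (fr.thresholds <= c + 1e-12))


class TestFiltrationDifference:
    def test_identical_matrices_zero_difference(self):
        F, D = _toy3()
        fr = filtrate(F, D=D)
        diff = filtration_difference(fr, fr)
        for name in ("clustering", "density", "char_path_length",
                     "wiring_cost"):
            assert np.allclose(diff[name], 0.0)

    def test_density_and_clustering_end_at_exactly_zero(self):
        F, D = _toy3()
        G = _conn(F.values * 0.9)  # different values, same structure
        diff = filtration_difference(filtrate(F, D=D), filtrate(G, D=D))
        assert diff["density"][-1] == 0.0
        assert diff["clustering"][-1] == 0.0

    def test_single_differing_entry_localised(self):
        """Difference is nonzero only between the two differing values."""
        a, b = 0.4, 0.6
        base = [[0.0, 0.2, a], [0.2, 0.0, 0.8], [a, 0.8, 0.0]]
        other = [[0.0, 0.2, b], [0.2, 0.0, 0.8], [b, 0.8, 0.0]]
        D = np.ones((3, 3)) - np.eye(3)
        d = filtration_difference(filtrate(_conn(base), D=D),
                                  filtrate(_conn(other), D=D))
        grid = d["thresholds"]
        inside = (grid >= a) & (grid < b)
        # density: EC gains its second edge at 0.4, EO at 0.6
        assert np.all(d["density"][inside] == pytest.approx(1 / 3))
        assert np.all(d["density"][~inside] == 0.0)

    def test_rule_mismatch_rejected(self):
        F, D = _toy3()
        with pytest.raises(ValueError):
            filtration_difference(filtrate(F, D=D, rule="sublevel"),
                                  filtrate(F, D=D, rule="superlevel"))

    def test_union_grid_contains_both_threshold_sets(self):
        F, D = _toy3()
        G = _conn(F.values * 0.77)
        d = filtration_difference(filtrate(F, D=D), filtrate(G, D=D))
        for tau in np.concatenate([filtrate(F, D=D).thresholds,
                                   filtrate(G, D=D).thresholds]):
            assert np.any(np.isclose(d["thresholds"], tau))
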