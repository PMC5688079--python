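"""Connectivity estimator correctness and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from wiringcost.connectivity import (connectivity_matrix, fisher_z,
                                     fisher_z_inverse, ispc, pli,
                                     spearman_power,
                                     windowed_connectivity_matrices)


class TestSpearmanPower:
    def test_identical_series_give_one(self):
        x = np.array([3.0, 1, 4, 1.5, 5, 9, 2, 6])
        assert spearman_power(x, x, fs=1.6, window_s=5.0) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(8.0)
        y = -x
        assert spearman_power(x, y, fs=1.6, window_s=5.0) == pytest.approx(-1.0)

    def test_matches_independent_spearman(self):
        px = np.array([3.0, 1, 4, 1.5, 5, 9, 2, 6])
        py = np.array([2.0, 7, 1, 8, 2.5, 8.5, 3, 9])
        ours = spearman_power(px, py, fs=1.6, window_s=5.0)
        assert ours == pytest.approx(spearmanr(px, py).statistic, abs=1e-12)

    def test_tied_ranks_match_independent_oracle(self):
        px = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        py = np.array([5.0, 2.0, 2.0, 7.0, 1.0, 7.0])
        ours = spearman_power(px, py, fs=1.2, window_s=5.0)
        assert ours == pytest.approx(spearmanr(px, py).statistic, abs=1e-12)

    def test_windowed_average(self):
        # two windows with correlations +1 and -1 average to 0
        px = np.concatenate([np.arange(5.0), np.arange(5.0)])
        py = np.concatenate([np.arange(5.0), -np.arange(5.0)])
        assert spearman_power(px, py, fs=1.0, window_s=5.0) == pytest.approx(0.0)

    def test_constant_window_skipped(self):
        px = np.concatenate([np.arange(5.0), np.ones(5)])
        py = np.concatenate([np.arange(5.0), np.arange(5.0)])
        assert spearman_power(px, py, fs=1.0, window_s=5.0) == pytest.approx(1.0)

    def test_all_windows_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_power(np.ones(10), np.arange(10.0), fs=2.0, window_s=5.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.random(10) * 10
        py = rng.random(10) * 10
        base = spearman_power(px, py, fs=2.0, window_s=5.0)
        warped = spearman_power(np.exp(px / 3), py**3, fs=2.0, window_s=5.0)
        assert warped == pytest.approx(base, abs=1e-12)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_maps_to_atanh_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_round_trip(self):
        r = np.array([-0.9, -0.3, 0.0, 0.42, 0.99])
        assert np.allclose(fisher_z_inverse(fisher_z(r)), r, atol=1e-12)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestISPC:
    def test_identical_phases_give_one(self):
        phi = np.linspace(0, 20, 500)
        assert ispc(phi, phi) == pytest.approx(1.0)

    def test_constant_offset_gives_one(self):
        phi = np.linspace(0, 20, 500)
        assert ispc(phi + 1.3, phi) == pytest.approx(1.0)

    def test_quarter_circle_differences_cancel(self):
        dphi = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert ispc(dphi, np.zeros(4)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(-np.pi, np.pi, (2, 100))
        assert ispc(a, b) == pytest.approx(ispc(b, a))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ispc(np.array([]), np.array([]))


class TestPLI:
    def test_constant_quarter_lead_gives_one(self):
        t = np.linspace(0, 10, 500)
        zx = np.exp(1j * (t + np.pi / 2))
        zy = np.exp(1j * t)
        assert pli(zx, zy) == pytest.approx(1.0)

    def test_alternating_lead_lag_cancels(self):
        dphi = np.tile([np.pi / 4, -np.pi / 4], 50)
        assert pli(np.exp(1j * dphi), np.ones(100, dtype=complex)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_zero_lag_gives_zero(self):
        # volume-conduction insensitivity: exactly in-phase signals score 0
        t = np.linspace(0, 10, 500)
        z = np.exp(1j * t)
        assert pli(z, z) == pytest.approx(0.0)
        assert pli(3 * z, z) == pytest.approx(0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(theta=st.floats(-np.pi, np.pi), seed=st.integers(0, 2**16))
    def test_invariant_under_common_unit_rotation(self, theta, seed):
        rng = np.random.default_rng(seed)
        zx = np.exp(1j * rng.uniform(-np.pi, np.pi, 200))
        zy = np.exp(1j * rng.uniform(-np.pi, np.pi, 200))
        rot = np.exp(1j * theta)
        assert pli(zx * rot, zy * rot) == pytest.approx(pli(zx, zy), abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        zx = np.exp(1j * rng.uniform(-np.pi, np.pi, 200))
        zy = np.exp(1j * rng.uniform(-np.pi, np.pi, 200))
        assert pli(zx, zy) == pytest.approx(pli(zy, zx))


class TestConnectivityMatrix:
    @pytest.mark.parametrize("measure", ["spearman_power", "ispc", "pli"])
    def test_symmetric_zero_diagonal(self, coupled_decomposition, measure):
        F = connectivity_matrix(coupled_decomposition, measure)
        assert np.allclose(F.values, F.values.T)
        assert np.all(np.diag(F.values) == 0)
        assert F.values.shape == (4, 4)

    @pytest.mark.parametrize("measure", ["ispc", "pli"])
    def test_phase_measures_bounded(self, coupled_decomposition, measure):
        F = connectivity_matrix(coupled_decomposition, measure)
        off = F.offdiag()
        assert np.all((off >= 0) & (off <= 1))

    def test_spearman_bounded(self, coupled_decomposition):
        off = connectivity_matrix(coupled_decomposition,
                                  "spearman_power").offdiag()
        assert np.all((off >= -1) & (off <= 1))

    def test_duplicate_channel_perfectly_correlated(self, coupled_decomposition):
        dec = coupled_decomposition
        import copy
        dup = copy.copy(dec)
        dup.z = np.concatenate([dec.z, dec.z[:1]], axis=0)
        dup.channels = dec.channels + ["TWIN"]
        F = connectivity_matrix(dup, "spearman_power")
        assert F.values[0, -1] == pytest.approx(1.0)

    def test_windowed_matrices_shape_and_mean(self, coupled_decomposition):
        mats = windowed_connectivity_matrices(coupled_decomposition,
                                              "spearman_power")
        F = connectivity_matrix(coupled_decomposition, "spearman_power")
        assert mats.ndim == 3 and mats.shape[1:] == (4, 4)
        assert np.allclose(mats.mean(axis=0), F.values, atol=1e-12)

    def test_single_channel_rejected(self, coupled_decomposition):
        import copy
        solo = copy.copy(coupled_decomposition)
        solo.z = coupled_decomposition.z[:1]
        solo.channels = coupled_decomposition.channels[:1]
        with pytest.raises(ValueError):
            connectivity_matrix(solo, "ispc")
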