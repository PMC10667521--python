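"""Radial profiles, cluster COMs, coexistence windows, and the demixing score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condmix.density import (coexisting_densities, demixing_measure,
                             largest_cluster_com, radial_density_profile,
                             site_histogram, system_com)


class TestSiteHistogram:
    @pytest.mark.parametrize("L", [4, 7, 12])
    def test_total_site_count_is_L_cubed(self, L):
        H0 = site_histogram(L, (L / 2, L / 2, L / 2))
        assert H0.sum() == L ** 3

    def test_fractional_center_also_exact(self):
        H0 = site_histogram(8, (3.3, 4.7, 2.1))
        assert H0.sum() == 8 ** 3


class TestRadialProfile:
    def test_fully_occupied_lattice_is_one_everywhere(self):
        L = 6
        ax = np.arange(L)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        beads = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        p = radial_density_profile(beads, (L / 2,) * 3, L)
        assert np.allclose(p.rho[p.defined], 1.0)

    def test_single_bead_at_center(self):
        L = 9
        center = (4, 4, 4)
        p = radial_density_profile(np.array([[4, 4, 4]]), center, L)
        H0 = site_histogram(L, center)
        assert p.rho[0] == pytest.approx(1.0 / H0[0])
        assert np.nansum(p.rho[1:]) == 0.0

    def test_counts_conserved(self, rng):
        L = 10
        beads = rng.integers(0, L, size=(40, 3))
        p = radial_density_profile(beads, (5.2, 4.8, 5.0), L)
        assert p.counts.sum() == 40

    def test_empty_component_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="empty"):
            p = radial_density_profile(np.empty((0, 3)), (2, 2, 2), 5)
        assert np.nansum(p.rho) == 0.0


class TestClusterCOM:
    def test_single_molecule_is_its_own_com(self):
        pts = np.array([[2, 2, 2], [2, 2, 3], [2, 3, 3]])
        com = largest_cluster_com(pts, L=10)
        assert np.allclose(com, pts.mean(axis=0), atol=1e-9)

    def test_largest_of_two_clusters_wins(self):
        big = np.array([[1, 1, 1], [1, 1, 2], [1, 2, 2], [2, 2, 2], [2, 2, 3]])
        small = np.array([[8, 8, 8], [8, 8, 9], [8, 9, 9]])
        com = largest_cluster_com(np.vstack([big, small]), L=12)
        assert np.allclose(com, big.mean(axis=0), atol=1e-9)

    def test_boundary_straddling_cluster_against_shifted_oracle(self):
        L = 10
        # cluster wrapping through the x=0 face
        pts = np.array([[9, 5, 5], [0, 5, 5], [1, 5, 5]])
        com = largest_cluster_com(pts, L=L)
        # shift-and-average oracle: recenter, average, shift back
        shifted = (pts + np.array([3, 0, 0])) % L
        oracle = (shifted.mean(axis=0) - [3, 0, 0]) % L
        assert np.allclose(com, oracle, atol=1e-9)

    def test_system_com_periodic_against_shift(self, rng):
        L = 16
        pts = rng.integers(0, 4, size=(30, 3))  # compact blob near origin face
        com = system_com(pts, L)
        shift = np.array([5, 7, 2])
        com2 = system_com((pts + shift) % L, L)
        assert np.allclose((com + shift) % L, com2, atol=1e-6)


class TestCoexistence:
    def test_constant_profile_gives_equal_phases(self):
        from condmix.density import DensityProfile
        n = 80
        prof = DensityProfile(rho=np.full(n, 0.37), counts=np.ones(n),
                              site_counts=np.ones(n),
                              edges=np.arange(n + 1) * 0.25,
                              center=np.zeros(3), L=20)
        cx = coexisting_densities(prof)
        assert cx.dense == pytest.approx(0.37)
        assert cx.dilute == pytest.approx(0.37)

    def test_window_arithmetic(self):
        # synthetic profile: rho=0.8 in the first 13 bins, 0.01 elsewhere
        from condmix.density import DensityProfile
        n = 100
        rho = np.full(n, 0.01)
        rho[:13] = 0.8
        prof = DensityProfile(rho=rho, counts=rho, site_counts=np.ones(n),
                              edges=np.arange(n + 1) * 0.25,
                              center=np.zeros(3), L=40)
        cx = coexisting_densities(prof)
        assert cx.dense == pytest.approx(0.8)
        assert cx.dilute == pytest.approx(0.01)
        assert cx.dilute_window == (n - 35, n - 15)

    def test_short_profile_raises(self):
        from condmix.density import DensityProfile
        prof = DensityProfile(rho=np.ones(30), counts=np.ones(30),
                              site_counts=np.ones(30),
                              edges=np.arange(31) * 0.25,
                              center=np.zeros(3), L=8)
        with pytest.raises(ValueError):
            coexisting_densities(prof)

    def test_dilute_window_bin_count_for_reference_box(self):
        # L=100, bin 0.25: ceil(sqrt(3)*50/0.25) bins in total
        L = 100
        n_bins = int(np.ceil(np.sqrt(3) * L / 2 / 0.25))
        p = radial_density_profile(np.array([[0, 0, 0]]), (L / 2,) * 3, L)
        assert len(p.rho) == n_bins


class TestDemixingScore:
    def test_identical_profiles_score_zero(self):
        p = np.array([0.2, 0.5, 0.3])
        assert demixing_measure(p, p).D == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_score_one(self):
        assert demixing_measure(np.array([1.0, 0.0]),
                                np.array([0.0, 1.0])).D == 1.0

    def test_two_bin_hand_computed_case(self):
        score = demixing_measure(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert score.D == pytest.approx(np.sqrt(1 - np.sqrt(0.5)), abs=1e-12)
        assert score.D == pytest.approx(0.5412, abs=1e-4)

    def test_zero_mass_profile_rejected(self):
        with pytest.raises(ValueError, match="zero-mass"):
            demixing_measure(np.zeros(3), np.array([1.0, 0, 0]))

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=30),
           st.lists(st.floats(0, 1e6), min_size=2, max_size=30))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_bounds_and_symmetry_under_fuzzing(self, a, b):
        n = min(len(a), len(b))
        p, q = np.array(a[:n]), np.array(b[:n])
        if p.sum() <= 0 or q.sum() <= 0:
            return
        d1 = demixing_measure(p, q)
        d2 = demixing_measure(q, p)
        assert 0.0 <= d1.D <= 1.0
        assert d1.D == pytest.approx(d2.D, abs=1e-9)
        assert d1.D == pytest.approx(np.sqrt(1 - d1.bhattacharyya), abs=1e-9)


class TestTwoBlobRecovery:
    def test_profile_peaks_at_planted_blob_separation(self, rng):
        """A dense blob at the center and a second blob at distance d produce
        profile peaks within one bin of 0 and d."""
        L = 30
        center = np.array([15.0, 15.0, 15.0])
        blob1 = (center + rng.normal(0, 0.8, (400, 3))).astype(int) % L
        d = 9.0
        blob2 = (center + [d, 0, 0] + rng.normal(0, 0.8, (400, 3))).astype(int) % L
        p1 = radial_density_profile(blob1, center, L)
        p2 = radial_density_profile(blob2, center, L)
        peak1 = p1.bin_centers[np.nanargmax(np.nan_to_num(p1.rho))]
        peak2 = p2.bin_centers[np.nanargmax(np.nan_to_num(p2.rho))]
        assert peak1 <= 1.0
        assert abs(peak2 - d) <= 1.0
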