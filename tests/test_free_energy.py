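"""Density inversion, WHAM, split-half errors and PMF stitching."""

import numpy as np
import pytest

from poregate.core_io import AtomIndexSet, Trajectory
from poregate.free_energy import (DensityProfile, FreeEnergyProfile,
                                  UmbrellaWindow, axial_density,
                                  boltzmann_invert, half_profile_error,
                                  split_half_error, stitch_pmf, wham)
from poregate.toysim import double_well_truth, sample_umbrella_windows
from poregate.units import kT as thermal_kT

from conftest import water_structure

KT = thermal_kT(298.0)
EDGES = np.arange(6.0, 30.01, 0.2)
CENTERS_2A = np.arange(6.0, 30.1, 2.0)   # 13 windows, 2 A apart


def quartic_pmf_errors(n_per_window, seed, spring=100.0):
    truth = double_well_truth()
    windows = sample_umbrella_windows(truth, CENTERS_2A, spring,
                                      n_per_window, seed=seed)
    res = wham(windows, EDGES)
    u = truth.energy(res.pmf.z)
    u -= u.min()
    m = res.pmf.valid_mask
    d = res.pmf.G[m] - u[m]
    d -= d.mean()
    rmsd = float(np.sqrt((d ** 2).mean()))
    inner = (res.pmf.z > 10) & (res.pmf.z < 26)
    barrier_err = float((res.pmf.G[inner].max() - res.pmf.G.min())
                        - u[inner].max())
    return res, rmsd, barrier_err


class TestAxialDensity:
    def _traj(self, frames):
        s = water_structure(frames[0])
        return Trajectory(s, np.asarray(frames, dtype=float), dt=1.0), \
            AtomIndexSet(np.arange(s.n_atoms))

    def test_single_particle_lands_in_its_bin(self):
        traj, sel = self._traj([[[0.0, 0.0, 5.0]]])
        d = axial_density(traj, sel, z_edges=np.arange(0, 10.1, 2.0))
        np.testing.assert_array_equal(d.counts, [0, 0, 1, 0, 0])

    def test_two_frames_average_half_each(self):
        traj, sel = self._traj([[[0, 0, 1.0]], [[0, 0, 5.0]]])
        d = axial_density(traj, sel, z_edges=np.arange(0, 10.1, 2.0))
        np.testing.assert_allclose(d.density, [0.5, 0, 0.5, 0, 0])

    def test_uniform_placement_uniform_within_poisson(self):
        rng = np.random.default_rng(2)
        n = 10000
        pts = np.column_stack([rng.uniform(-3, 3, (n, 2)),
                               rng.uniform(0, 10, n)[:, None]]).reshape(n, 3)
        # keep only the cylinder r <= 3 so the axial marginal is uniform
        traj, sel = self._traj([pts])
        edges = np.arange(0, 10.1, 1.0)
        d = axial_density(traj, sel, lateral_radius=3.0, z_edges=edges)
        expected = d.counts.sum() / len(d.counts)
        assert np.all(np.abs(d.counts - expected) <= 4 * np.sqrt(expected))

    def test_lateral_cylinder_excludes_outsiders(self):
        traj, sel = self._traj([[[0, 0, 5.0], [9.0, 0, 5.0]]])
        d = axial_density(traj, sel, lateral_radius=5.0,
                          z_edges=np.arange(0, 10.1, 2.0))
        assert d.counts.sum() == 1


class TestBoltzmannInvert:
    def test_uniform_density_gives_zero(self):
        d = DensityProfile(np.arange(0, 10.1, 1.0), np.full(10, 7.0), n_frames=1)
        prof = boltzmann_invert(d, bulk_zrange=(0, 10))
        np.testing.assert_allclose(prof.G, 0.0, atol=1e-14)

    def test_gaussian_density_inverts_to_quadratic(self):
        # rho = rho0 exp(-z^2) with kT = 1 kcal/mol -> G = z^2 exactly
        edges = np.arange(-3.0, 3.01, 0.25)
        zc = 0.5 * (edges[:-1] + edges[1:])
        d = DensityProfile(edges, 5.0 * np.exp(-zc ** 2), n_frames=1)
        T = 1.0 / 0.0019872041  # temperature at which kT = 1 kcal/mol
        prof = boltzmann_invert(d, temperature=T, bulk_zrange=(-0.2, 0.2))
        # bulk reference is the central bin (z = +-0.125): G offset z_bulk^2
        expected = zc ** 2 - (0.125 ** 2)
        np.testing.assert_allclose(prof.G, expected, atol=1e-10)

    def test_zero_count_bin_capped_and_flagged(self):
        counts = np.array([5.0, 5.0, 0.0, 5.0])
        d = DensityProfile(np.arange(0, 4.1, 1.0), counts, n_frames=1)
        prof = boltzmann_invert(d, bulk_zrange=(0, 2), cap=10.0)
        assert prof.G[2] == 10.0
        assert list(prof.capped_bins) == [2]

    def test_exp_composition_is_identity(self):
        rng = np.random.default_rng(0)
        edges = np.arange(0, 8.1, 0.5)
        rho = rng.uniform(0.5, 4.0, len(edges) - 1)
        d = DensityProfile(edges, rho, n_frames=1)
        prof = boltzmann_invert(d, temperature=298.0, bulk_zrange=(0, 8))
        rho_bulk = rho.mean()
        np.testing.assert_allclose(np.exp(-prof.G / KT) * rho_bulk, rho,
                                   rtol=1e-12)

    def test_empty_bulk_rejected(self):
        d = DensityProfile(np.arange(0, 4.1, 1.0), np.zeros(4), n_frames=1)
        with pytest.raises(ValueError):
            boltzmann_invert(d, bulk_zrange=(0, 4))


class TestWham:
    def test_near_zero_spring_reduces_to_histogram_inversion(self):
        rng = np.random.default_rng(5)
        samples = rng.normal(18.0, 3.0, size=20000)
        w = UmbrellaWindow(center=18.0, spring=1e-9, samples=samples)
        res = wham([w], EDGES)
        h = np.histogram(samples, bins=EDGES)[0]
        m = h > 0
        direct = -KT * np.log(h[m] / h[m].sum())
        direct -= direct.min()
        np.testing.assert_allclose(res.pmf.G[res.pmf.valid_mask], direct,
                                   atol=1e-10)

    def test_flat_truth_gives_flat_pmf(self):
        truth = double_well_truth(barrier_kT=0.0)  # a = 0: flat potential
        windows = sample_umbrella_windows(truth, CENTERS_2A, 100.0, 5000, seed=3)
        res = wham(windows, EDGES)
        m = res.pmf.valid_mask
        g = res.pmf.G[m] - res.pmf.G[m].mean()
        assert np.sqrt((g ** 2).mean()) <= 0.1 * KT

    def test_quartic_double_well_recovered(self):
        res, rmsd, barrier_err = quartic_pmf_errors(5000, seed=17)
        assert res.converged
        assert rmsd <= 0.15 * KT
        assert abs(barrier_err) <= 0.2 * KT

    def test_invariant_under_window_reordering(self):
        truth = double_well_truth()
        windows = sample_umbrella_windows(truth, CENTERS_2A, 100.0, 1000, seed=2)
        a = wham(windows, EDGES)
        b = wham(windows[::-1], EDGES)
        np.testing.assert_allclose(a.pmf.G, b.pmf.G, atol=1e-9)

    def test_merging_identical_windows_equals_concatenation(self):
        rng = np.random.default_rng(11)
        s1 = rng.normal(18, 1.5, 2000)
        s2 = rng.normal(18, 1.5, 2000)
        w_split = [UmbrellaWindow(18.0, 100.0, s1),
                   UmbrellaWindow(18.0, 100.0, s2)]
        w_merged = [UmbrellaWindow(18.0, 100.0, np.concatenate([s1, s2]))]
        edges = np.arange(12, 24.01, 0.2)
        a, b = wham(w_split, edges), wham(w_merged, edges)
        np.testing.assert_allclose(a.pmf.G, b.pmf.G, atol=1e-9)

    def test_non_overlapping_windows_flagged(self):
        rng = np.random.default_rng(1)
        w1 = UmbrellaWindow(8.0, 400.0, rng.normal(8.0, 0.5, 1000))
        w2 = UmbrellaWindow(28.0, 400.0, rng.normal(28.0, 0.5, 1000))
        res = wham([w1, w2], EDGES)
        assert not res.converged
        assert res.diagnostics is not None and "overlap" in res.diagnostics


class TestSplitHalfError:
    def test_duplicated_halves_give_zero_error(self):
        rng = np.random.default_rng(3)
        windows = []
        for c in CENTERS_2A:
            half = rng.normal(c, 1.5, 500)
            windows.append(UmbrellaWindow(c, 100.0, np.concatenate([half, half])))
        err, flagged = split_half_error(windows, EDGES)
        assert np.nanmax(err) <= 1e-9

    def test_constant_offset_halves_align_to_zero_error(self):
        z = np.arange(6, 30, 0.2)
        g = 0.05 * (z - 18.0) ** 2
        p1 = FreeEnergyProfile(z=z, G=g)
        p2 = FreeEnergyProfile(z=z, G=g + 3.7)
        err, flagged = half_profile_error(p1, p2)
        np.testing.assert_allclose(err, 0.0, atol=1e-12)
        assert len(flagged) == 0

    def test_capped_bins_flagged_not_scored(self):
        z = np.arange(0, 5.0)
        p1 = FreeEnergyProfile(z=z, G=np.zeros(5), capped_bins=np.array([4]))
        p2 = FreeEnergyProfile(z=z, G=np.zeros(5), capped_bins=np.array([0]))
        err, flagged = half_profile_error(p1, p2)
        assert set(flagged) == {0, 4}
        assert np.isnan(err[0]) and np.isnan(err[4])


class TestStitchPmf:
    def test_flat_profiles_with_offset_stitch_flat(self):
        z1 = np.arange(6.0, 20.01, 0.5)
        z2 = np.arange(18.0, 30.01, 0.5)
        a = FreeEnergyProfile(z=z1, G=np.zeros(len(z1)))
        b = FreeEnergyProfile(z=z2, G=np.full(len(z2), 3.0))
        out = stitch_pmf(a, b, overlap_zrange=(18.0, 20.0))
        np.testing.assert_allclose(out.G, 0.0, atol=1e-12)

    def test_quadratic_reconstructed_exactly(self):
        g = lambda z: 0.02 * (z - 15.0) ** 2
        z1 = np.arange(6.0, 20.01, 0.5)
        z2 = np.arange(18.0, 30.01, 0.5)
        a = FreeEnergyProfile(z=z1, G=g(z1))
        b = FreeEnergyProfile(z=z2, G=g(z2) + 2.0)  # arbitrary offset
        out = stitch_pmf(a, b, overlap_zrange=(18.0, 20.0))
        expected = g(out.z) - g(15.0)
        np.testing.assert_allclose(out.G, expected - expected.min(), atol=1e-9)

    def test_provenance_recorded(self):
        z1 = np.arange(6.0, 20.01, 0.5)
        z2 = np.arange(18.0, 30.01, 0.5)
        a = FreeEnergyProfile(z=z1, G=np.zeros(len(z1)))
        b = FreeEnergyProfile(z=z2, G=np.zeros(len(z2)))
        out = stitch_pmf(a, b, overlap_zrange=(18.0, 20.0))
        assert set(out.provenance) == {"umbrella", "blend", "equilibrium"}

    def test_disjoint_overlap_rejected(self):
        a = FreeEnergyProfile(z=np.arange(6.0, 12.0), G=np.zeros(6))
        b = FreeEnergyProfile(z=np.arange(20.0, 26.0), G=np.zeros(6))
        with pytest.raises(ValueError, match="overlap"):
            stitch_pmf(a, b, overlap_zrange=(12.0, 20.0))
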