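"""Synthetic generators: toy pore builder/dynamics, exact samplers, fixtures."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import chisquare

from poregate.toysim import (PRESETS, PotentialSpec, TelegraphConfig,
                             ToyPoreConfig, build_pore_system,
                             double_well_truth, free_state,
                             make_cylinder_fixture, make_funnel_fixture,
                             run_langevin, sample_umbrella_windows,
                             telegraph_series, wetting_fraction)
from poregate.units import kT as thermal_kT, spring_kj_nm2_to_kcal_A2

SMALL = ToyPoreConfig(n_solvent=40, box=(7.0, 7.0, 12.0), seed=3)


class TestBuildPoreSystem:
    def test_zero_solvent_rejected(self):
        with pytest.raises(ValueError, match="n_solvent"):
            ToyPoreConfig(n_solvent=0)

    def test_solvent_clears_walls(self):
        state = build_pore_system(SMALL)
        wall = state.structure.coords[state.wall_mask]
        solvent = state.structure.coords[~state.wall_mask]
        d, _ = cKDTree(wall).query(solvent)
        assert d.min() >= 0.8

    def test_identical_seeds_identical_systems(self):
        a = build_pore_system(SMALL)
        b = build_pore_system(SMALL)
        np.testing.assert_array_equal(a.structure.coords, b.structure.coords)

    def test_overfilled_box_errors(self):
        with pytest.raises(RuntimeError, match="density"):
            build_pore_system(ToyPoreConfig(n_solvent=2000,
                                            box=(6.0, 6.0, 10.0)))


class TestRunLangevin:
    def test_harmonic_trap_variance_matches_gibbs(self):
        # single free bead in a k=1 trap: Var(x) = kT/k per axis
        cfg = ToyPoreConfig(n_solvent=1, box=(40.0, 40.0, 40.0), seed=0,
                            temperature=1.0, dt=1e-3)
        state = free_state(cfg)
        traj = run_langevin(state, n_steps=1_000_000, sample_stride=20,
                            seed=9, trap_k=1.0)
        x = traj.frames[5000:, 0, :]          # discard equilibration
        var = x.var(axis=0).mean()
        # correlation time ~ gamma/k = 1e3 steps = 50 samples
        n_eff = len(x) / (2 * 50)
        se = 1.0 * np.sqrt(2.0 / n_eff)
        assert abs(var - 1.0) <= 3 * se

    def test_zero_temperature_from_rest_no_motion(self):
        cfg = ToyPoreConfig(n_solvent=8, box=(12.0, 12.0, 12.0),
                            temperature=0.0, seed=1)
        state = free_state(cfg)
        # corners of a cube, 4 sigma apart: outside every interaction range
        state.structure.coords[:] = np.array(
            [[sx, sy, sz] for sx in (-2.0, 2.0) for sy in (-2.0, 2.0)
             for sz in (-2.0, 2.0)])
        traj = run_langevin(state, n_steps=200, sample_stride=50, seed=1)
        for f in range(traj.n_frames):
            np.testing.assert_allclose(traj.frames[f], state.structure.coords,
                                       atol=1e-12)

    def test_identical_seeds_bit_identical(self):
        state = build_pore_system(SMALL)
        a = run_langevin(state, n_steps=400, sample_stride=100, seed=12)
        b = run_langevin(state, n_steps=400, sample_stride=100, seed=12)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_unstable_dt_rejected(self):
        cfg = dataclasses.replace(SMALL, dt=0.01)
        with pytest.raises(ValueError, match="dt"):
            run_langevin(build_pore_system(cfg), n_steps=100)

    def test_closed_box_axial_density_uniform(self):
        cfg = ToyPoreConfig(n_solvent=120, box=(8.0, 8.0, 12.0), seed=5)
        traj = run_langevin(free_state(cfg), n_steps=8000, sample_stride=40,
                            seed=5)
        z = traj.frames[50:, :, 2].ravel()
        edges = np.linspace(-6, 6, 9)
        counts = np.histogram(z, bins=edges)[0]
        expected = counts.sum() / len(counts)
        # frames are correlated: allow 4 Poisson SD on effective samples
        n_eff_scale = np.sqrt(len(traj.frames[50:]) / 8.0)
        assert np.all(np.abs(counts - expected)
                      <= 4 * np.sqrt(expected) * n_eff_scale)


class TestWettingFraction:
    def test_result_fields_and_equilibration_cut(self):
        cfg = dataclasses.replace(PRESETS["narrow-hydrophobic"], n_solvent=80,
                                  seed=2)
        state = build_pore_system(cfg)
        traj = run_langevin(state, n_steps=4000, sample_stride=40, seed=2)
        res = wetting_fraction(traj, cfg)
        assert 0.0 <= res.fraction <= 1.0
        assert res.n_frames == traj.n_frames - int(0.25 * traj.n_frames)
        with pytest.raises(ValueError):
            wetting_fraction(traj, cfg, equil_frac=1.0)


class TestUmbrellaSamplers:
    def test_flat_truth_gives_spring_gaussian(self):
        truth = PotentialSpec("flat", z_range=(0.0, 40.0))
        (w,) = sample_umbrella_windows(truth, [18.0], 100.0, 10_000, seed=4)
        kT = thermal_kT(298.0)
        var_expected = kT / spring_kj_nm2_to_kcal_A2(100.0)
        assert w.samples.mean() == pytest.approx(18.0, abs=0.05)
        assert w.samples.var() == pytest.approx(var_expected, rel=0.05)

    def test_harmonic_truth_product_gaussian(self):
        ku, zu = 0.5, 10.0
        truth = PotentialSpec("harmonic", {"k": ku, "z0": zu}, z_range=(0, 40))
        (w,) = sample_umbrella_windows(truth, [20.0], 150.0, 20_000, seed=8)
        kb = spring_kj_nm2_to_kcal_A2(150.0)
        kT = thermal_kT(298.0)
        mean = (ku * zu + kb * 20.0) / (ku + kb)
        var = kT / (ku + kb)
        assert w.samples.mean() == pytest.approx(mean, abs=0.03)
        assert w.samples.var() == pytest.approx(var, rel=0.05)

    def test_quartic_histogram_matches_density(self):
        truth = double_well_truth()
        (w,) = sample_umbrella_windows(truth, [18.0], 100.0, 20_000, seed=6)
        kT = thermal_kT(298.0)
        edges = np.linspace(12.0, 24.0, 25)
        zc = 0.5 * (edges[:-1] + edges[1:])
        p = np.exp(-(truth.energy(zc)
                     + 0.5 * spring_kj_nm2_to_kcal_A2(100.0)
                     * (zc - 18.0) ** 2) / kT)
        obs = np.histogram(w.samples, bins=edges)[0]
        exp = p / p.sum() * obs.sum()
        keep = exp > 5
        stat, pvalue = chisquare(obs[keep], exp[keep] * obs[keep].sum()
                                 / exp[keep].sum())
        assert pvalue > 0.01

    def test_sampler_converges_at_root_n(self):
        truth = PotentialSpec("flat", z_range=(0.0, 40.0))
        kT = thermal_kT(298.0)
        sigma = np.sqrt(kT / spring_kj_nm2_to_kcal_A2(100.0))
        errs = []
        for n in (100, 1000, 10_000):
            (w,) = sample_umbrella_windows(truth, [18.0], 100.0, n, seed=13)
            errs.append(abs(w.samples.mean() - 18.0))
        # error at n=10^4 should be far below error bound at n=10^2
        assert errs[2] <= 5 * sigma / np.sqrt(10_000)


class TestTelegraph:
    def test_symmetric_rates_half_occupancy(self):
        cfg = TelegraphConfig(levels=(40, 0), rates=(0.01, 0.01), dt=1.0,
                              n_steps=200_000, seed=1)
        s = telegraph_series(cfg)
        occ = np.mean(s.n_water == 40)
        se = np.sqrt(0.25 / (200_000 * 0.01 * 2))   # ~n_switches events
        assert abs(occ - 0.5) <= 3 * max(se, 0.01)

    def test_asymmetric_rates_stationary_occupancy(self):
        k12, k21 = 0.02, 0.005
        cfg = TelegraphConfig(levels=(40, 0), rates=(k12, k21), dt=1.0,
                              n_steps=300_000, seed=2)
        s = telegraph_series(cfg)
        occ2 = np.mean(s.n_water == 0)
        assert occ2 == pytest.approx(k12 / (k12 + k21), abs=0.03)

    def test_identical_seeds_identical_series(self):
        cfg = TelegraphConfig(seed=5)
        np.testing.assert_array_equal(telegraph_series(cfg).n_water,
                                      telegraph_series(cfg).n_water)

    def test_discretization_validity_enforced(self):
        with pytest.raises(ValueError, match="dt"):
            TelegraphConfig(rates=(0.5, 0.5), dt=1.0)


class TestGeometryFixtures:
    def test_atom_count(self):
        s = make_cylinder_fixture(8.0, 30.0, ring_spacing=1.0, atoms_per_ring=36)
        assert s.n_atoms == 36 * 31

    def test_ring_radius_by_construction(self):
        s = make_cylinder_fixture(8.0, 10.0)
        r = np.hypot(s.coords[:, 0], s.coords[:, 1])
        np.testing.assert_allclose(r, 8.0, atol=1e-12)

    def test_funnel_midpoint_radius(self):
        s = make_funnel_fixture(10.0, 4.0, 30.0)
        mid = np.abs(s.coords[:, 2] - 15.0) < 1e-9
        r = np.hypot(s.coords[mid, 0], s.coords[mid, 1])
        np.testing.assert_allclose(r, 7.0, atol=1e-12)
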