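"""Structure I/O, selection grammar, COM and pore-axis alignment."""

import numpy as np
import pytest

from poregate.core_io import (AtomIndexSet, PDBFormatError, SelectionError,
                              Structure, Trajectory, align_to_pore_axis,
                              center_of_mass, load_structure,
                              read_xyz_trajectory, select, write_pdb,
                              write_xyz_trajectory)

from conftest import GLY_PDB, random_rigid_transform, random_structure


class TestPDB:
    def test_parses_three_atom_glycine(self, gly_pdb):
        s = load_structure(gly_pdb)
        assert s.n_atoms == 3
        assert list(s.names) == ["N", "CA", "C"]
        assert set(s.resnames) == {"GLY"}
        assert list(s.elements) == ["N", "C", "C"]
        np.testing.assert_allclose(s.coords[0], [11.104, 6.134, -6.504])

    def test_duplicate_serial_error_names_the_serial(self, tmp_path):
        bad = GLY_PDB.replace("ATOM      2", "ATOM      1")
        p = tmp_path / "dup.pdb"
        p.write_text(bad)
        with pytest.raises(PDBFormatError, match="serial 1"):
            load_structure(str(p))

    def test_unparsable_line_names_line_number(self, tmp_path):
        bad = GLY_PDB.replace("11.639", "xx.xxx")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(PDBFormatError, match="line 2"):
            load_structure(str(p))

    def test_round_trip_preserves_coords_and_annotations(self, tmp_path):
        s = random_structure(100, seed=3)
        path = tmp_path / "rt.pdb"
        write_pdb(s, str(path))
        back = load_structure(str(path))
        # PDB stores 3 decimals: 1e-3 A round-trip precision
        np.testing.assert_allclose(back.coords, s.coords, atol=1e-3 + 1e-12)
        assert list(back.elements) == list(s.elements)
        assert list(back.names) == list(s.names)
        assert list(back.resids) == list(s.resids)
        assert list(back.chains) == list(s.chains)

    def test_non_a_altloc_dropped(self, tmp_path):
        lines = GLY_PDB.splitlines()
        lines[1] = lines[1][:16] + "B" + lines[1][17:]
        p = tmp_path / "alt.pdb"
        p.write_text("\n".join(lines) + "\n")
        s = load_structure(str(p))
        assert s.n_atoms == 2


class TestXYZ:
    def test_round_trip(self, tmp_path):
        s = random_structure(20, seed=1)
        rng = np.random.default_rng(0)
        frames = s.coords[None] + rng.normal(size=(4, 20, 3))
        traj = Trajectory(s, frames, dt=50.0, time0=100.0)
        path = tmp_path / "t.xyz"
        write_xyz_trajectory(traj, str(path))
        back = read_xyz_trajectory(str(path), topology=s)
        np.testing.assert_allclose(back.frames, frames, atol=1e-6)
        assert back.dt == pytest.approx(50.0)
        assert back.time0 == pytest.approx(100.0)


class TestSelection:
    def test_backbone_of_residue_range(self):
        s = random_structure(60, seed=2)
        s.names[:] = np.resize(["N", "CA", "C", "O"], 60)
        sel = select(s, "resid 3-5 and backbone")
        expected = np.flatnonzero((s.resids >= 3) & (s.resids <= 5))
        np.testing.assert_array_equal(sorted(sel.indices), expected)

    def test_within_keeps_near_group_only(self):
        # one "lipid" 5 A from the reference residue, one 20 A away
        coords = np.array([[0, 0, 0], [5, 0, 0], [20, 0, 0]], dtype=float)
        s = Structure(np.arange(1, 4), ["C"] * 3, ["C1"] * 3,
                      ["REF", "POPC", "POPC"], [1, 2, 3], ["A"] * 3,
                      coords, np.full(3, 12.011))
        sel = select(s, "resname POPC and within 10.0 of (resid 1)")
        assert list(sel.indices) == [1]

    @pytest.mark.parametrize("cutoff", [3.0, 6.0, 9.0])
    def test_within_matches_brute_force(self, cutoff):
        s = random_structure(200, seed=7)
        ref = select(s, "resid 10-20")
        got = select(s, f"within {cutoff} of (resid 10-20)")
        d = np.linalg.norm(s.coords[:, None, :] - s.coords[None, ref.indices, :],
                           axis=2)
        expected = np.flatnonzero((d <= cutoff).any(axis=1))
        np.testing.assert_array_equal(sorted(got.indices), expected)

    @pytest.mark.parametrize("expr", ["resid 1-10", "resname UNK", "backbone",
                                      "name C1 N2", "chain A and resid 2-8",
                                      "not resid 5", "within 6 of (resid 1-3)"])
    def test_idempotent_and_subset_consistent(self, expr):
        s = random_structure(80, seed=11)
        a = set(select(s, expr).indices)
        assert set(select(s, expr).indices) == a  # deterministic
        both = set(select(s, f"({expr}) and resid 2-9").indices)
        assert both <= a  # (A and B) is a subset of A

    def test_parse_error_reports_column(self):
        s = random_structure(5)
        with pytest.raises(SelectionError, match="column 11"):
            select(s, "resid 1-3 bogus")

    def test_empty_selection_is_valid(self):
        s = random_structure(5)
        assert len(select(s, "resname XXX")) == 0


class TestCenterOfMass:
    def test_unit_masses_midpoint(self):
        s = Structure([1, 2], ["C", "C"], ["C", "C"], ["UNK"] * 2, [1, 2],
                      ["A"] * 2, [[0, 0, 0], [0, 0, 2]], [1.0, 1.0])
        com = center_of_mass(s, AtomIndexSet(np.array([0, 1])))
        np.testing.assert_allclose(com, [0, 0, 1])

    def test_mass_weighted_mean(self):
        s = Structure([1, 2], ["C", "C"], ["C", "C"], ["UNK"] * 2, [1, 2],
                      ["A"] * 2, [[0, 0, 0], [0, 0, 4]], [1.0, 3.0])
        com = center_of_mass(s, AtomIndexSet(np.array([0, 1])))
        np.testing.assert_allclose(com, [0, 0, 3])
        geo = center_of_mass(s, AtomIndexSet(np.array([0, 1])), mass_weighted=False)
        np.testing.assert_allclose(geo, [0, 0, 2])

    def test_matches_direct_formula_on_random_fixture(self):
        s = random_structure(50, seed=5)
        sel = AtomIndexSet(np.arange(50))
        com = center_of_mass(s, sel)
        direct = (s.coords * s.masses[:, None]).sum(0) / s.masses.sum()
        np.testing.assert_allclose(com, direct, atol=1e-12)

    def test_empty_selection_raises(self):
        s = random_structure(5)
        with pytest.raises(ValueError):
            center_of_mass(s, AtomIndexSet(np.array([], dtype=int)))


def _rod_structure():
    """A reference cluster at the origin plus a straight rod along +z.

    The rod's principal axis is exactly +z, so the canonical pose is an
    exact fixed point of the alignment.
    """
    rng = np.random.default_rng(0)
    ref = rng.normal(scale=1.0, size=(10, 3))
    ref -= ref.mean(axis=0)
    zs = np.linspace(2, 22, 30)
    rod = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
    coords = np.vstack([ref, rod])
    n = len(coords)
    s = Structure(np.arange(1, n + 1), ["C"] * n, ["C"] * n, ["UNK"] * n,
                  np.arange(1, n + 1), ["A"] * n, coords, np.ones(n))
    return s, AtomIndexSet(np.arange(10)), AtomIndexSet(np.arange(10, n))


class TestAlignment:
    def test_canonical_pose_is_fixed_point(self):
        s, ref, axis = _rod_structure()
        traj = Trajectory(s, s.coords[None], dt=1.0)
        aligned, frame = align_to_pore_axis(traj, ref, axis)
        np.testing.assert_allclose(aligned.frames[0], s.coords, atol=1e-9)
        assert frame.sign_convention == "cavity-positive"

    def test_recovers_pose_rotated_90_deg_about_x(self):
        s, ref, axis = _rod_structure()
        Rx = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        rotated = Trajectory(s, (s.coords @ Rx.T)[None], dt=1.0)
        aligned, _ = align_to_pore_axis(rotated, ref, axis)
        np.testing.assert_allclose(aligned.frames[0], s.coords, atol=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_ref_com_at_origin_and_distances_preserved(self, seed):
        s, ref, axis = _rod_structure()
        Q, t = random_rigid_transform(seed)
        moved = Trajectory(s, (s.coords @ Q.T + t)[None], dt=1.0)
        aligned, _ = align_to_pore_axis(moved, ref, axis)
        com = center_of_mass(aligned.topology, ref, coords=aligned.frames[0])
        np.testing.assert_allclose(com, [0, 0, 0], atol=1e-9)
        d_before = np.linalg.norm(s.coords[:, None] - s.coords[None, :], axis=2)
        a = aligned.frames[0]
        d_after = np.linalg.norm(a[:, None] - a[None, :], axis=2)
        np.testing.assert_allclose(d_after, d_before, atol=1e-6)
        # cavity (rod) on the positive side
        assert aligned.frames[0][10:, 2].mean() > 0

    def test_degenerate_axis_raises(self):
        s, ref, _ = _rod_structure()
        axis = AtomIndexSet(np.array([3]))  # a single point has no axis
        traj = Trajectory(s, s.coords[None], dt=1.0)
        with pytest.raises(ValueError, match="degenerate|zero-length"):
            align_to_pore_axis(traj, ref, axis)
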