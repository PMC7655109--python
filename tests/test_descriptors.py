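import numpy as np
import pytest

from channelsift.descriptors import (
    DescriptorSeries,
    ResidueRoleMap,
    gate_distance,
    ligand_pose_rmsd,
    loop_descriptors,
    pocket_water_count,
    residue_displacement_map,
)
from channelsift.fingerprints import LigandSpec
from channelsift.geometry import min_distance
from channelsift.structure import Structure, Trajectory
from conftest import make_atom, make_loop_chain, make_pentamer, random_rigid_transform
from oracles import dihedral_oracle


@pytest.fixture
def pentamer():
    return make_pentamer()


class TestLigandPoseRmsd:
    def test_reference_frame_zero(self, pentamer):
        structure, lig = pentamer
        traj = Trajectory(structure, [structure.coords], [0.0])
        out = ligand_pose_rmsd(traj, structure, lig, ResidueRoleMap())
        for chain in "ABCDE":
            assert out[chain].values[0] == pytest.approx(0.0, abs=1e-9)
        assert out["mean"].values[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_subunit_translated(self, pentamer):
        structure, lig = pentamer
        coords = structure.coords.copy()
        idx = [i for i, a in enumerate(structure.atoms)
               if a.residue_name == "LIG" and a.chain_id == "B"]
        coords[idx] += np.array([2.0, 0.0, 0.0])
        traj = Trajectory(structure, [coords], [0.0])
        out = ligand_pose_rmsd(traj, structure, lig, ResidueRoleMap())
        assert out["B"].values[0] == pytest.approx(2.0, abs=1e-9)
        for chain in "ACDE":
            assert out[chain].values[0] == pytest.approx(0.0, abs=1e-9)
        assert out["mean"].values[0] == pytest.approx(0.4, abs=1e-9)

    def test_oscillating_poses(self, pentamer):
        structure, lig = pentamer
        base = structure.coords
        moved = base.copy()
        lig_idx = [i for i, a in enumerate(structure.atoms) if a.residue_name == "LIG"]
        moved[lig_idx] += np.array([0.9, 1.2, 0.0])  # |d| = 1.5
        frames = [base, moved, base, moved]
        traj = Trajectory(structure, frames, [0.0, 1.0, 2.0, 3.0])
        out = ligand_pose_rmsd(traj, structure, lig, ResidueRoleMap())
        np.testing.assert_allclose(out["A"].values, [0.0, 1.5, 0.0, 1.5], atol=1e-6)

    def test_substructure_mode(self, pentamer):
        structure, lig = pentamer
        coords = structure.coords.copy()
        # move only N1 of chain A's ligand
        i = structure.atom_index("A", 900, "N1")
        coords[i] += np.array([0.0, 0.0, 1.3])
        traj = Trajectory(structure, [coords], [0.0])
        out = ligand_pose_rmsd(traj, structure, lig, ResidueRoleMap(),
                               substructure=["N1"])
        assert out["A"].values[0] == pytest.approx(1.3, abs=1e-9)
        with pytest.raises(ValueError, match="QX"):
            ligand_pose_rmsd(traj, structure, lig, ResidueRoleMap(),
                             substructure=["QX"])

    def test_rigid_invariance(self, pentamer):
        structure, lig = pentamer
        rng = np.random.default_rng(4)
        coords = structure.coords.copy()
        lig_idx = [i for i, a in enumerate(structure.atoms)
                   if a.residue_name == "LIG" and a.chain_id == "C"]
        coords[lig_idx] += np.array([1.0, -0.5, 0.3])
        rot, t = random_rigid_transform(rng)
        traj1 = Trajectory(structure, [coords], [0.0])
        traj2 = Trajectory(structure, [coords @ rot.T + t], [0.0])
        r1 = ligand_pose_rmsd(traj1, structure, lig, ResidueRoleMap())
        r2 = ligand_pose_rmsd(traj2, structure, lig, ResidueRoleMap())
        for chain in "ABCDE":
            assert r2[chain].values[0] == pytest.approx(r1[chain].values[0], abs=1e-6)


class TestLoopDescriptors:
    @pytest.fixture
    def loop_structure(self):
        return Structure(make_loop_chain())

    def test_reference_zero_rmsd(self, loop_structure):
        traj = Trajectory(loop_structure, [loop_structure.coords], [0.0])
        out = loop_descriptors(traj, loop_structure, ResidueRoleMap())
        rmsd_s, dih_s = out["A"]
        assert rmsd_s.values[0] == pytest.approx(0.0, abs=1e-9)
        ca = {r: loop_structure.coords[loop_structure.atom_index("A", r, "CA")]
              for r in (208, 199, 198, 203)}
        expect = dihedral_oracle(ca[208], ca[199], ca[198], ca[203])
        assert dih_s.values[0] == pytest.approx(expect, abs=1e-8)

    def test_rigid_rotation_leaves_descriptors(self, loop_structure):
        rng = np.random.default_rng(1)
        rot, t = random_rigid_transform(rng)
        moved = loop_structure.coords @ rot.T + t
        traj = Trajectory(loop_structure, [moved], [0.0])
        out = loop_descriptors(traj, loop_structure, ResidueRoleMap())
        rmsd_s, dih_s = out["A"]
        assert rmsd_s.values[0] == pytest.approx(0.0, abs=1e-6)
        base = loop_descriptors(
            Trajectory(loop_structure, [loop_structure.coords], [0.0]),
            loop_structure, ResidueRoleMap())["A"][1].values[0]
        assert dih_s.values[0] == pytest.approx(base, abs=1e-6)

    def test_swung_loop_changes_dihedral_monotonically(self, loop_structure):
        # rotate residues 200-206 about the x axis progressively
        base = loop_structure.coords
        idx = [i for i, a in enumerate(loop_structure.atoms)
               if 200 <= a.residue_number <= 206]
        vals = []
        frames = []
        for k, ang in enumerate(np.radians([0, 10, 20, 30])):
            rot = np.array([[1, 0, 0], [0, np.cos(ang), -np.sin(ang)],
                            [0, np.sin(ang), np.cos(ang)]])
            c = base.copy()
            c[idx] = c[idx] @ rot.T
            frames.append(c)
        traj = Trajectory(loop_structure, frames, [0.0, 1.0, 2.0, 3.0])
        out = loop_descriptors(traj, loop_structure, ResidueRoleMap())
        dih = out["A"][1].values
        diffs = np.diff(dih)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_missing_backbone_atom_raises(self):
        atoms = [a for a in make_loop_chain()
                 if not (a.residue_number == 202 and a.name == "C")]
        s = Structure(atoms)
        traj = Trajectory(s, [s.coords], [0.0])
        with pytest.raises(ValueError, match="202"):
            loop_descriptors(traj, s, ResidueRoleMap())


class TestGateDistance:
    def _gate_structure(self, d_closest=3.5):
        atoms = [
            make_atom(1, "NE", "N", "ARG", 65, "A", (0, 0, 0)),
            make_atom(2, "NH1", "N", "ARG", 65, "A", (1.0, 0.5, 0)),
            make_atom(3, "NH2", "N", "ARG", 65, "A", (-1.0, 0.5, 0)),
            make_atom(4, "OD1", "O", "ASP", 202, "A", (1.0, 0.5 + d_closest, 0)),
            make_atom(5, "OD2", "O", "ASP", 202, "A", (1.0, 0.5 + d_closest + 2.2, 0)),
        ]
        return Structure(atoms)

    def test_engaged(self):
        s = self._gate_structure(3.5)
        d, engaged = gate_distance(s, ResidueRoleMap())["A"]
        assert d == pytest.approx(3.5)
        assert engaged

    def test_not_engaged(self):
        s = self._gate_structure(4.5)
        d, engaged = gate_distance(s, ResidueRoleMap())["A"]
        assert d == pytest.approx(4.5)
        assert not engaged

    def test_boundary_inclusive(self):
        s = self._gate_structure(4.0)
        d, engaged = gate_distance(s, ResidueRoleMap())["A"]
        assert d == pytest.approx(4.0)
        assert engaged

    def test_delegates_to_min_distance(self):
        s = self._gate_structure(3.1)
        coords = s.coords
        d, _ = gate_distance(s, ResidueRoleMap())["A"]
        expect, _ = min_distance(coords[:3], coords[3:])
        assert d == pytest.approx(expect, abs=1e-12)

    def test_missing_atoms_raise(self):
        atoms = [make_atom(1, "CB", "C", "ARG", 65, "A", (0, 0, 0))]
        with pytest.raises(ValueError):
            gate_distance(Structure(atoms), ResidueRoleMap())


class TestPocketWaterCount:
    def _scene(self, water_dists):
        atoms = [make_atom(1, "C1", "C", "LIG", 900, "A", (0, 0, 0), hetero=True),
                 make_atom(2, "O1", "O", "LIG", 900, "A", (1.4, 0, 0), hetero=True)]
        serial = 3
        for k, d in enumerate(water_dists):
            atoms.append(make_atom(serial, "O", "O", "HOH", 500 + k, "W",
                                   (0, d, 0), hetero=True))
            serial += 1
        return Structure(atoms), LigandSpec(residue_name="LIG", nonpolar_atoms=["C1"],
                                            hbond_acceptors=["O1"])

    def test_planted_counts(self):
        s, lig = self._scene([2.5, 2.7, 2.9, 3.6, 4.0])
        assert pocket_water_count(s, lig)["A"] == 3

    def test_3p01_excluded(self):
        s, lig = self._scene([3.01])
        assert pocket_water_count(s, lig)["A"] == 0

    def test_water_counted_once(self):
        # water within 3 Å of both ligand atoms
        s, lig = self._scene([2.0])
        assert pocket_water_count(s, lig)["A"] == 1

    def test_monotone_in_cutoff(self):
        s, lig = self._scene([2.5, 3.2, 3.9, 5.0])
        counts = [pocket_water_count(s, lig, cutoff=c)["A"]
                  for c in (2.0, 3.0, 4.0, 6.0)]
        assert counts == sorted(counts)


class TestDisplacementMap:
    def _two_structures(self, move_resnum=None, delta=2.0):
        atoms_a = make_loop_chain()
        s_a = Structure(atoms_a)
        coords_b = s_a.coords.copy()
        if move_resnum is not None:
            i = s_a.atom_index("A", move_resnum, "CA")
            coords_b[i] += np.array([0.0, 0.0, delta])
        return s_a, s_a.with_coords(coords_b)

    def test_identical_all_zero(self):
        a, b = self._two_structures()
        df = residue_displacement_map(a, b, ResidueRoleMap())
        assert np.allclose(df.displacement, 0.0, atol=1e-9)

    def test_rigid_translation_all_zero(self):
        a, _ = self._two_structures()
        b = a.with_coords(a.coords + np.array([5.0, -3.0, 2.0]))
        df = residue_displacement_map(a, b, ResidueRoleMap())
        assert np.allclose(df.displacement, 0.0, atol=1e-8)

    def test_single_residue_displaced(self):
        a, b = self._two_structures(move_resnum=203, delta=2.0)
        # align on residues away from the perturbation so the fit is clean
        roles = ResidueRoleMap()
        from channelsift.structure import SelectionSpec
        roles.alignment_selection = SelectionSpec.build(
            atom_names=["CA"], residue_ranges=[(198, 201), (205, 208)])
        df = residue_displacement_map(a, b, roles)
        moved = df[df.residue_number == 203].displacement.iloc[0]
        assert moved == pytest.approx(2.0, abs=1e-9)
        others = df[df.residue_number != 203].displacement
        assert np.allclose(others, 0.0, atol=1e-9)

    def test_unmatched_residue_absent(self):
        a, b_full = self._two_structures()
        keep = [at for at in b_full.atoms if at.residue_number != 208]
        b = Structure(keep)
        df = residue_displacement_map(a, b, ResidueRoleMap())
        assert 208 not in set(df.residue_number)

    def test_smoothing_column(self):
        a, b = self._two_structures(move_resnum=203)
        df = residue_displacement_map(a, b, ResidueRoleMap(), smooth=True)
        assert "smoothed" in df.columns
        assert df.smoothed.notna().all()


class TestDescriptorSeries:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            DescriptorSeries("x", "A", [0.0, 1.0], [1.0], "Å")

    def test_dataframe(self):
        s = DescriptorSeries("gate", "A", [0.0], [3.2], "Å")
        df = s.to_dataframe()
        assert list(df.columns) == ["descriptor", "chain", "time_ps", "value", "units"]
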