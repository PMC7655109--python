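import numpy as np
import pytest

from channelsift.fingerprints import (
    BIT_NAMES,
    FingerprintConfig,
    InteractionBitset,
    LigandAnnotationError,
    LigandSpec,
    aromatic_contact,
    classify_residue_frame,
    fingerprint_trajectory,
    hydrogen_bond,
    water_bridges,
)
from channelsift.geometry import ring_geometry
from channelsift.structure import Structure, Trajectory, attached_hydrogens
from channelsift.synthetic import (
    OccupancySchedule,
    PlantedInteraction,
    PocketSceneSpec,
    build_pocket_scene,
    build_pocket_trajectory,
)
from conftest import ALL_BITS_DEFAULTS, make_atom
from oracles import BruteForceFingerprint

CFG = FingerprintConfig()


def scene_bits(scene, structure=None):
    """Fingerprint a static scene and return {label: bit string}."""
    s = structure or scene.structure
    traj = Trajectory(s, [s.coords], [0.0])
    m = fingerprint_trajectory(traj, scene.ligand, scene.config)
    return {r: "".join("1" if x else "0" for x in m.bits[i, 0, 0])
            for i, r in enumerate(m.residues)}


class TestBitset:
    def test_roundtrip_string(self):
        b = InteractionBitset.from_string("101000011")
        assert b.to_string() == "101000011"
        assert b["APOLAR"] and b["AROM_ETF"] and b["WATER1"] and b["WATER2"]

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            InteractionBitset.from_string("10100")

    def test_nine_bits(self):
        assert len(BIT_NAMES) == 9


class TestApolarCutoff:
    def _pair_scene(self, d):
        spec = PocketSceneSpec(planted=[PlantedInteraction("APOLAR", d)], seed=0)
        return build_pocket_scene(spec)

    def test_4p49_sets_bit(self):
        scene = self._pair_scene(4.49)
        assert scene_bits(scene)[("LEU", 10)] == "100000000"

    def test_4p51_clears_bit(self):
        scene = self._pair_scene(4.51)
        assert scene_bits(scene)[("LEU", 10)] == "000000000"

    def test_nitrogen_not_apolar(self):
        # ligand N (donor) 4.0 Å from a residue carbon only: no bits
        atoms = [
            make_atom(1, "N1", "N", "LIG", 900, "L", (0, 0, 0), hetero=True),
            make_atom(2, "C1", "C", "LIG", 900, "L", (0, 0, 50.0), hetero=True),
            make_atom(3, "CB", "C", "ALA", 10, "A", (4.0, 0, 0)),
        ]
        s = Structure(atoms)
        lig = LigandSpec(residue_name="LIG", hbond_donors=["N1"], nonpolar_atoms=["C1"])
        bs = classify_residue_frame(s, s.coords, lig, [0, 1], [2], [], CFG)
        assert bs.to_string() == "000000000"

    def test_asp_scene_sets_elec_neg(self):
        spec = PocketSceneSpec(planted=[PlantedInteraction("ELEC_PROT_NEG", 3.8)], seed=1)
        scene = build_pocket_scene(spec)
        assert scene_bits(scene)[("ASP", 10)] == "000000100"


class TestAromaticContact:
    def _ring(self, center, normal, phase=0.0):
        from channelsift.synthetic import _ring_coords
        pts = _ring_coords(np.asarray(center, dtype=float),
                           np.asarray(normal, dtype=float), phase=phase)
        return ring_geometry(pts, range(6)), pts

    def test_parallel_close_face_to_face(self):
        r1, p1 = self._ring((0, 0, 0), (0, 0, 1))
        r2, p2 = self._ring((0, 0, 3.6), (0, 0, 1))
        assert aromatic_contact(r1, r2, p1, p2, CFG) == "face_to_face"

    def test_perpendicular_edge_to_face(self):
        r1, p1 = self._ring((0, 0, 0), (0, 0, 1))
        r2, p2 = self._ring((0, 0, -3.3), (0, 1, 0), phase=np.pi / 2)
        d = min(np.linalg.norm(a - b) for a in p1 for b in p2)
        assert d <= 4.0
        assert aromatic_contact(r1, r2, p1, p2, CFG) == "edge_to_face"

    def test_beyond_cutoff_none(self):
        r1, p1 = self._ring((0, 0, 0), (0, 0, 1))
        r2, p2 = self._ring((0, 0, 4.2), (0, 0, 1))
        assert aromatic_contact(r1, r2, p1, p2, CFG) == "none"

    def test_tilt_at_45_boundary(self):
        r1, p1 = self._ring((0, 0, 0), (0, 0, 1))
        n = np.array([np.sin(np.radians(44.0)), 0, np.cos(np.radians(44.0))])
        r2, p2 = self._ring((0, 0, 3.4), n)
        assert aromatic_contact(r1, r2, p1, p2, CFG) == "face_to_face"
        n = np.array([np.sin(np.radians(46.0)), 0, np.cos(np.radians(46.0))])
        r3, p3 = self._ring((0, 0, 3.4), n)
        assert aromatic_contact(r1, r3, p1, p3, CFG) == "edge_to_face"


class TestHydrogenBond:
    def test_canonical(self):
        donor = np.array([0.0, 0, 0])
        acceptor = np.array([2.8, 0, 0])
        h = donor + 0.96 * np.array([np.cos(np.radians(10)), np.sin(np.radians(10)), 0])
        assert hydrogen_bond(donor, acceptor, [h], CFG)

    def test_beyond_heavy_cutoff(self):
        assert not hydrogen_bond((0, 0, 0), (3.6, 0, 0), None, CFG)

    def test_bad_angle_rejected(self):
        donor = np.array([0.0, 0, 0])
        acceptor = np.array([3.0, 0, 0])
        # H at ~95 degrees donor-H-acceptor
        from oracles import angle
        h = np.array([0.2, 0.94, 0.0])
        assert angle(tuple(donor), tuple(h), tuple(acceptor)) < 120
        assert not hydrogen_bond(donor, acceptor, [h], CFG)

    def test_distance_only_fallback(self):
        assert hydrogen_bond((0, 0, 0), (3.0, 0, 0), None, CFG)


class TestWaterBridges:
    def _chain_structure(self, n_waters, spacing=2.8):
        atoms = [make_atom(1, "O1", "O", "LIG", 900, "L", (0, 0, 0), hetero=True)]
        serial = 2
        for w in range(n_waters):
            x = spacing * (w + 1)
            atoms.append(make_atom(serial, "O", "O", "HOH", 500 + w, "W",
                                   (x, 0, 0), hetero=True)); serial += 1
        atoms.append(make_atom(serial, "ND2", "N", "ASN", 10, "A",
                               (spacing * (n_waters + 1), 0, 0)))
        return Structure(atoms)

    def test_order1_bridge(self):
        s = self._chain_structure(1)
        out = water_bridges(s.coords, [0], [2], [1], {}, CFG)
        assert out == [(1, (0, 1, 2))]

    def test_order2_bridge_no_order1(self):
        s = self._chain_structure(2)
        out = water_bridges(s.coords, [0], [3], [1, 2], {}, CFG)
        assert out == [(2, (0, 1, 2, 3))]

    def test_three_water_chain_not_reported(self):
        s = self._chain_structure(3)
        out = water_bridges(s.coords, [0], [4], [1, 2, 3], {}, CFG)
        assert out == []

    def test_water_order_invariance(self):
        rng = np.random.default_rng(0)
        lig = np.zeros((1, 3))
        res = np.array([[6.0, 0, 0]])
        waters = rng.uniform(-1, 7, size=(15, 3))
        coords = np.vstack([lig, res, waters])
        base = water_bridges(coords, [0], [1], list(range(2, 17)), {}, CFG)
        for perm_seed in range(5):
            perm = np.random.default_rng(perm_seed).permutation(15) + 2
            got = water_bridges(coords, [0], [1], [int(p) for p in perm], {}, CFG)
            assert got == base

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        atoms = [make_atom(1, "O1", "O", "LIG", 900, "L", (0, 0, 0), hetero=True),
                 make_atom(2, "ND2", "N", "ASN", 10, "A", (5.6, 0, 0))]
        serial = 3
        for w in range(20):
            p = rng.uniform(-2, 8, size=3)
            atoms.append(make_atom(serial, "O", "O", "HOH", 500 + w, "W",
                                   tuple(p), hetero=True))
            serial += 1
        s = Structure(atoms)
        lig_spec = LigandSpec(residue_name="LIG", hbond_acceptors=["O1"])
        waters = list(range(2, 22))
        got = set(water_bridges(s.coords, [0], [1], waters, {}, CFG))
        oracle = BruteForceFingerprint(s, lig_spec, CFG).bridges([0], [1])
        assert got == oracle


class TestSceneOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_planted_scene_matches_brute_force(self, seed):
        spec = PocketSceneSpec(
            planted=[PlantedInteraction(b, d) for b, d in ALL_BITS_DEFAULTS],
            seed=seed, n_decoy_atoms=20, n_waters=5)
        scene = build_pocket_scene(spec)
        got = scene_bits(scene)
        oracle = BruteForceFingerprint(scene.structure, scene.ligand, scene.config)
        expect = oracle.all_residues()
        for label, bits in got.items():
            assert bits == expect[label], label
        for label, truth in scene.ground_truth.items():
            assert got[label] == truth.to_string(), label

    def test_monotone_in_cutoffs(self, full_scene):
        base = scene_bits(full_scene)
        bigger = FingerprintConfig(apolar_cutoff=6.0, aromatic_cutoff=5.0,
                                   electrostatic_cutoff=5.5, hbond_heavy_cutoff=4.0)
        s = full_scene.structure
        traj = Trajectory(s, [s.coords], [0.0])
        m = fingerprint_trajectory(traj, full_scene.ligand, bigger)
        enlarged = {r: m.bits[i, 0, 0] for i, r in enumerate(m.residues)}
        for label, bits in base.items():
            for b in (0, 5, 6, 7, 8):  # purely distance-gated bits
                if bits[b] == "1":
                    assert enlarged[label][b], (label, BIT_NAMES[b])

    def test_missing_annotation_atom_raises(self, full_scene):
        s = full_scene.structure
        bad = LigandSpec(residue_name="LIG", nonpolar_atoms=["CX99"])
        with pytest.raises(LigandAnnotationError, match="CX99"):
            traj = Trajectory(s, [s.coords], [0.0])
            fingerprint_trajectory(traj, bad, CFG)


class TestTrajectoryFingerprint:
    def test_planted_frames_recovered(self):
        spec = PocketSceneSpec(planted=[PlantedInteraction("APOLAR", 4.2)], seed=2)
        scene = build_pocket_scene(spec)
        # engaged in frames 0-4, disengaged in 5-9
        states = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        label, direction, idxs = scene.planted_geometry["APOLAR"]
        base = scene.structure.coords
        frames = []
        for st in states:
            c = base.copy()
            if st == 0:
                c[idxs] += direction * 40.0
            frames.append(c)
        traj = Trajectory(scene.structure, frames, list(range(10)))
        m = fingerprint_trajectory(traj, scene.ligand, scene.config)
        r = m.residues.index(label)
        got = m.bits[r, 0, :, BIT_NAMES.index("APOLAR")].astype(int)
        np.testing.assert_array_equal(got, states)

    def test_markov_toggled_series_exact(self):
        spec = PocketSceneSpec(
            planted=[PlantedInteraction("APOLAR", 4.2),
                     PlantedInteraction("WATER1", 2.8)],
            seed=5, n_decoy_atoms=10, n_waters=4)
        scene = build_pocket_scene(spec)
        sched = OccupancySchedule(entries={"APOLAR": (0.4, 0.2), "WATER1": (0.5, 0.5)},
                                  n_frames=60, seed=9)
        traj, series = build_pocket_trajectory(scene, sched)
        m = fingerprint_trajectory(traj, scene.ligand, scene.config)
        for (label, bit), chain in series.items():
            r = m.residues.index(label)
            got = m.bits[r, 0, :, BIT_NAMES.index(bit)].astype(int)
            np.testing.assert_array_equal(got, chain)

    def test_subunit_permutation_symmetry(self):
        # five identical rotated pockets: per-residue probabilities identical
        from conftest import make_pentamer
        structure, lig = make_pentamer()
        rng = np.random.default_rng(0)
        frames = [structure.coords + rng.normal(scale=1e-6, size=(len(structure), 3))
                  for _ in range(3)]
        traj = Trajectory(structure, frames, [0.0, 1.0, 2.0])
        m = fingerprint_trajectory(traj, lig, CFG)
        assert len(m.subunits) == 5
        probs = m.bits.mean(axis=2)  # residue x subunit x bit
        for s in range(1, 5):
            np.testing.assert_allclose(probs[:, s], probs[:, 0])
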