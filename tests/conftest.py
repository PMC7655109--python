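"""Shared fixtures: planted scenes, a toy pentamer, and rigid transforms."""

from __future__ import annotations

import numpy as np
import pytest

from channelsift.fingerprints import FingerprintConfig, LigandSpec
from channelsift.structure import AtomRecord, Structure, Trajectory
from channelsift.synthetic import (
    PlantedInteraction,
    PocketSceneSpec,
    build_pocket_scene,
)

ALL_BITS_DEFAULTS = (
    ("APOLAR", 4.2), ("AROM_FTF", 3.6), ("AROM_ETF", 3.5),
    ("HB_PROT_DONOR", 2.8), ("HB_PROT_ACCEPTOR", 2.8),
    ("ELEC_PROT_POS", 3.8), ("ELEC_PROT_NEG", 3.8),
    ("WATER1", 2.8), ("WATER2", 2.8),
)


def make_atom(serial, name, element, resname, resnum, chain, xyz,
              hetero=False, icode="", altloc="", occupancy=1.0, b=0.0):
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, residue_number=resnum,
                      insertion_code=icode, chain_id=chain, altloc=altloc,
                      coords=tuple(float(v) for v in xyz),
                      occupancy=occupancy, b_factor=b, is_hetero=hetero)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-20, 20, size=3)
    return rot, t


@pytest.fixture
def full_scene():
    """A scene planting all nine bits at canonical engaged distances."""
    spec = PocketSceneSpec(
        planted=[PlantedInteraction(b, d) for b, d in ALL_BITS_DEFAULTS],
        seed=11, n_decoy_atoms=25, n_waters=6)
    return build_pocket_scene(spec)


@pytest.fixture
def scene_trajectory(full_scene):
    s = full_scene.structure
    return Trajectory(s, [s.coords], [0.0])


def make_pentamer(n_ca_per_chain: int = 6, ligand: bool = True,
                  seed: int = 0) -> tuple[Structure, LigandSpec]:
    """Five rotated copies of an asymmetric chain around the z axis.

    Each chain carries Cα atoms (for alignment) and, optionally, a rigid
    three-atom ligand copy; chains are exact C5 rotations of each other.
    """
    rng = np.random.default_rng(seed)
    base_ca = rng.uniform(-4, 4, size=(n_ca_per_chain, 3)) + np.array([14.0, 0, 0])
    base_lig = np.array([[10.0, 2.0, 1.0], [11.2, 2.5, 1.4], [10.4, 3.1, 0.2]])
    atoms = []
    serial = 1
    for c, chain in enumerate("ABCDE"):
        ang = 2 * np.pi * c / 5
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        for r in range(n_ca_per_chain):
            atoms.append(make_atom(serial, "CA", "C", "ALA", 100 + r, chain,
                                   base_ca[r] @ rot.T))
            serial += 1
        if ligand:
            for k, name in enumerate(("C1", "N1", "O1")):
                element = name[0]
                atoms.append(make_atom(serial, name, element, "LIG", 900, chain,
                                       base_lig[k] @ rot.T, hetero=True))
                serial += 1
    spec = LigandSpec(residue_name="LIG", hbond_donors=["N1"],
                      hbond_acceptors=["O1"], nonpolar_atoms=["C1"])
    return Structure(atoms, identifier="pentamer"), spec


def make_loop_chain(chain: str = "A", offset=np.zeros(3)) -> list:
    """Backbone for residues 198..208 plus gate residues 65 and 202 sidechains."""
    rng = np.random.default_rng(42)
    atoms = []
    serial = 1
    for resnum in range(198, 209):
        base = np.array([resnum - 198.0, 0.0, 0.0]) * 3.8 + offset
        jitter = rng.normal(scale=0.3, size=(3, 3))
        atoms.append(make_atom(serial, "N", "N", "ALA", resnum, chain,
                               base + [0.0, 0.5, 0.2] + jitter[0])); serial += 1
        atoms.append(make_atom(serial, "CA", "C", "ALA", resnum, chain,
                               base + jitter[1])); serial += 1
        atoms.append(make_atom(serial, "C", "C", "ALA", resnum, chain,
                               base + [1.2, -0.4, 0.1] + jitter[2])); serial += 1
    return atoms
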