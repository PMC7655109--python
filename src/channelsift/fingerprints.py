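"""Per-residue 9-bit protein-ligand interaction fingerprints.

Bit order (fixed, also the serialization order):

    0 APOLAR            carbon-carbon contact within the apolar cutoff
    1 AROM_FTF          face-to-face aromatic ring stacking
    2 AROM_ETF          edge-to-face aromatic ring stacking
    3 HB_PROT_DONOR     hydrogen bond, protein atom is the donor
    4 HB_PROT_ACCEPTOR  hydrogen bond, protein atom is the acceptor
    5 ELEC_PROT_POS     electrostatic, protein group positively charged
    6 ELEC_PROT_NEG     electrostatic, protein group negatively charged
    7 WATER1            one-water-mediated hydrogen-bond bridge
    8 WATER2            two-water-mediated hydrogen-bond bridge

All distance cutoffs are inclusive (<=).  Hydrogens never enter distance
tests; the hydrogen-bond angle criterion applies only when hydrogens exist in
the topology, otherwise a distance-only fallback is used (cryo-EM models
carry no hydrogens, simulation frames do).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from channelsift.geometry import RingGeometry, angle_deg, min_distance, normal_angle, ring_geometry
from channelsift.structure import Structure, Trajectory, attached_hydrogens

BIT_NAMES = (
    "APOLAR", "AROM_FTF", "AROM_ETF", "HB_PROT_DONOR", "HB_PROT_ACCEPTOR",
    "ELEC_PROT_POS", "ELEC_PROT_NEG", "WATER1", "WATER2",
)
N_BITS = len(BIT_NAMES)

POLAR_ELEMENTS = frozenset({"N", "O", "S"})

#: Protein charged side-chain groups at force-field pH 7 protonation.
#: His counts as positive only under its explicitly protonated residue names.
PROTEIN_POSITIVE_GROUPS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIP": ("ND1", "NE2"),
    "HSP": ("ND1", "NE2"),
}
PROTEIN_NEGATIVE_GROUPS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: Aromatic side-chain rings as ordered atom-name cycles.  Trp contributes
#: two independently evaluated rings (pyrrole and benzene of the indole).
PROTEIN_RINGS = {
    "PHE": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TYR": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
    "HIS": (("CG", "ND1", "CE1", "NE2", "CD2"),),
    "HID": (("CG", "ND1", "CE1", "NE2", "CD2"),),
    "HIE": (("CG", "ND1", "CE1", "NE2", "CD2"),),
    "HIP": (("CG", "ND1", "CE1", "NE2", "CD2"),),
    "HSD": (("CG", "ND1", "CE1", "NE2", "CD2"),),
    "HSE": (("CG", "ND1", "CE1", "NE2", "CD2"),),
    "HSP": (("CG", "ND1", "CE1", "NE2", "CD2"),),
}


class LigandAnnotationError(ValueError):
    """A ligand annotation references an atom missing from the topology."""


@dataclass(frozen=True)
class FingerprintConfig:
    """Geometric criteria for the nine interaction types."""

    apolar_cutoff: float = 4.5
    aromatic_cutoff: float = 4.0
    electrostatic_cutoff: float = 4.0
    hbond_heavy_cutoff: float = 3.5
    hbond_angle_min: float = 120.0
    ftf_normal_angle_max: float = 45.0
    water_bridge_max_order: int = 2

    def __post_init__(self) -> None:
        for name in ("apolar_cutoff", "aromatic_cutoff", "electrostatic_cutoff",
                     "hbond_heavy_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.ftf_normal_angle_max < 90):
            raise ValueError("ftf_normal_angle_max must be in (0, 90)")

    @property
    def max_cutoff(self) -> float:
        return max(self.apolar_cutoff, self.aromatic_cutoff,
                   self.electrostatic_cutoff, self.hbond_heavy_cutoff)


@dataclass
class LigandSpec:
    """Chemistry annotations for one ligand residue.

    Atom names refer to atoms inside the selected ligand residue; the same
    annotation is reused for every copy of the ligand in the structure.
    """

    residue_name: str
    chain_id: Optional[str] = None
    residue_number: Optional[int] = None
    ring_groups: list[list[str]] = field(default_factory=list)
    hbond_donors: list[str] = field(default_factory=list)
    hbond_acceptors: list[str] = field(default_factory=list)
    positive_groups: list[list[str]] = field(default_factory=list)
    negative_groups: list[list[str]] = field(default_factory=list)
    nonpolar_atoms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ring in self.ring_groups:
            if len(ring) < 5:
                raise ValueError("ring groups need at least 5 members")

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "LigandSpec":
        data = yaml.safe_load(Path(source).read_text())
        return cls(**data)

    def to_yaml(self, target: Union[str, Path]) -> None:
        data = {
            "residue_name": self.residue_name,
            "chain_id": self.chain_id,
            "residue_number": self.residue_number,
            "ring_groups": [list(r) for r in self.ring_groups],
            "hbond_donors": list(self.hbond_donors),
            "hbond_acceptors": list(self.hbond_acceptors),
            "positive_groups": [list(g) for g in self.positive_groups],
            "negative_groups": [list(g) for g in self.negative_groups],
            "nonpolar_atoms": list(self.nonpolar_atoms),
        }
        Path(target).write_text(yaml.safe_dump(data, sort_keys=False))

    def all_named_atoms(self) -> set[str]:
        names: set[str] = set(self.hbond_donors) | set(self.hbond_acceptors)
        names |= set(self.nonpolar_atoms)
        for grp in list(self.ring_groups) + list(self.positive_groups) + list(self.negative_groups):
            names |= set(grp)
        return names

    def validate(self, structure: Structure) -> None:
        """Check every named atom exists in (every copy of) the ligand residue."""
        copies = find_ligand_copies(structure, self)
        if not copies:
            raise LigandAnnotationError(
                f"no residue {self.residue_name!r} matching the ligand selector")
        for chain, idxs in copies.items():
            present = {structure.atoms[i].name for i in idxs}
            missing = self.all_named_atoms() - present
            if missing:
                raise LigandAnnotationError(
                    f"ligand copy in chain {chain!r} is missing annotated atoms "
                    f"{sorted(missing)}")
            for lst, kind in ((self.hbond_donors, "donor"), (self.hbond_acceptors, "acceptor")):
                for name in lst:
                    idx = next(i for i in idxs if structure.atoms[i].name == name)
                    if structure.atoms[idx].element not in POLAR_ELEMENTS:
                        raise LigandAnnotationError(
                            f"{kind} atom {name} is not N/O/S")


class InteractionBitset:
    """Fixed-order 9-bit interaction record."""

    __slots__ = ("bits",)

    def __init__(self, bits: Optional[Sequence[bool]] = None) -> None:
        if bits is None:
            self.bits = np.zeros(N_BITS, dtype=bool)
        else:
            arr = np.asarray(bits, dtype=bool)
            if arr.shape != (N_BITS,):
                raise ValueError(f"need exactly {N_BITS} bits")
            self.bits = arr

    def __getitem__(self, key: Union[int, str]) -> bool:
        if isinstance(key, str):
            key = BIT_NAMES.index(key)
        return bool(self.bits[key])

    def set(self, key: Union[int, str], value: bool = True) -> None:
        if isinstance(key, str):
            key = BIT_NAMES.index(key)
        self.bits[key] = value

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "InteractionBitset":
        if len(s) != N_BITS or set(s) - {"0", "1"}:
            raise ValueError("bit string must be nine 0/1 characters")
        return cls([c == "1" for c in s])

    def __eq__(self, other) -> bool:
        return isinstance(other, InteractionBitset) and bool(np.array_equal(self.bits, other.bits))

    def __repr__(self) -> str:
        return f"InteractionBitset({self.to_string()})"


@dataclass
class FingerprintMatrix:
    """residue x subunit x frame bit array with axis labels."""

    residues: list[tuple[str, int]]  # (residue_name, residue_number)
    subunits: list[str]  # ligand-copy chain ids
    times: list[float]
    bits: np.ndarray  # shape (n_res, n_sub, n_frames, 9), bool

    def __post_init__(self) -> None:
        expected = (len(self.residues), len(self.subunits), len(self.times), N_BITS)
        if self.bits.shape != expected:
            raise ValueError(f"bits shape {self.bits.shape} != {expected}")

    def residue_label(self, residue: tuple[str, int]) -> str:
        return f"{residue[0]}{residue[1]}"

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r, res in enumerate(self.residues):
            for s, chain in enumerate(self.subunits):
                for f, t in enumerate(self.times):
                    row = {"residue": self.residue_label(res), "chain": chain,
                           "time_ps": t}
                    for b, name in enumerate(BIT_NAMES):
                        row[name] = int(self.bits[r, s, f, b])
                    rows.append(row)
        return pd.DataFrame(rows)

    def bit_strings(self) -> dict[tuple[str, str, float], str]:
        out = {}
        for r, res in enumerate(self.residues):
            for s, chain in enumerate(self.subunits):
                for f, t in enumerate(self.times):
                    out[(self.residue_label(res), chain, t)] = "".join(
                        "1" if x else "0" for x in self.bits[r, s, f])
        return out


# ---------------------------------------------------------------------------
# Elementary classifiers
# ---------------------------------------------------------------------------

def hydrogen_bond(donor_heavy: np.ndarray, acceptor_heavy: np.ndarray,
                  attached_h: Optional[Sequence[np.ndarray]] = None,
                  config: FingerprintConfig = FingerprintConfig()) -> bool:
    """Geometric hydrogen bond between a donor heavy atom and an acceptor.

    True iff the heavy-atom distance is within the cutoff and, when hydrogen
    positions are available, the best donor-H-acceptor angle reaches the
    angle minimum.  Without hydrogens the distance criterion alone decides.
    """
    donor_heavy = np.asarray(donor_heavy, dtype=float)
    acceptor_heavy = np.asarray(acceptor_heavy, dtype=float)
    d = float(np.linalg.norm(donor_heavy - acceptor_heavy))
    if d > config.hbond_heavy_cutoff:
        return False
    if not attached_h:
        return True
    best = max(angle_deg(donor_heavy, h, acceptor_heavy) for h in attached_h)
    return best >= config.hbond_angle_min


def aromatic_contact(ring1: RingGeometry, ring2: RingGeometry,
                     coords1: np.ndarray, coords2: np.ndarray,
                     config: FingerprintConfig = FingerprintConfig()) -> str:
    """Classify a ring-ring contact as 'none', 'face_to_face' or 'edge_to_face'.

    Contact exists iff the minimum inter-ring heavy-atom distance is within
    the aromatic cutoff; the face/edge split is by the inter-normal angle
    folded to [0, 90] degrees.
    """
    pts1 = np.asarray(coords1, dtype=float).reshape(-1, 3)[list(ring1.member_indices)]
    pts2 = np.asarray(coords2, dtype=float).reshape(-1, 3)[list(ring2.member_indices)]
    dmin, _ = min_distance(pts1, pts2)
    if dmin > config.aromatic_cutoff:
        return "none"
    ang = normal_angle(ring1.unit_normal, ring2.unit_normal)
    return "face_to_face" if ang <= config.ftf_normal_angle_max else "edge_to_face"


def _polar_link(coords: np.ndarray, i: int, j: int,
                hmap: dict[int, list[int]],
                config: FingerprintConfig) -> bool:
    """Hydrogen-bond link with either partner allowed to donate.

    Used for water bridges, where a water oxygen acts as donor and acceptor
    simultaneously.  With no hydrogens on either side the distance criterion
    alone decides.
    """
    d = float(np.linalg.norm(coords[i] - coords[j]))
    if d > config.hbond_heavy_cutoff:
        return False
    hs = [(i, h) for h in hmap.get(i, ())] + [(j, h) for h in hmap.get(j, ())]
    if not hs:
        return True
    for donor, h in hs:
        other = j if donor == i else i
        if angle_deg(coords[donor], coords[h], coords[other]) >= config.hbond_angle_min:
            return True
    return False


def water_bridges(coords: np.ndarray,
                  ligand_polar: Sequence[int],
                  residue_polar: Sequence[int],
                  water_oxygens: Sequence[int],
                  hmap: dict[int, list[int]],
                  config: FingerprintConfig = FingerprintConfig()) -> list[tuple[int, tuple[int, ...]]]:
    """Enumerate one- and two-water hydrogen-bond bridges.

    Returns (order, atom index path) tuples; paths never revisit a water and
    chains longer than ``water_bridge_max_order`` are not reported.  Results
    are sorted, hence independent of the input water ordering.
    """
    coords = np.asarray(coords, dtype=float)
    ligand_polar = list(ligand_polar)
    residue_polar = list(residue_polar)
    waters = list(water_oxygens)
    out: list[tuple[int, tuple[int, ...]]] = []
    if not ligand_polar or not residue_polar or not waters:
        return out

    # prefilter: a water can only start a path if near some ligand polar atom
    lig_xyz = coords[ligand_polar]
    wat_xyz = coords[waters]
    near_lig = cdist(wat_xyz, lig_xyz).min(axis=1) <= config.hbond_heavy_cutoff
    first_shell = [w for w, ok in zip(waters, near_lig) if ok]

    seen: set[tuple[int, ...]] = set()
    for lp in ligand_polar:
        for w1 in first_shell:
            if not _polar_link(coords, lp, w1, hmap, config):
                continue
            for rp in residue_polar:
                if _polar_link(coords, w1, rp, hmap, config):
                    path = (lp, w1, rp)
                    if path not in seen:
                        seen.add(path)
                        out.append((1, path))
            if config.water_bridge_max_order < 2:
                continue
            for w2 in waters:
                if w2 == w1 or not _polar_link(coords, w1, w2, hmap, config):
                    continue
                for rp in residue_polar:
                    if _polar_link(coords, w2, rp, hmap, config):
                        path = (lp, w1, w2, rp)
                        if path not in seen:
                            seen.add(path)
                            out.append((2, path))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Residue-frame classification
# ---------------------------------------------------------------------------

def find_ligand_copies(structure: Structure, ligand: LigandSpec) -> dict[str, list[int]]:
    """Map chain id -> atom indices of the ligand copy in that chain."""
    out: dict[str, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.residue_name != ligand.residue_name:
            continue
        if ligand.chain_id is not None and a.chain_id != ligand.chain_id:
            continue
        if ligand.residue_number is not None and a.residue_number != ligand.residue_number:
            continue
        out.setdefault(a.chain_id, []).append(i)
    return out


def _ligand_atom_indices(structure: Structure, copy_idx: list[int],
                         names: Sequence[str]) -> list[int]:
    lut = {structure.atoms[i].name: i for i in copy_idx}
    missing = [n for n in names if n not in lut]
    if missing:
        raise LigandAnnotationError(f"ligand annotation references missing atoms {missing}")
    return [lut[n] for n in names]


def classify_residue_frame(structure: Structure,
                           coords: np.ndarray,
                           ligand: LigandSpec,
                           ligand_copy: list[int],
                           residue_atoms: list[int],
                           water_oxygens: Sequence[int],
                           config: FingerprintConfig = FingerprintConfig(),
                           hmap: Optional[dict[int, list[int]]] = None) -> InteractionBitset:
    """Classify all nine interaction types for one residue in one frame.

    Both side-chain and backbone heavy atoms of the residue are considered.
    ``hmap`` maps heavy atoms to attached hydrogens (from the topology); pass
    the result of :func:`channelsift.structure.attached_hydrogens` to enable
    the angle criterion.
    """
    coords = np.asarray(coords, dtype=float)
    if hmap is None:
        hmap = {}
    bitset = InteractionBitset()
    atoms = structure.atoms
    res_heavy = [i for i in residue_atoms if atoms[i].element != "H"]
    if not res_heavy:
        return bitset
    res_name = atoms[res_heavy[0]].residue_name

    # APOLAR: ligand nonpolar carbons vs residue carbons
    if ligand.nonpolar_atoms:
        lig_np = _ligand_atom_indices(structure, ligand_copy, ligand.nonpolar_atoms)
        res_c = [i for i in res_heavy if atoms[i].element == "C"]
        if lig_np and res_c:
            d, _ = min_distance(coords[lig_np], coords[res_c])
            if d <= config.apolar_cutoff:
                bitset.set("APOLAR")

    # Aromatic: ligand rings vs residue rings
    res_rings = PROTEIN_RINGS.get(res_name, ())
    if ligand.ring_groups and res_rings:
        res_name_lut = {atoms[i].name: i for i in res_heavy}
        for lig_ring_names in ligand.ring_groups:
            lig_ring_idx = _ligand_atom_indices(structure, ligand_copy, lig_ring_names)
            lig_ring = ring_geometry(coords, lig_ring_idx)
            for ring_names in res_rings:
                if not all(n in res_name_lut for n in ring_names):
                    continue
                res_ring = ring_geometry(coords, [res_name_lut[n] for n in ring_names])
                kind = aromatic_contact(lig_ring, res_ring, coords, coords, config)
                if kind == "face_to_face":
                    bitset.set("AROM_FTF")
                elif kind == "edge_to_face":
                    bitset.set("AROM_ETF")

    # Hydrogen bonds
    res_polar = [i for i in res_heavy if atoms[i].element in POLAR_ELEMENTS]
    has_any_h = bool(hmap)
    if ligand.hbond_acceptors and res_polar:
        lig_acc = _ligand_atom_indices(structure, ligand_copy, ligand.hbond_acceptors)
        for rp in res_polar:
            hs = [coords[h] for h in hmap.get(rp, ())]
            if has_any_h and not hs:
                continue  # topology has hydrogens but this atom bears none: not a donor
            for la in lig_acc:
                if hydrogen_bond(coords[rp], coords[la], hs, config):
                    bitset.set("HB_PROT_DONOR")
                    break
            if bitset["HB_PROT_DONOR"]:
                break
    if ligand.hbond_donors and res_polar:
        lig_don = _ligand_atom_indices(structure, ligand_copy, ligand.hbond_donors)
        for ld in lig_don:
            hs = [coords[h] for h in hmap.get(ld, ())]
            if has_any_h and not hs:
                continue
            for rp in res_polar:
                if hydrogen_bond(coords[ld], coords[rp], hs, config):
                    bitset.set("HB_PROT_ACCEPTOR")
                    break
            if bitset["HB_PROT_ACCEPTOR"]:
                break

    # Electrostatics
    res_name_lut = {atoms[i].name: i for i in res_heavy}
    pos_names = PROTEIN_POSITIVE_GROUPS.get(res_name, ())
    if pos_names and ligand.negative_groups:
        prot_pos = [res_name_lut[n] for n in pos_names if n in res_name_lut]
        for grp in ligand.negative_groups:
            lig_neg = _ligand_atom_indices(structure, ligand_copy, grp)
            if prot_pos and lig_neg:
                d, _ = min_distance(coords[prot_pos], coords[lig_neg])
                if d <= config.electrostatic_cutoff:
                    bitset.set("ELEC_PROT_POS")
    neg_names = PROTEIN_NEGATIVE_GROUPS.get(res_name, ())
    if neg_names and ligand.positive_groups:
        prot_neg = [res_name_lut[n] for n in neg_names if n in res_name_lut]
        for grp in ligand.positive_groups:
            lig_pos = _ligand_atom_indices(structure, ligand_copy, grp)
            if prot_neg and lig_pos:
                d, _ = min_distance(coords[prot_neg], coords[lig_pos])
                if d <= config.electrostatic_cutoff:
                    bitset.set("ELEC_PROT_NEG")

    # Water bridges between ligand polar atoms and residue polar atoms
    if water_oxygens and res_polar:
        lig_polar_names = list(dict.fromkeys(list(ligand.hbond_donors) + list(ligand.hbond_acceptors)))
        if lig_polar_names:
            lig_polar = _ligand_atom_indices(structure, ligand_copy, lig_polar_names)
            bridges = water_bridges(coords, lig_polar, res_polar, water_oxygens,
                                    hmap, config)
            for order, _path in bridges:
                bitset.set("WATER1" if order == 1 else "WATER2")
    return bitset


def fingerprint_trajectory(traj: Trajectory,
                           ligand: LigandSpec,
                           config: FingerprintConfig = FingerprintConfig(),
                           stride_ps: Optional[float] = None,
                           residues: Optional[Sequence[tuple[str, int]]] = None,
                           ) -> FingerprintMatrix:
    """Fingerprint every (residue, subunit, sampled frame) triple.

    Subunits are the chains holding a ligand copy.  The residue list defaults
    to all protein residues with any atom within ``max_cutoff + 2 Å`` of any
    ligand atom in any sampled frame; residues are labeled (name, number) so
    equivalent positions in a symmetric oligomer pool across subunits.
    """
    topo = traj.topology
    copies = find_ligand_copies(topo, ligand)
    if not copies:
        raise LigandAnnotationError(
            f"no ligand copies of {ligand.residue_name!r} found in any chain")
    ligand.validate(topo)
    subunits = sorted(copies)
    frame_idx = traj.sample_indices(stride_ps)
    hmap = attached_hydrogens(topo)
    water_ox = [i for i, a in enumerate(topo.atoms)
                if a.is_water and a.element == "O"]
    atoms = topo.atoms

    protein_res: dict[tuple[str, int, str], list[int]] = {}
    for key, idxs in topo.residues().items():
        if atoms[idxs[0]].residue_name in _protein_residue_names():
            protein_res[key] = idxs

    # pocket assignment: residues near each ligand copy in any sampled frame;
    # water-bridged residues sit up to max_order hydrogen-bond links away
    reach = config.max_cutoff + 2.0 + config.water_bridge_max_order * config.hbond_heavy_cutoff
    pocket: dict[str, dict[tuple[str, int], list[int]]] = {s: {} for s in subunits}
    for key, idxs in protein_res.items():
        heavy = [i for i in idxs if atoms[i].element != "H"]
        if not heavy:
            continue
        label = (atoms[heavy[0]].residue_name, key[1])
        for s in subunits:
            lig_idx = copies[s]
            near = False
            for k in frame_idx:
                coords = traj.frames[k]
                d, _ = min_distance(coords[heavy], coords[lig_idx])
                if d <= reach:
                    near = True
                    break
            if near:
                if label in pocket[s]:
                    pocket[s][label] = pocket[s][label] + idxs
                else:
                    pocket[s][label] = list(idxs)

    if residues is None:
        labels = sorted({lbl for s in subunits for lbl in pocket[s]},
                        key=lambda x: (x[1], x[0]))
    else:
        labels = [tuple(r) for r in residues]

    bits = np.zeros((len(labels), len(subunits), len(frame_idx), N_BITS), dtype=bool)
    times = [traj.times[k] for k in frame_idx]
    for s, chain in enumerate(subunits):
        lig_idx = copies[chain]
        for r, label in enumerate(labels):
            res_atoms = pocket[chain].get(label)
            if res_atoms is None:
                continue
            for f, k in enumerate(frame_idx):
                bs = classify_residue_frame(
                    topo, traj.frames[k], ligand, lig_idx, res_atoms,
                    water_ox, config, hmap)
                bits[r, s, f] = bs.bits
    return FingerprintMatrix(residues=labels, subunits=subunits, times=times, bits=bits)


def _protein_residue_names() -> frozenset[str]:
    from channelsift.structure import AMINO_ACIDS
    return AMINO_ACIDS
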