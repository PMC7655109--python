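"""Channel-specific per-frame conformational descriptors.

Covers ligand-pose RMSD (whole ligand or a named substructure), the flexible
binding-site loop's backbone RMSD and orientation dihedral, the salt-bridge
gate distance with an engagement threshold, binding-site water counts, and
per-residue Cα displacement maps between two structures.

All RMSD-style descriptors first align each frame onto the reference using
the role map's alignment selection (Cα atoms of the stable domain core) and
then measure without re-fitting.  Distance cutoffs are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline

from channelsift.fingerprints import LigandSpec, find_ligand_copies
from channelsift.geometry import dihedral, kabsch_superpose, min_distance, raw_rmsd
from channelsift.structure import SelectionSpec, Structure, Trajectory, select


@dataclass
class ResidueRoleMap:
    """Residue roles used by the descriptors.

    Defaults target a typical pentameric-channel numbering: the loop backbone
    RMSD range spans residues 200-205, the orientation dihedral runs over the
    Cα atoms of residues 208, 199, 198, 203, and the gate pair is Arg65's
    guanidinium nitrogens against Asp202's carboxylate oxygens.
    """

    loop_rmsd_range: tuple[int, int] = (200, 205)
    loop_dihedral_residues: tuple[int, int, int, int] = (208, 199, 198, 203)
    gate_pair: tuple[tuple[int, tuple[str, ...]], tuple[int, tuple[str, ...]]] = (
        (65, ("NE", "NH1", "NH2")), (202, ("OD1", "OD2")))
    alignment_selection: SelectionSpec = field(
        default_factory=lambda: SelectionSpec.build(element_classes=["calpha"]))
    pore_marker_residues: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "ResidueRoleMap":
        data = yaml.safe_load(Path(source).read_text())
        kwargs = {}
        if "loop_rmsd_range" in data:
            kwargs["loop_rmsd_range"] = tuple(data["loop_rmsd_range"])
        if "loop_dihedral_residues" in data:
            kwargs["loop_dihedral_residues"] = tuple(data["loop_dihedral_residues"])
        if "gate_pair" in data:
            gp = data["gate_pair"]
            kwargs["gate_pair"] = ((gp[0][0], tuple(gp[0][1])), (gp[1][0], tuple(gp[1][1])))
        if "alignment_selection" in data:
            kwargs["alignment_selection"] = SelectionSpec.build(**data["alignment_selection"])
        if "pore_marker_residues" in data:
            kwargs["pore_marker_residues"] = dict(data["pore_marker_residues"])
        return cls(**kwargs)


@dataclass
class DescriptorSeries:
    """A labeled per-frame scalar series with units."""

    name: str
    subunit: str
    times: list[float]
    values: list[float]
    units: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.times):
            raise ValueError("values and times length mismatch")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "descriptor": self.name, "chain": self.subunit,
            "time_ps": self.times, "value": self.values, "units": self.units,
        })


def _alignment_indices(structure: Structure, roles: ResidueRoleMap) -> list[int]:
    idx = select(structure, roles.alignment_selection)
    if len(idx) < 3:
        # fall back to all protein heavy atoms (warn): tiny fixtures and
        # coarse models may not carry three Cα atoms
        fallback = select(structure, SelectionSpec.build(element_classes=["heavy"],
                                                         hetero=False))
        if len(fallback) < 3:
            raise ValueError("alignment selection resolves to fewer than 3 atoms")
        import warnings
        warnings.warn("alignment selection too small; falling back to all "
                      "protein heavy atoms")
        return fallback
    return idx


def ligand_pose_rmsd(traj: Trajectory, reference: Structure, ligand: LigandSpec,
                     roles: ResidueRoleMap,
                     substructure: Optional[Sequence[str]] = None,
                     stride_ps: Optional[float] = None,
                     ) -> dict[str, DescriptorSeries]:
    """Per-subunit ligand heavy-atom RMSD to the reference pose.

    Frames are aligned on the role map's alignment selection; the RMSD is
    measured over ligand heavy atoms (or the named substructure) without
    re-fitting.  The returned dict has one series per ligand-copy chain plus
    a ``"mean"`` series averaging subunits per frame.
    """
    topo = traj.topology
    copies = find_ligand_copies(topo, ligand)
    if not copies:
        raise ValueError(f"no ligand copies of {ligand.residue_name!r}")
    align_idx = _alignment_indices(topo, roles)
    ref_coords = reference.coords
    if ref_coords.shape[0] != topo.coords.shape[0]:
        raise ValueError("reference and topology atom counts differ")
    frame_idx = traj.sample_indices(stride_ps)
    times = [traj.times[k] for k in frame_idx]
    name = "ligand_pose_rmsd" if substructure is None else "substructure_rmsd"

    measure: dict[str, list[int]] = {}
    for chain, idxs in sorted(copies.items()):
        if substructure is None:
            sel = [i for i in idxs if topo.atoms[i].element != "H"]
        else:
            lut = {topo.atoms[i].name: i for i in idxs}
            missing = [n for n in substructure if n not in lut]
            if missing:
                raise ValueError(f"substructure atoms {missing} missing in chain {chain!r}")
            sel = [lut[n] for n in substructure]
        measure[chain] = sel

    out: dict[str, DescriptorSeries] = {}
    per_chain: dict[str, list[float]] = {c: [] for c in measure}
    for k in frame_idx:
        frame = traj.frames[k]
        sup = kabsch_superpose(frame[align_idx], ref_coords[align_idx])
        moved = sup.apply(frame)
        for chain, sel in measure.items():
            per_chain[chain].append(raw_rmsd(moved[sel], ref_coords[sel]))
    for chain, vals in per_chain.items():
        out[chain] = DescriptorSeries(name, chain, times, vals, "Å")
    grand = np.mean([per_chain[c] for c in per_chain], axis=0)
    out["mean"] = DescriptorSeries(name, "mean", times, [float(v) for v in grand], "Å")
    return out


def _loop_backbone_indices(structure: Structure, chain: str,
                           lo: int, hi: int) -> list[int]:
    idx = []
    for resnum in range(lo, hi + 1):
        for atom_name in ("CA", "C", "N"):
            try:
                idx.append(structure.atom_index(chain, resnum, atom_name))
            except KeyError as exc:
                raise ValueError(
                    f"missing backbone atom {atom_name} of residue {resnum} "
                    f"in chain {chain!r}") from exc
    return idx


def loop_descriptors(traj: Trajectory, reference: Structure, roles: ResidueRoleMap,
                     stride_ps: Optional[float] = None,
                     ) -> dict[str, tuple[DescriptorSeries, DescriptorSeries]]:
    """Loop backbone RMSD and orientation dihedral, per subunit chain.

    The RMSD compares the Cα + carbonyl C + backbone N atoms of the loop
    residue range (18 atoms for a 6-residue loop) after alignment on the role
    map's selection; the dihedral is drawn over the four role Cα atoms.
    """
    topo = traj.topology
    align_idx = _alignment_indices(topo, roles)
    ref_coords = reference.coords
    lo, hi = roles.loop_rmsd_range
    protein_chains = sorted({a.chain_id for a in topo.atoms
                             if a.residue_number == lo and a.name == "CA"})
    if not protein_chains:
        raise ValueError(f"no chain contains residue {lo} with a CA atom")
    frame_idx = traj.sample_indices(stride_ps)
    times = [traj.times[k] for k in frame_idx]

    out: dict[str, tuple[DescriptorSeries, DescriptorSeries]] = {}
    for chain in protein_chains:
        loop_idx = _loop_backbone_indices(topo, chain, lo, hi)
        dih_idx = [topo.atom_index(chain, r, "CA") for r in roles.loop_dihedral_residues]
        rmsd_vals, dih_vals = [], []
        for k in frame_idx:
            frame = traj.frames[k]
            sup = kabsch_superpose(frame[align_idx], ref_coords[align_idx])
            moved = sup.apply(frame)
            rmsd_vals.append(raw_rmsd(moved[loop_idx], ref_coords[loop_idx]))
            p = [frame[i] for i in dih_idx]
            dih_vals.append(dihedral(*p))
        out[chain] = (
            DescriptorSeries("loop_rmsd", chain, times, rmsd_vals, "Å"),
            DescriptorSeries("loop_dihedral", chain, times, dih_vals, "degrees"),
        )
    return out


def gate_distance(structure: Structure, roles: ResidueRoleMap,
                  threshold: float = 4.0,
                  coords: Optional[np.ndarray] = None,
                  chain_pairs: Optional[dict[str, str]] = None,
                  ) -> dict[str, tuple[float, bool]]:
    """Minimum polar-atom distance of the gate residue pair, per subunit.

    Returns chain -> (distance Å, engaged) where engaged means distance <=
    threshold (inclusive).  By default both residues are taken from the same
    chain; ``chain_pairs`` maps the first residue's chain to the partner
    chain holding the second residue (for interfacial pairs).
    """
    if coords is None:
        coords = structure.coords
    (res_a, names_a), (res_b, names_b) = roles.gate_pair
    chains = sorted({a.chain_id for a in structure.atoms
                     if a.residue_number == res_a and a.name in names_a})
    if not chains:
        raise ValueError(f"no chain contains residue {res_a} with atoms {names_a}")
    out = {}
    for chain in chains:
        partner = (chain_pairs or {}).get(chain, chain)
        idx_a = [i for i, a in enumerate(structure.atoms)
                 if a.chain_id == chain and a.residue_number == res_a and a.name in names_a]
        idx_b = [i for i, a in enumerate(structure.atoms)
                 if a.chain_id == partner and a.residue_number == res_b and a.name in names_b]
        if not idx_a or not idx_b:
            raise ValueError(
                f"gate residues missing listed polar atoms in chains {chain}/{partner}")
        d, _ = min_distance(coords[idx_a], coords[idx_b])
        out[chain] = (d, d <= threshold)
    return out


def pocket_water_count(structure: Structure, ligand: LigandSpec,
                       cutoff: float = 3.0,
                       coords: Optional[np.ndarray] = None) -> dict[str, int]:
    """Count water oxygens within ``cutoff`` of any ligand atom, per subunit.

    Each water oxygen is counted once per subunit pocket even when close to
    several ligand atoms.
    """
    if coords is None:
        coords = structure.coords
    water_ox = [i for i, a in enumerate(structure.atoms)
                if a.is_water and a.element == "O"]
    copies = find_ligand_copies(structure, ligand)
    if not copies:
        raise ValueError(f"no ligand copies of {ligand.residue_name!r}")
    out = {}
    for chain, lig_idx in sorted(copies.items()):
        if not water_ox:
            out[chain] = 0
            continue
        from scipy.spatial.distance import cdist
        d = cdist(coords[water_ox], coords[lig_idx])
        out[chain] = int(np.sum(d.min(axis=1) <= cutoff))
    return out


def residue_displacement_map(struct_a: Structure, struct_b: Structure,
                             roles: ResidueRoleMap,
                             smooth: bool = False) -> pd.DataFrame:
    """Per-residue Cα displacement between two structures after alignment.

    B is aligned onto A using atoms of the role map's alignment selection
    matched by (chain, residue number, insertion code, atom name); the
    displacement is |Cα_A - Cα_B'| for every residue with a Cα in both.
    Residues present in only one structure are absent from the table, never
    reported as zero.  With ``smooth=True`` a natural cubic spline over the
    sequential residue index is added per chain (column ``smoothed``), never
    crossing chain breaks.
    """
    sel_a = select(struct_a, roles.alignment_selection)
    key_a = {(struct_a.atoms[i].chain_id, struct_a.atoms[i].residue_number,
              struct_a.atoms[i].insertion_code, struct_a.atoms[i].name): i
             for i in sel_a}
    sel_b = select(struct_b, roles.alignment_selection)
    key_b = {(struct_b.atoms[i].chain_id, struct_b.atoms[i].residue_number,
              struct_b.atoms[i].insertion_code, struct_b.atoms[i].name): i
             for i in sel_b}
    common = sorted(set(key_a) & set(key_b))
    if len(common) < 3:
        raise ValueError("fewer than 3 common alignment atoms")
    coords_a, coords_b = struct_a.coords, struct_b.coords
    sup = kabsch_superpose(coords_b[[key_b[k] for k in common]],
                           coords_a[[key_a[k] for k in common]])
    moved_b = sup.apply(coords_b)

    ca_a = {(a.chain_id, a.residue_number, a.insertion_code): i
            for i, a in enumerate(struct_a.atoms) if a.name == "CA" and not a.is_hetero}
    ca_b = {(a.chain_id, a.residue_number, a.insertion_code): i
            for i, a in enumerate(struct_b.atoms) if a.name == "CA" and not a.is_hetero}
    rows = []
    for key in sorted(set(ca_a) & set(ca_b)):
        ia, ib = ca_a[key], ca_b[key]
        disp = float(np.linalg.norm(coords_a[ia] - moved_b[ib]))
        rows.append({"chain": key[0], "residue_number": key[1],
                     "insertion_code": key[2], "displacement": disp})
    df = pd.DataFrame(rows)
    if smooth and not df.empty:
        smoothed = np.full(len(df), np.nan)
        for chain, grp in df.groupby("chain"):
            x = grp["residue_number"].to_numpy(dtype=float)
            y = grp["displacement"].to_numpy(dtype=float)
            if len(x) >= 2:
                spline = CubicSpline(x, y, bc_type="natural")
                smoothed[grp.index] = spline(x)
            else:
                smoothed[grp.index] = y
        df["smoothed"] = smoothed
    return df


def displacement_bfactor_structure(struct_a: Structure,
                                   displacement: pd.DataFrame) -> Structure:
    """Copy of A with per-residue displacements stuffed into B-factors."""
    from dataclasses import replace
    lut = {(r.chain, r.residue_number): r.displacement
           for r in displacement.itertuples()}
    atoms = [replace(a, b_factor=float(lut.get((a.chain_id, a.residue_number), 0.0)))
             for a in struct_a.atoms]
    return Structure(atoms, list(struct_a.bonds), struct_a.identifier + "_displacement")
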