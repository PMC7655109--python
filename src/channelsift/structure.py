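"""Atomic structures, multi-model PDB trajectories, selections, and bonds.

The required trajectory dialect is multi-model PDB (MODEL/ENDMDL delimited);
binary trajectory formats can be adapted onto the same :class:`Trajectory`
contract externally.  Coordinates are Å throughout, times are ps, residue
numbering is 1-based as in the PDB.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Residue names recognized as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "TIP", "SPC"})

#: Standard amino-acid residue names (incl. common His tautomer aliases).
AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
})

# Cordero-style single-bond covalent radii (Å).
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "K": 2.03,
    "MG": 1.41, "CA": 1.76, "ZN": 1.22, "FE": 1.32, "SE": 1.20, "B": 0.84,
}

_TWO_LETTER_ELEMENTS = frozenset({"CL", "BR", "NA", "MG", "ZN", "FE", "SE", "CA", "K"})

_H_BOND_MAX = 1.25  # Å; a hydrogen bonds only to a heavy atom this close
_CLASH_DISTANCE = 0.5  # Å


class PDBFormatError(ValueError):
    """Raised for malformed PDB content in strict mode."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, mirroring the fixed-column PDB fields."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    altloc: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESNAMES

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, residue_number, insertion_code) identifying the residue."""
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """An ordered list of atoms plus optional bonds."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    identifier: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range for {n} atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float64 coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=tuple(map(float, xyz)))
                 for a, xyz in zip(self.atoms, coords)]
        return Structure(atoms, list(self.bonds), self.identifier)

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Map residue_key -> atom indices, preserving atom order."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def atom_index(self, chain_id: str, residue_number: int, name: str,
                   insertion_code: str = "") -> int:
        for i, a in enumerate(self.atoms):
            if (a.chain_id == chain_id and a.residue_number == residue_number
                    and a.name == name and a.insertion_code == insertion_code):
                return i
        raise KeyError(f"atom {chain_id}/{residue_number}{insertion_code}/{name} not found")


@dataclass
class Trajectory:
    """Topology plus an ordered stack of coordinate frames."""

    topology: Structure
    frames: list[np.ndarray]
    times: list[float]

    def __post_init__(self) -> None:
        n = len(self.topology.atoms)
        self.frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k} has {f.shape[0]} coordinates, topology has {n} atoms")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        t = np.asarray(self.times, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.times = [float(x) for x in t]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, k: int) -> Structure:
        return self.topology.with_coords(self.frames[k])

    def sample_indices(self, stride_ps: Optional[float]) -> list[int]:
        """Frame indices at an equidistant time stride.

        ``None`` selects every frame.  Otherwise samples are taken at times
        ``t0 + k*stride`` for k = 1 .. floor(duration / stride), mapped to the
        nearest stored frame, so a 100 ns trajectory sampled at a 500 ps
        stride yields exactly 200 frames.
        """
        if stride_ps is None:
            return list(range(self.n_frames))
        if stride_ps <= 0:
            raise ValueError("stride must be positive")
        t = np.asarray(self.times)
        duration = t[-1] - t[0]
        n_samples = int(np.floor(duration / stride_ps + 1e-9))
        targets = t[0] + stride_ps * np.arange(1, n_samples + 1)
        return [int(np.argmin(np.abs(t - target))) for target in targets]


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection; constraints intersect, empty spec selects nothing."""

    chains: Optional[frozenset[str]] = None
    residue_ranges: Optional[tuple[tuple[int, int], ...]] = None
    residue_names: Optional[frozenset[str]] = None
    atom_names: Optional[frozenset[str]] = None
    element_classes: Optional[frozenset[str]] = None
    hetero: Optional[bool] = None

    @staticmethod
    def build(chains: Optional[Iterable[str]] = None,
              residue_ranges: Optional[Iterable[tuple[int, int]]] = None,
              residue_names: Optional[Iterable[str]] = None,
              atom_names: Optional[Iterable[str]] = None,
              element_classes: Optional[Iterable[str]] = None,
              hetero: Optional[bool] = None) -> "SelectionSpec":
        return SelectionSpec(
            chains=frozenset(chains) if chains is not None else None,
            residue_ranges=tuple(tuple(r) for r in residue_ranges) if residue_ranges is not None else None,
            residue_names=frozenset(residue_names) if residue_names is not None else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            element_classes=frozenset(element_classes) if element_classes is not None else None,
            hetero=hetero,
        )

    @property
    def is_empty(self) -> bool:
        return all(v is None for v in (
            self.chains, self.residue_ranges, self.residue_names,
            self.atom_names, self.element_classes, self.hetero))


_ELEMENT_CLASSES = {"backbone", "calpha", "heavy", "water-oxygen", "sidechain"}
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


def _matches_class(atom: AtomRecord, cls: str) -> bool:
    if cls == "backbone":
        return atom.residue_name in AMINO_ACIDS and atom.name in _BACKBONE_NAMES
    if cls == "calpha":
        return atom.residue_name in AMINO_ACIDS and atom.name == "CA"
    if cls == "heavy":
        return atom.element != "H"
    if cls == "water-oxygen":
        return atom.is_water and atom.element == "O"
    if cls == "sidechain":
        return (atom.residue_name in AMINO_ACIDS and atom.name not in _BACKBONE_NAMES
                and atom.element != "H")
    raise ValueError(f"unknown element class {cls!r}; known: {sorted(_ELEMENT_CLASSES)}")


def select(structure: Structure, spec: SelectionSpec) -> list[int]:
    """Resolve a :class:`SelectionSpec` to an ordered list of atom indices.

    Selections referencing chains absent from the structure yield an empty
    result with a warning rather than an error.
    """
    if spec.is_empty:
        return []
    if spec.chains is not None:
        present = set(structure.chains())
        missing = spec.chains - present
        if missing and not (spec.chains & present):
            warnings.warn(f"selection references unknown chain(s) {sorted(missing)}")
    out = []
    for i, a in enumerate(structure.atoms):
        if spec.chains is not None and a.chain_id not in spec.chains:
            continue
        if spec.residue_ranges is not None and not any(
                lo <= a.residue_number <= hi for lo, hi in spec.residue_ranges):
            continue
        if spec.residue_names is not None and a.residue_name not in spec.residue_names:
            continue
        if spec.atom_names is not None and a.name not in spec.atom_names:
            continue
        if spec.element_classes is not None and not any(
                _matches_class(a, c) for c in spec.element_classes):
            continue
        if spec.hetero is not None and a.is_hetero != spec.hetero:
            continue
        out.append(i)
    return out


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------

def _infer_element(name: str, residue_name: str, hetero: bool) -> str:
    """Best-effort element from the atom-name field when columns 77-78 are blank."""
    stripped = name.strip()
    if not stripped:
        return ""
    if hetero and stripped.upper() in _TWO_LETTER_ELEMENTS and residue_name.strip() == stripped:
        return stripped.upper().capitalize() if len(stripped) > 1 else stripped
    # hydrogens may be digit-prefixed, e.g. 1HB2
    core = stripped.lstrip("0123456789")
    if not core:
        return ""
    if core[0] in ("H", "D"):
        return "H"
    return core[0]


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:21].strip()
        chain_id = line[21].strip()
        residue_number = int(line[22:26])
        insertion_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
        b_factor = float(line[60:66]) if line[60:66].strip() else 0.0
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if element:
        element = element.capitalize() if len(element) > 1 else element
    else:
        element = _infer_element(name, residue_name, line.startswith("HETATM"))
    if not np.all(np.isfinite([x, y, z])):
        raise PDBFormatError(f"non-finite coordinates at line {lineno}")
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=residue_name,
        residue_number=residue_number, insertion_code=insertion_code,
        chain_id=chain_id, altloc=altloc, coords=(x, y, z),
        occupancy=occupancy, b_factor=b_factor,
        is_hetero=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[int]:
    """Indices of atoms kept after altloc filtering.

    Policy: for each (chain, resnum, icode, name) keep the highest-occupancy
    altloc; ties broken by altloc letter, 'A' first.
    """
    groups: dict[tuple, list[int]] = {}
    for i, a in enumerate(atoms):
        groups.setdefault((a.residue_key, a.name), []).append(i)
    keep: list[int] = []
    for idxs in groups.values():
        if len(idxs) == 1:
            keep.append(idxs[0])
        else:
            best = min(idxs, key=lambda i: (-atoms[i].occupancy, atoms[i].altloc or "~"))
            keep.append(best)
    return sorted(keep)


def read_structure(source: Union[str, Path, io.TextIOBase], strict: bool = True,
                   default_stride_ps: float = 1.0,
                   times: Optional[Sequence[float]] = None,
                   identifier: str = "") -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Single-model files yield a one-frame trajectory.  Times default to
    ``frame_index * default_stride_ps`` unless given explicitly.  In strict
    mode malformed records and inter-model atom-count mismatches raise
    :class:`PDBFormatError`; otherwise bad records are skipped with a warning
    (count mismatches always raise).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        if not identifier:
            identifier = Path(source).stem
    else:
        text = source.read()

    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model_records = False
    model_number = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model_records = True
            in_model = True
            model_number += 1
            current = []
        elif rec.startswith("ENDMDL"):
            in_model = False
            models.append(current)
            current = []
        elif rec.startswith(("ATOM  ", "HETATM")):
            try:
                current.append(_parse_atom_line(line, lineno))
            except PDBFormatError:
                if strict:
                    raise
                warnings.warn(f"skipping malformed record at line {lineno}")
    if current:
        models.append(current)
    if not models or not models[0]:
        raise PDBFormatError("no atoms found")

    keep = _resolve_altlocs(models[0])
    ref_atoms = [models[0][i] for i in keep]
    ref_sig = [(a.residue_key, a.name) for a in ref_atoms]

    frames = [np.array([a.coords for a in ref_atoms], dtype=float)]
    for m, model in enumerate(models[1:], start=2):
        km = _resolve_altlocs(model)
        atoms_m = [model[i] for i in km]
        if len(atoms_m) != len(ref_atoms):
            raise PDBFormatError(
                f"model {m} has {len(atoms_m)} atoms, model 1 has {len(ref_atoms)}")
        sig = [(a.residue_key, a.name) for a in atoms_m]
        if sig != ref_sig:
            # same count but different atom identities: reorder if possible
            lut = {s: i for i, s in enumerate(sig)}
            try:
                atoms_m = [atoms_m[lut[s]] for s in ref_sig]
            except KeyError as exc:
                raise PDBFormatError(f"model {m} atom identities differ from model 1") from exc
        frames.append(np.array([a.coords for a in atoms_m], dtype=float))

    topo = Structure(ref_atoms, identifier=identifier)
    if times is None:
        times = [k * default_stride_ps for k in range(len(frames))]
    else:
        times = list(times)
    _ = saw_model_records  # models without MODEL records handled identically
    return Trajectory(topo, frames, times)


def _format_atom_line(a: AtomRecord, serial: int, coords: np.ndarray) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = a.name
    if len(name) < 4 and (len(a.element) < 2 or a.element.upper() not in _TWO_LETTER_ELEMENTS):
        name = f" {name}"
    elem = a.element.upper().rjust(2)[:2]
    return (f"{record}{serial:>5d} {name:<4s}{a.altloc or ' ':1s}{a.residue_name:<4s}"
            f"{a.chain_id or ' ':1s}{a.residue_number:>4d}{a.insertion_code or ' ':1s}   "
            f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {elem}")


def write_structure(obj: Union[Structure, Trajectory],
                    target: Union[str, Path, io.TextIOBase]) -> None:
    """Write a Structure (single model) or Trajectory (multi-model) as PDB."""
    if isinstance(obj, Structure):
        traj = Trajectory(obj, [obj.coords], [0.0])
    else:
        traj = obj
    lines: list[str] = []
    multi = traj.n_frames > 1
    for k, frame in enumerate(traj.frames):
        if multi:
            lines.append(f"MODEL {k + 1:>8d}")
        for i, a in enumerate(traj.topology.atoms):
            lines.append(_format_atom_line(a, i + 1, frame[i]))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)


# ---------------------------------------------------------------------------
# Bond inference
# ---------------------------------------------------------------------------

def covalent_radius(element: str) -> float:
    r = COVALENT_RADII.get(element.upper())
    if r is None:
        r = 0.76  # fall back to carbon for exotic elements
    return r


def infer_bonds(structure: Structure, tolerance: float = 0.45) -> list[tuple[int, int]]:
    """Distance-based bond inference with Cordero-style covalent radii.

    Bond i-j iff d(i, j) <= r_cov(i) + r_cov(j) + tolerance, except that a
    hydrogen only bonds to the heavy atoms within 1.25 Å, and no bond crosses
    into a water residue from a different residue.  Atoms closer than 0.5 Å
    are reported as clashes.
    """
    coords = structure.coords
    if len(coords) < 2:
        return []
    radii = np.array([covalent_radius(a.element) for a in structure.atoms])
    max_cut = 2 * radii.max() + tolerance
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    bonds: list[tuple[int, int]] = []
    clashes: list[tuple[int, int]] = []
    for i, j in pairs:
        i, j = int(i), int(j)
        ai, aj = structure.atoms[i], structure.atoms[j]
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < _CLASH_DISTANCE:
            clashes.append((i, j))
            continue
        if (ai.is_water or aj.is_water) and ai.residue_key != aj.residue_key:
            continue
        h_i, h_j = ai.element == "H", aj.element == "H"
        if h_i and h_j:
            continue
        if h_i or h_j:
            if d <= _H_BOND_MAX:
                bonds.append((i, j))
            continue
        if d <= radii[i] + radii[j] + tolerance:
            bonds.append((i, j))
    if clashes:
        raise ValueError(f"clashing atom pairs closer than {_CLASH_DISTANCE} Å: {clashes}")
    return sorted(bonds)


def attached_hydrogens(structure: Structure) -> dict[int, list[int]]:
    """Map heavy-atom index -> indices of hydrogens within bonding distance."""
    coords = structure.coords
    h_idx = [i for i, a in enumerate(structure.atoms) if a.element == "H"]
    out: dict[int, list[int]] = {}
    if not h_idx:
        return out
    heavy_idx = [i for i, a in enumerate(structure.atoms) if a.element != "H"]
    tree = cKDTree(coords[heavy_idx])
    for h in h_idx:
        dist, nearest = tree.query(coords[h], k=1)
        if dist <= _H_BOND_MAX:
            heavy = heavy_idx[int(nearest)]
            if structure.atoms[h].residue_key == structure.atoms[heavy].residue_key:
                out.setdefault(heavy, []).append(h)
    return out
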