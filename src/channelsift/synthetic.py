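"""Ground-truth-labeled synthetic fixtures for every analysis stage.

Three generators:

* :func:`build_pocket_scene` — a miniature two-chain binding pocket with a
  rigid multi-group ligand and one planted interaction per target residue,
  each realized at an exactly controlled geometry, plus decoy atoms and decoy
  waters placed outside all cutoffs.  Returns the exact expected bitsets.
* :func:`build_pocket_trajectory` — toggles planted geometries between
  engaged and disengaged poses following simulated two-state Markov chains,
  returning the exact per-frame state series.
* :func:`build_pore_structure` — rings of pseudo-atoms lining an analytic
  radius profile, returning the analytically known accessible radius.

Fixtures use minimal ideal-geometry residue templates, not full receptor
models; waters carry explicit hydrogens so angle criteria are exercised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from channelsift.fingerprints import (
    BIT_NAMES,
    FingerprintConfig,
    InteractionBitset,
    LigandSpec,
)
from channelsift.structure import AtomRecord, Structure, Trajectory

_MIN_SEPARATION = 0.5


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteraction:
    """One interaction planted at a controlled geometry.

    ``distance`` is the defining contact distance of the interaction type:
    carbon-carbon for APOLAR, ring-centroid separation for AROM_FTF, minimum
    inter-ring atom distance for AROM_ETF, heavy-atom distance for the
    hydrogen-bond and water-bridge links, and group-atom distance for the
    electrostatic types.  ``hb_angle`` sets the donor-H-acceptor angle of
    planted hydrogen bonds.
    """

    bit: str
    distance: float
    hb_angle: float = 180.0

    def __post_init__(self) -> None:
        if self.bit not in BIT_NAMES:
            raise ValueError(f"unknown bit {self.bit!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class PocketSceneSpec:
    """Recipe for a planted pocket scene.  ``seed`` is mandatory."""

    planted: list[PlantedInteraction]
    seed: int
    n_decoy_atoms: int = 0
    n_waters: int = 0
    box: float = 40.0
    config: FingerprintConfig = field(default_factory=FingerprintConfig)


@dataclass
class PocketScene:
    """A generated scene with its exact expected fingerprint."""

    structure: Structure
    ligand: LigandSpec
    ground_truth: dict[tuple[str, int], InteractionBitset]
    #: per planted bit: (residue label, engagement direction, residue atom indices)
    planted_geometry: dict[str, tuple[tuple[str, int], np.ndarray, list[int]]]
    config: FingerprintConfig
    seed: int


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +x onto ``direction`` (Rodrigues)."""
    a = np.array([1.0, 0.0, 0.0])
    b = _unit(direction)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _ring_coords(center: np.ndarray, normal: np.ndarray, radius: float = 1.39,
                 n: int = 6, phase: float = 0.0) -> np.ndarray:
    normal = _unit(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(normal, ref))
    v = np.cross(normal, u)
    ang = phase + 2 * np.pi * np.arange(n) / n
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


# local templates: (atom name, element, local coords); anchor atom at the
# origin with the ligand direction along +x
_TEMPLATES = {
    "LEU": ("CD1", [("CA", "C", (-3.0, 0.6, 0.0)), ("CB", "C", (-2.0, -0.2, 0.6)),
                    ("CG", "C", (-1.2, 0.4, -0.4)), ("CD1", "C", (0.0, 0.0, 0.0)),
                    ("CD2", "C", (-1.6, 1.2, -1.6))]),
    "SER": ("OG", [("CA", "C", (-2.4, 0.2, 0.4)), ("CB", "C", (-1.4, -0.3, -0.4)),
                   ("OG", "O", (0.0, 0.0, 0.0)), ("HG", "H", (0.96, 0.0, 0.0))]),
    "ASN": ("OD1", [("CA", "C", (-3.1, 0.4, 0.3)), ("CB", "C", (-2.2, -0.4, -0.5)),
                    ("CG", "C", (-1.2, 0.3, 0.2)), ("OD1", "O", (0.0, 0.0, 0.0)),
                    ("ND2", "N", (-1.5, 1.4, 0.9))]),
    "ASP": ("OD1", [("CA", "C", (-3.1, 0.4, 0.3)), ("CB", "C", (-2.2, -0.4, -0.5)),
                    ("CG", "C", (-1.1, 0.3, 0.2)), ("OD1", "O", (0.0, 0.0, 0.0)),
                    ("OD2", "O", (-1.3, 1.5, 0.7))]),
    "ARG": ("NH1", [("CD", "C", (-2.8, 0.3, 0.4)), ("NE", "N", (-2.0, -0.5, -0.3)),
                    ("CZ", "C", (-1.2, 0.4, 0.2)), ("NH1", "N", (0.0, 0.0, 0.0)),
                    ("NH2", "N", (-1.6, 1.6, 0.6))]),
}

# ligand group geometry (rigid, multi-fragment test ligand)
_D = 6.0
_DIAG = 1.0 / np.sqrt(2.0)
_LIG_RING_CENTER = np.array([-_D, 0.0, 0.0])
_LIG_ANCHORS = {
    "APOLAR": (np.array([_D, 0.0, 0.0]), np.array([1.0, 0.0, 0.0])),
    "AROM_FTF": (_LIG_RING_CENTER, np.array([0.0, 0.0, 1.0])),
    "AROM_ETF": (_LIG_RING_CENTER, np.array([0.0, 0.0, -1.0])),
    "HB_PROT_ACCEPTOR": (np.array([0.0, _D, 0.0]), np.array([0.0, 1.0, 0.0])),
    "HB_PROT_DONOR": (np.array([0.0, -_D, 0.0]), np.array([0.0, -1.0, 0.0])),
    "ELEC_PROT_NEG": (np.array([0.0, 0.0, _D]), np.array([0.0, 0.0, 1.0])),
    "ELEC_PROT_POS": (np.array([0.0, 0.0, -_D]), np.array([0.0, 0.0, -1.0])),
    "WATER1": (np.array([_D * _DIAG, _D * _DIAG, 0.0]), np.array([_DIAG, _DIAG, 0.0])),
    "WATER2": (np.array([-_D * _DIAG, -_D * _DIAG, 0.0]), np.array([-_DIAG, -_DIAG, 0.0])),
}


def _ligand_atoms() -> list[tuple[str, str, np.ndarray]]:
    atoms: list[tuple[str, str, np.ndarray]] = [
        ("C1", "C", _LIG_ANCHORS["APOLAR"][0]),
        ("N1", "N", _LIG_ANCHORS["HB_PROT_ACCEPTOR"][0]),
        ("H11", "H", _LIG_ANCHORS["HB_PROT_ACCEPTOR"][0] + np.array([0.0, 0.96, 0.0])),
        ("O1", "O", _LIG_ANCHORS["HB_PROT_DONOR"][0]),
        ("N2", "N", _LIG_ANCHORS["ELEC_PROT_NEG"][0]),
        ("C9", "C", _LIG_ANCHORS["ELEC_PROT_POS"][0]),
        ("O2", "O", _LIG_ANCHORS["ELEC_PROT_POS"][0] + np.array([0.6, 0.0, -0.8])),
        ("O3", "O", _LIG_ANCHORS["ELEC_PROT_POS"][0] + np.array([-0.6, 0.0, -0.8])),
        ("O4", "O", _LIG_ANCHORS["WATER1"][0]),
        ("O5", "O", _LIG_ANCHORS["WATER2"][0]),
    ]
    ring = _ring_coords(_LIG_RING_CENTER, np.array([0.0, 0.0, 1.0]))
    for k, xyz in enumerate(ring):
        atoms.append((f"CR{k + 1}", "C", xyz))
    return atoms


def _ligand_spec() -> LigandSpec:
    return LigandSpec(
        residue_name="LIG",
        chain_id=None,
        ring_groups=[[f"CR{k}" for k in range(1, 7)]],
        hbond_donors=["N1"],
        hbond_acceptors=["O1", "O4", "O5"],
        positive_groups=[["N2"]],
        negative_groups=[["O2", "O3"]],
        nonpolar_atoms=["C1"],
    )


def _place_donor_h(donor: np.ndarray, acceptor: np.ndarray,
                   direction: np.ndarray, target_angle: float) -> np.ndarray:
    """Hydrogen at 0.96 Å from the donor realizing donor-H-acceptor = angle.

    The achieved angle decreases monotonically as the hydrogen swings off the
    donor-acceptor axis, so a bisection over the swing angle is exact.
    """
    from channelsift.geometry import angle_deg
    perp = _unit(np.cross(direction, [0.41, 0.12, 0.9]))

    def h_at(phi: float) -> np.ndarray:
        return donor + 0.96 * (-direction * np.cos(phi) + perp * np.sin(phi))

    lo, hi = 0.0, np.pi * 0.99  # angle(lo) = 180, decreasing in phi
    if target_angle >= 180.0:
        return h_at(0.0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if angle_deg(donor, h_at(mid), acceptor) > target_angle:
            lo = mid
        else:
            hi = mid
    return h_at(0.5 * (lo + hi))


def _expected_bit(planted: PlantedInteraction, config: FingerprintConfig) -> bool:
    """Expected bit value from the planted geometry by the stated rules."""
    b, d = planted.bit, planted.distance
    if b == "APOLAR":
        return d <= config.apolar_cutoff
    if b in ("AROM_FTF", "AROM_ETF"):
        return d <= config.aromatic_cutoff
    if b in ("ELEC_PROT_POS", "ELEC_PROT_NEG"):
        return d <= config.electrostatic_cutoff
    if b in ("HB_PROT_DONOR", "HB_PROT_ACCEPTOR"):
        return d <= config.hbond_heavy_cutoff and planted.hb_angle >= config.hbond_angle_min
    if b in ("WATER1", "WATER2"):
        return d <= config.hbond_heavy_cutoff
    raise AssertionError(b)


def build_pocket_scene(spec: PocketSceneSpec) -> PocketScene:
    """Generate a pocket scene with exactly known per-residue bitsets.

    Each planted interaction gets its own target residue placed along a
    dedicated direction from the corresponding ligand group, so planted
    geometries never interfere; decoy atoms and decoy waters are rejected
    into positions outside all interaction cutoffs.
    """
    seen = [p.bit for p in spec.planted]
    if len(seen) != len(set(seen)):
        raise ValueError("at most one planted interaction per bit type")
    rng = np.random.default_rng(spec.seed)
    cfg = spec.config

    atoms: list[AtomRecord] = []
    serial = [1]

    def add_atom(name: str, element: str, resname: str, resnum: int,
                 chain: str, xyz: np.ndarray, hetero: bool = False) -> int:
        atoms.append(AtomRecord(
            serial=serial[0], name=name, element=element, residue_name=resname,
            residue_number=resnum, insertion_code="", chain_id=chain, altloc="",
            coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
            is_hetero=hetero))
        serial[0] += 1
        return len(atoms) - 1

    for name, element, xyz in _ligand_atoms():
        add_atom(name, element, "LIG", 900, "L", np.asarray(xyz), hetero=True)

    ground_truth: dict[tuple[str, int], InteractionBitset] = {}
    planted_geometry: dict[str, tuple[tuple[str, int], np.ndarray, list[int]]] = {}
    resnum = 10
    chain_cycle = ("A", "B")

    for k, planted in enumerate(spec.planted):
        chain = chain_cycle[k % 2]
        anchor, direction = _LIG_ANCHORS[planted.bit]
        idxs: list[int] = []

        if planted.bit in ("AROM_FTF", "AROM_ETF"):
            resname = "PHE"
            if planted.bit == "AROM_FTF":
                center = anchor + direction * planted.distance
                ring = _ring_coords(center, direction)
            else:
                # perpendicular ring; offset solved so the min inter-ring
                # atom distance equals the requested value
                lig_ring = _ring_coords(_LIG_RING_CENTER, np.array([0.0, 0.0, 1.0]))
                normal = np.array([0.0, 1.0, 0.0])

                def min_dist_at(offset: float) -> float:
                    c = anchor + direction * offset
                    r = _ring_coords(c, normal, phase=np.pi / 2)
                    from scipy.spatial.distance import cdist
                    return float(cdist(lig_ring, r).min())

                lo, hi = 0.5, 15.0
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    if min_dist_at(mid) < planted.distance:
                        lo = mid
                    else:
                        hi = mid
                center = anchor + direction * hi
                ring = _ring_coords(center, normal, phase=np.pi / 2)
            ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
            for name, xyz in zip(ring_names, ring):
                idxs.append(add_atom(name, "C", resname, resnum, chain, xyz))
            idxs.append(add_atom("CB", "C", resname, resnum, chain,
                                 center + direction * 2.6))
        elif planted.bit in ("WATER1", "WATER2"):
            resname = "ASN"
            order = 1 if planted.bit == "WATER1" else 2
            link = planted.distance
            for w in range(order):
                opos = anchor + direction * link * (w + 1)
                wi = add_atom("O", "O", "HOH", 500 + resnum + w, "W", opos, hetero=True)
                # one hydrogen toward each neighbor so every link can donate
                add_atom("H1", "H", "HOH", 500 + resnum + w, "W",
                         opos - direction * 0.96, hetero=True)
                add_atom("H2", "H", "HOH", 500 + resnum + w, "W",
                         opos + direction * 0.96, hetero=True)
                _ = wi
            rot = _rotation_to(-direction)
            origin = anchor + direction * link * (order + 1)
            _, template = _TEMPLATES[resname]
            for name, element, local in template:
                xyz = origin + rot @ np.asarray(local)
                idxs.append(add_atom(name, element, resname, resnum, chain, xyz))
        else:
            resname = {"APOLAR": "LEU", "HB_PROT_DONOR": "SER",
                       "HB_PROT_ACCEPTOR": "ASN", "ELEC_PROT_NEG": "ASP",
                       "ELEC_PROT_POS": "ARG"}[planted.bit]
            rot = _rotation_to(-direction)
            if planted.bit == "HB_PROT_ACCEPTOR":
                # the ligand donor hydrogen is fixed along +direction, so the
                # requested donor-H-acceptor angle is realized by swinging the
                # acceptor off-axis at the requested heavy-atom distance
                from channelsift.geometry import angle_deg
                h = anchor + 0.96 * direction  # ligand H11 position
                perp = _unit(np.cross(direction, [0.37, 0.21, 0.9]))

                def acceptor_at(phi: float) -> np.ndarray:
                    return anchor + planted.distance * (
                        direction * np.cos(phi) + perp * np.sin(phi))

                lo, hi = 0.0, np.pi * 0.99
                if planted.hb_angle < 180.0:
                    for _ in range(80):
                        mid = 0.5 * (lo + hi)
                        if angle_deg(anchor, h, acceptor_at(mid)) > planted.hb_angle:
                            lo = mid
                        else:
                            hi = mid
                    phi = 0.5 * (lo + hi)
                else:
                    phi = 0.0
                origin = acceptor_at(phi)
                direction = _unit(origin - anchor)
                rot = _rotation_to(-direction)
            elif planted.bit == "ELEC_PROT_POS":
                # the ligand's negative group has off-axis oxygens: solve the
                # axial offset so the minimum group-atom distance is exact
                grp = np.array([anchor + [0.6, 0.0, -0.8],
                                anchor + [-0.6, 0.0, -0.8]])
                lo, hi = 0.0, 20.0
                for _ in range(80):
                    mid = 0.5 * (lo + hi)
                    p = anchor + direction * mid
                    if np.linalg.norm(grp - p, axis=1).min() < planted.distance:
                        lo = mid
                    else:
                        hi = mid
                origin = anchor + direction * hi
            else:
                origin = anchor + direction * planted.distance
            _, template = _TEMPLATES[resname]
            for name, element, local in template:
                xyz = origin + rot @ np.asarray(local)
                if name == "HG" and planted.bit == "HB_PROT_DONOR":
                    xyz = _place_donor_h(origin, anchor, direction,
                                         planted.hb_angle)
                idxs.append(add_atom(name, element, resname, resnum, chain, xyz))

        label = (resname, resnum)
        bits = InteractionBitset()
        if _expected_bit(planted, cfg):
            bits.set(planted.bit)
        ground_truth[label] = bits
        planted_geometry[planted.bit] = (label, direction.copy(), idxs)
        resnum += 1

    # decoys: carbons and waters rejected into positions beyond every cutoff
    occupied = np.array([a.coords for a in atoms])
    polar_or_water = np.array([a.coords for a in atoms
                               if a.element in ("N", "O", "S")]).reshape(-1, 3)
    keep_out = cfg.max_cutoff + 0.5

    def sample_position(min_any: float, min_polar: float) -> np.ndarray:
        nonlocal occupied
        for _ in range(10_000):
            p = rng.uniform(-spec.box / 2, spec.box / 2, size=3)
            if np.linalg.norm(occupied - p, axis=1).min() < min_any:
                continue
            if polar_or_water.size and np.linalg.norm(polar_or_water - p, axis=1).min() < min_polar:
                continue
            return p
        raise RuntimeError("could not place decoy: box too small")

    for k in range(spec.n_decoy_atoms):
        lig = np.array([a.coords for a in atoms if a.residue_name == "LIG"])
        for _ in range(10_000):
            p = sample_position(3.0, 3.0)
            if np.linalg.norm(lig - p, axis=1).min() > keep_out:
                break
        else:
            raise RuntimeError("could not place decoy atom")
        add_atom("C", "C", "DEC", 700 + k, "D", p, hetero=True)
        occupied = np.array([a.coords for a in atoms])

    for k in range(spec.n_waters):
        p = sample_position(3.0, keep_out + 1.0)
        wnum = 800 + k
        add_atom("O", "O", "HOH", wnum, "V", p, hetero=True)
        d1 = _unit(rng.normal(size=3))
        add_atom("H1", "H", "HOH", wnum, "V", p + 0.96 * d1, hetero=True)
        add_atom("H2", "H", "HOH", wnum, "V", p - 0.96 * d1, hetero=True)
        occupied = np.array([a.coords for a in atoms])

    structure = Structure(atoms, identifier=f"pocket_scene_seed{spec.seed}")
    coords = structure.coords
    from scipy.spatial.distance import pdist
    if len(coords) > 1 and pdist(coords).min() < _MIN_SEPARATION:
        raise ValueError("infeasible geometry: planted atoms closer than 0.5 Å")
    return PocketScene(structure=structure, ligand=_ligand_spec(),
                       ground_truth=ground_truth,
                       planted_geometry=planted_geometry,
                       config=cfg, seed=spec.seed)


# ---------------------------------------------------------------------------
# Markov-switching trajectories
# ---------------------------------------------------------------------------

@dataclass
class OccupancySchedule:
    """Two-state transition probabilities per scheduled bit."""

    entries: dict[str, tuple[float, float]]  # bit -> (p01, p10)
    n_frames: int
    seed: int
    dt_ps: float = 500.0
    start_state: Optional[int] = None

    def __post_init__(self) -> None:
        for bit, (p01, p10) in self.entries.items():
            if bit not in BIT_NAMES:
                raise ValueError(f"unknown bit {bit!r}")
            if not (0 <= p01 <= 1 and 0 <= p10 <= 1):
                raise ValueError("transition probabilities must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def simulate_two_state_chain(p01: float, p10: float, n: int,
                             rng: np.random.Generator,
                             start_state: Optional[int] = None) -> np.ndarray:
    """Simulate a binary Markov chain; start drawn from the stationary law."""
    if start_state is None:
        if p01 + p10 == 0:
            state = 1
        else:
            state = int(rng.random() < p01 / (p01 + p10))
    else:
        state = int(start_state)
    out = np.empty(n, dtype=int)
    u = rng.random(n)
    for k in range(n):
        out[k] = state
        if state == 0:
            state = 1 if u[k] < p01 else 0
        else:
            state = 0 if u[k] < p10 else 1
    return out


def build_pocket_trajectory(scene: PocketScene, schedule: OccupancySchedule,
                            ) -> tuple[Trajectory, dict[tuple[tuple[str, int], str], np.ndarray]]:
    """Markov-toggle planted geometries into a labeled trajectory.

    For each scheduled bit, the planted residue's atoms move between the
    engaged pose and a disengaged pose 40 Å further out along the planting
    direction, following a simulated two-state chain.  Returns the trajectory
    and the exact per-frame state series keyed by (residue label, bit).
    """
    targets: dict[str, tuple[tuple[str, int], np.ndarray, list[int]]] = {}
    used_residues: set[tuple[str, int]] = set()
    for bit in schedule.entries:
        if bit not in scene.planted_geometry:
            raise ValueError(f"scheduled bit {bit!r} is not planted in the scene")
        label, direction, idxs = scene.planted_geometry[bit]
        if label in used_residues:
            raise ValueError(f"conflicting schedules target residue {label}")
        used_residues.add(label)
        targets[bit] = (label, direction, idxs)

    rng = np.random.default_rng(schedule.seed)
    base = scene.structure.coords
    series: dict[tuple[tuple[str, int], str], np.ndarray] = {}
    chains: dict[str, np.ndarray] = {}
    for bit, (p01, p10) in sorted(schedule.entries.items()):
        label = targets[bit][0]
        chain = simulate_two_state_chain(p01, p10, schedule.n_frames, rng,
                                         schedule.start_state)
        chains[bit] = chain
        series[(label, bit)] = chain

    frames = []
    for f in range(schedule.n_frames):
        coords = base.copy()
        for bit, chain in chains.items():
            _, direction, idxs = targets[bit]
            if chain[f] == 0:
                coords[idxs] = coords[idxs] + direction * 40.0
        frames.append(coords)
    times = [(f + 1) * schedule.dt_ps for f in range(schedule.n_frames)]
    return Trajectory(scene.structure, frames, times), series


# ---------------------------------------------------------------------------
# Analytic pore structures
# ---------------------------------------------------------------------------

@dataclass
class PoreFixture:
    structure: Structure
    analytic_radius: Callable[[float], float]  # accessible radius at z (on-axis)
    analytic_min_radius: float
    z_values: np.ndarray
    vdw: float


def build_pore_structure(radius_fn: Callable[[float], float],
                         lining_density: float = 2.0,
                         vdw: float = 1.7,
                         z_range: tuple[float, float] = (-15.0, 15.0),
                         dz: float = 0.5,
                         seed: int = 0) -> PoreFixture:
    """Rings of pseudo-atoms whose accessible radius profile is known exactly.

    Atom centers sit at ``radius_fn(z) + vdw`` from the axis so the on-axis
    accessible radius at a ring plane is exactly ``radius_fn(z)``; between
    planes the analytic radius accounts for all neighboring rings.  A warning
    is raised when ``lining_density`` (atoms per Å of ring circumference) is
    too low for sub-0.05 Å in-plane discreteness.
    """
    rng = np.random.default_rng(seed)
    z_values = np.arange(z_range[0], z_range[1] + 1e-9, dz)
    ring_radii = np.array([radius_fn(z) + vdw for z in z_values])
    if np.any(ring_radii <= vdw):
        raise ValueError("radius_fn must be positive over z_range")
    if lining_density < 1.5:
        warnings.warn("lining density below 1.5 atoms/Å: in-plane discreteness "
                      "may exceed 0.05 Å")
    atoms: list[AtomRecord] = []
    serial = 1
    for resnum, (z, rr) in enumerate(zip(z_values, ring_radii), start=1):
        n = max(6, int(np.ceil(lining_density * 2 * np.pi * rr)))
        phase = rng.uniform(0, 2 * np.pi)
        ang = phase + 2 * np.pi * np.arange(n) / n
        for k in range(n):
            atoms.append(AtomRecord(
                serial=serial, name=f"C{k % 99}", element="C", residue_name="POR",
                residue_number=resnum, insertion_code="", chain_id="P", altloc="",
                coords=(float(rr * np.cos(ang[k])), float(rr * np.sin(ang[k])),
                        float(z)), is_hetero=True))
            serial += 1
    structure = Structure(atoms, identifier="pore_fixture")

    def analytic(z: float) -> float:
        d = np.sqrt(ring_radii ** 2 + (z_values - z) ** 2) - vdw
        return float(d.min())

    analytic_min = float(min(analytic(z) for z in z_values))
    return PoreFixture(structure=structure, analytic_radius=analytic,
                       analytic_min_radius=analytic_min, z_values=z_values,
                       vdw=vdw)
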