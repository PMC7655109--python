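"""Maximal-sphere pore-radius profiling along a channel axis.

At each axial position z, the largest sphere centered in the plane normal to
the axis is found: its radius is the minimum over atoms of (center-to-atom
distance minus the atom's van der Waals radius).  The in-plane center is
optimized with deterministic multi-start Nelder-Mead plus grid refinement
(rather than simulated annealing), warm-started from the previous plane so
consecutive centers track the pore lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from channelsift.structure import Structure, Trajectory, select, SelectionSpec

#: Bondi van der Waals radii (Å).
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "ZN": 1.39, "SE": 1.90,
}
DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class PoreConfig:
    """Profiler settings: radius table, cap, sweep step, optimizer tolerance."""

    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    vdw_set_name: str = "bondi"
    max_radius: float = 10.0
    step: float = 0.5
    xatol: float = 1e-4
    grid_refine: float = 0.05  # half-width of the final local grid refinement


@dataclass
class PoreProfile:
    """Ordered (z, in-plane center, maximal sphere radius) samples."""

    axis: np.ndarray  # unit 3-vector
    anchor: np.ndarray  # point on the axis (Å)
    z: np.ndarray  # Å along the axis, strictly increasing
    centers: np.ndarray  # (n, 2) in-plane centers, Å
    radii: np.ndarray  # Å
    unbounded: np.ndarray  # bool; True where the plane saw no atoms in reach
    vdw_set_name: str = "bondi"

    @property
    def min_radius(self) -> float:
        bounded = self.radii[~self.unbounded]
        if bounded.size == 0:
            raise ValueError("profile is unbounded everywhere")
        return float(bounded.min())

    @property
    def min_z(self) -> float:
        masked = np.where(self.unbounded, np.inf, self.radii)
        return float(self.z[int(np.argmin(masked))])

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "z": self.z, "center_x": self.centers[:, 0],
            "center_y": self.centers[:, 1], "radius": self.radii,
            "unbounded": self.unbounded,
        })


@dataclass
class PoreStatistics:
    """Per-z mean and sample standard deviation over frames."""

    z: np.ndarray
    mean_radius: np.ndarray
    sd_radius: np.ndarray
    n_frames: int

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"z": self.z, "mean_radius": self.mean_radius,
                             "sd_radius": self.sd_radius,
                             "n_frames": self.n_frames})


def principal_axis(structure: Structure,
                   selection: Optional[SelectionSpec] = None) -> tuple[np.ndarray, np.ndarray]:
    """(unit axis, anchor) from the principal inertia axis of Cα atoms.

    For a Cn-symmetric oligomer the symmetry axis is the covariance
    eigenvector whose eigenvalue is most separated from the other two (the
    in-plane pair is degenerate).  The anchor is the selection centroid.
    """
    if selection is None:
        selection = SelectionSpec.build(element_classes=["calpha"])
    idx = select(structure, selection)
    if len(idx) < 3:
        idx = [i for i, a in enumerate(structure.atoms) if a.element != "H"]
    pts = structure.coords[idx]
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)
    # pick eigenvalue farthest from the mean of the other two
    sep = [abs(evals[i] - np.mean(np.delete(evals, i))) for i in range(3)]
    axis = evecs[:, int(np.argmax(sep))]
    if axis[2] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), center


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _strip_atoms(structure: Structure) -> list[int]:
    """Protein heavy atoms only: waters, hetero ligands and ions removed."""
    from channelsift.structure import AMINO_ACIDS
    return [i for i, a in enumerate(structure.atoms)
            if a.residue_name in AMINO_ACIDS and a.element != "H"]


def pore_radius_at(coords: np.ndarray, vdw: np.ndarray, z: float,
                   axis: np.ndarray, anchor: np.ndarray,
                   prev_center: Sequence[float] = (0.0, 0.0),
                   config: PoreConfig = PoreConfig()) -> tuple[float, np.ndarray, bool]:
    """Largest sphere centered in the plane at z; returns (radius, center, unbounded).

    The objective maximized over the in-plane center c is
    ``min_i |p(c) - x_i| - vdw_i`` capped at ``max_radius``.  Optimization is
    a deterministic multi-start Nelder-Mead warm-started at ``prev_center``
    followed by a local grid refinement, so repeated runs are bit-identical.
    """
    axis = axis / np.linalg.norm(axis)
    u, v = _plane_basis(axis)
    base = anchor + z * axis

    # restrict to atoms that can bound a sphere of interest in this plane
    proj_z = (coords - anchor) @ axis
    near = np.abs(proj_z - z) <= (config.max_radius + vdw.max())
    pts = coords[near]
    rr = vdw[near]
    if pts.size == 0:
        return config.max_radius, np.asarray(prev_center, dtype=float), True

    def objective(c):
        p = base + c[0] * u + c[1] * v
        d = np.linalg.norm(pts - p, axis=1) - rr
        return -min(float(d.min()), config.max_radius)

    starts = [np.asarray(prev_center, dtype=float)]
    for dx, dy in ((1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)):
        starts.append(np.asarray(prev_center, dtype=float) + [dx, dy])
    best_c, best_f = None, np.inf
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"xatol": config.xatol, "fatol": 1e-8,
                                "maxiter": 400})
        if res.fun < best_f:
            best_f, best_c = res.fun, res.x
    # local grid refinement around the simplex optimum
    g = config.grid_refine
    offsets = np.linspace(-g, g, 5)
    for dx in offsets:
        for dy in offsets:
            c = best_c + np.array([dx, dy])
            f = objective(c)
            if f < best_f:
                best_f, best_c = f, c
    # final high-precision polish so the result is invariant (to ~1e-7)
    # under rigid transforms of the inputs
    res = minimize(objective, best_c, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 800})
    if res.fun <= best_f:
        best_f, best_c = res.fun, res.x
    radius = -best_f
    unbounded = radius >= config.max_radius
    return float(min(radius, config.max_radius)), best_c, unbounded


def pore_profile(structure: Structure,
                 axis: Optional[np.ndarray] = None,
                 anchor: Optional[np.ndarray] = None,
                 z_range: Optional[tuple[float, float]] = None,
                 config: PoreConfig = PoreConfig(),
                 coords: Optional[np.ndarray] = None,
                 atom_indices: Optional[Sequence[int]] = None) -> PoreProfile:
    """Sweep the maximal-sphere radius along the axis over z_range.

    Waters, hetero ligands and ions are stripped unless explicit
    ``atom_indices`` are given.  The sweep warm-starts the in-plane center in
    both directions from the midpoint so consecutive centers stay continuous.
    """
    if config.step <= 0:
        raise ValueError("step must be positive")
    if axis is None or anchor is None:
        ax, an = principal_axis(structure)
        axis = ax if axis is None else np.asarray(axis, dtype=float)
        anchor = an if anchor is None else np.asarray(anchor, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    anchor = np.asarray(anchor, dtype=float)
    if atom_indices is None:
        atom_indices = _strip_atoms(structure)
        if not atom_indices:  # synthetic pseudo-atom fixtures
            atom_indices = [i for i, a in enumerate(structure.atoms) if a.element != "H"]
    all_coords = structure.coords if coords is None else np.asarray(coords, dtype=float)
    pts = all_coords[list(atom_indices)]
    vdw = np.array([config.vdw_radii.get(structure.atoms[i].element.upper(), DEFAULT_VDW)
                    for i in atom_indices])
    if z_range is None:
        proj = (pts - anchor) @ axis
        z_range = (float(proj.min()), float(proj.max()))
    z_vals = np.arange(z_range[0], z_range[1] + 1e-9, config.step)

    mid = len(z_vals) // 2
    radii = np.zeros(len(z_vals))
    centers = np.zeros((len(z_vals), 2))
    unbounded = np.zeros(len(z_vals), dtype=bool)

    prev = np.zeros(2)
    for k in range(mid, len(z_vals)):
        r, c, ub = pore_radius_at(pts, vdw, z_vals[k], axis, anchor, prev, config)
        radii[k], centers[k], unbounded[k] = r, c, ub
        prev = c
    prev = centers[mid]
    for k in range(mid - 1, -1, -1):
        r, c, ub = pore_radius_at(pts, vdw, z_vals[k], axis, anchor, prev, config)
        radii[k], centers[k], unbounded[k] = r, c, ub
        prev = c
    return PoreProfile(axis=axis, anchor=anchor, z=z_vals, centers=centers,
                       radii=radii, unbounded=unbounded,
                       vdw_set_name=config.vdw_set_name)


def trajectory_profiles(traj: Trajectory, stride_ps: Optional[float] = None,
                        config: PoreConfig = PoreConfig(),
                        axis: Optional[np.ndarray] = None,
                        anchor: Optional[np.ndarray] = None,
                        z_range: Optional[tuple[float, float]] = None,
                        ) -> list[PoreProfile]:
    """One profile per sampled frame, on a common z grid."""
    frame_idx = traj.sample_indices(stride_ps)
    if axis is None or anchor is None:
        ax, an = principal_axis(traj.topology.with_coords(traj.frames[frame_idx[0]]))
        axis = ax if axis is None else axis
        anchor = an if anchor is None else anchor
    if z_range is None:
        idx = _strip_atoms(traj.topology)
        if not idx:
            idx = [i for i, a in enumerate(traj.topology.atoms) if a.element != "H"]
        proj = (traj.frames[frame_idx[0]][idx] - anchor) @ axis
        z_range = (float(proj.min()), float(proj.max()))
    return [pore_profile(traj.topology, axis=axis, anchor=anchor, z_range=z_range,
                         config=config, coords=traj.frames[k])
            for k in frame_idx]


def profile_statistics(profiles: Sequence[PoreProfile]) -> PoreStatistics:
    """Per-z mean and sample standard deviation across profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    z0 = profiles[0].z
    for p in profiles[1:]:
        if p.z.shape != z0.shape or not np.allclose(p.z, z0):
            raise ValueError("profiles are not on a common z grid")
    stack = np.vstack([p.radii for p in profiles])
    return PoreStatistics(z=z0, mean_radius=stack.mean(axis=0),
                          sd_radius=stack.std(axis=0, ddof=1),
                          n_frames=len(profiles))


def nearest_lining_residue(structure: Structure, profile: PoreProfile,
                           atom_indices: Optional[Sequence[int]] = None) -> tuple[str, int, str]:
    """(chain, residue number, residue name) closest to the constriction sphere."""
    if atom_indices is None:
        atom_indices = _strip_atoms(structure)
        if not atom_indices:
            atom_indices = list(range(len(structure.atoms)))
    k = int(np.argmin(np.where(profile.unbounded, np.inf, profile.radii)))
    u, v = _plane_basis(profile.axis)
    p = (profile.anchor + profile.z[k] * profile.axis
         + profile.centers[k, 0] * u + profile.centers[k, 1] * v)
    pts = structure.coords[list(atom_indices)]
    i = list(atom_indices)[int(np.argmin(np.linalg.norm(pts - p, axis=1)))]
    a = structure.atoms[i]
    return a.chain_id, a.residue_number, a.residue_name
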