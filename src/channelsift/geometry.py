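"""Primitive geometry: dihedrals, ring planes, Kabsch superposition, RMSD.

Dihedral signs follow the IUPAC convention (clockwise positive when viewed
along the second-to-third point axis); angles are degrees in (-180, 180].
Superposition uses unweighted Kabsch with the SVD reflection branch corrected
to a proper rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist


class DegenerateGeometryError(ValueError):
    """Raised for collinear/degenerate point configurations."""


@dataclass(frozen=True)
class RingGeometry:
    """Best-fit plane of an ordered atom ring."""

    member_indices: tuple[int, ...]
    centroid: np.ndarray
    unit_normal: np.ndarray


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-10:
        raise DegenerateGeometryError("central points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation superposition of mobile onto reference."""
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise ValueError("point counts differ")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    pm = mobile - cm
    pr = reference - cr
    if np.linalg.matrix_rank(pm, tol=1e-8) < 2 or np.linalg.matrix_rank(pr, tol=1e-8) < 2:
        raise DegenerateGeometryError("degenerate (collinear) configuration")
    h = pm.T @ pr
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = pm @ rot.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    translation = cr - rot @ cm
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("point counts differ")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_after_alignment(frame: np.ndarray, reference: np.ndarray,
                         align_idx: Sequence[int], measure_idx: Sequence[int]) -> float:
    """RMSD over measure_idx after fitting the transform on align_idx only.

    The measured set is deliberately not re-fit: the transform from the
    alignment atoms is applied to the whole frame before measuring.
    """
    frame = np.asarray(frame, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    measure_idx = list(measure_idx)
    if not measure_idx:
        raise ValueError("empty measure selection")
    align_idx = list(align_idx)
    sup = kabsch_superpose(frame[align_idx], reference[align_idx])
    moved = sup.apply(frame[measure_idx])
    return raw_rmsd(moved, reference[measure_idx])


def min_distance(set_a: np.ndarray, set_b: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Exact minimum distance over the Cartesian product, with achieving pair.

    Ties break deterministically to the lowest (i, j) in row-major order.
    """
    set_a = np.asarray(set_a, dtype=float).reshape(-1, 3)
    set_b = np.asarray(set_b, dtype=float).reshape(-1, 3)
    if set_a.size == 0 or set_b.size == 0:
        raise ValueError("empty coordinate set")
    d = cdist(set_a, set_b)
    flat = int(np.argmin(d))
    i, j = divmod(flat, d.shape[1])
    return float(d[i, j]), (int(i), int(j))


def ring_geometry(coords: np.ndarray, member_indices: Sequence[int]) -> RingGeometry:
    """Least-squares ring plane: centroid plus unit normal.

    The normal is the smallest-singular-value direction of the centered ring
    coordinates, with its sign fixed by the right-hand rule over the ordered
    member list.
    """
    member_indices = tuple(int(i) for i in member_indices)
    if len(member_indices) < 3:
        raise ValueError("ring needs at least 3 members")
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)[list(member_indices)]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:
        raise DegenerateGeometryError("collinear ring atoms")
    normal = vt[2]
    # right-hand orientation over the ordered member polygon
    winding = np.zeros(3)
    for k in range(len(centered)):
        winding += np.cross(centered[k], centered[(k + 1) % len(centered)])
    if np.dot(winding, normal) < 0:
        normal = -normal
    normal = normal / np.linalg.norm(normal)
    return RingGeometry(member_indices=member_indices, centroid=centroid,
                        unit_normal=normal)


def normal_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two plane normals folded into [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a-vertex-b in degrees."""
    v1 = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v2 = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
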