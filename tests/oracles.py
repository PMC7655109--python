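"""Independent brute-force oracles used by the tests.

Everything here re-derives criteria from raw coordinates with naive loops,
deliberately sharing no geometry code with the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
}
WATERS = {"HOH", "WAT", "TIP3", "SOL", "TIP", "SPC"}
POS_GROUPS = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"},
              "HIP": {"ND1", "NE2"}, "HSP": {"ND1", "NE2"}}
NEG_GROUPS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
RINGS = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
}


def dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def angle(p, vertex, q):
    v1 = [a - b for a, b in zip(p, vertex)]
    v2 = [a - b for a, b in zip(q, vertex)]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    c = sum(a * b for a, b in zip(v1, v2)) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def plane_normal(points):
    """Plane normal by explicit eigen-decomposition of the scatter matrix."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    m = (pts - c).T @ (pts - c)
    evals, evecs = np.linalg.eigh(m)
    return evecs[:, 0]


def dihedral_oracle(p1, p2, p3, p4):
    """Signed dihedral via projections onto the plane normal to the central bond."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1u, v), w))
    return math.degrees(math.atan2(y, x))


def kabsch_rmsd_oracle(mobile, reference):
    """Closed-form minimum RMSD from the SVD singular values."""
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    s = np.linalg.svd(h, compute_uv=False)
    if np.linalg.det(h) < 0:
        s[-1] = -s[-1]
    e0 = float(np.sum(pc ** 2) + np.sum(qc ** 2))
    msd = max(0.0, (e0 - 2.0 * float(np.sum(s))) / len(p))
    return math.sqrt(msd)


class BruteForceFingerprint:
    """Naive re-derivation of all nine interaction bits from coordinates."""

    def __init__(self, structure, ligand, config):
        self.s = structure
        self.ligand = ligand
        self.cfg = config
        self.coords = [tuple(a.coords) for a in structure.atoms]
        self.lig_idx = [i for i, a in enumerate(structure.atoms)
                        if a.residue_name == ligand.residue_name]
        self.lig_by_name = {structure.atoms[i].name: i for i in self.lig_idx}
        self.water_ox = [i for i, a in enumerate(structure.atoms)
                         if a.residue_name in WATERS and a.element == "O"]
        # hydrogens attached to heavy atoms (same residue, within 1.25 Å)
        self.hmap = {}
        hs = [i for i, a in enumerate(structure.atoms) if a.element == "H"]
        for h in hs:
            best, bd = None, 1.25
            for i, a in enumerate(structure.atoms):
                if a.element == "H":
                    continue
                d = dist(self.coords[h], self.coords[i])
                if d <= bd and a.residue_key == structure.atoms[h].residue_key:
                    best, bd = i, d
            if best is not None:
                self.hmap.setdefault(best, []).append(h)
        self.has_h = bool(self.hmap)

    def residue_groups(self):
        groups = {}
        for i, a in enumerate(self.s.atoms):
            if a.residue_name in AMINO:
                groups.setdefault((a.residue_name, a.residue_number, a.chain_id), []).append(i)
        return groups

    def hb(self, donor, acceptor):
        if dist(self.coords[donor], self.coords[acceptor]) > self.cfg.hbond_heavy_cutoff:
            return False
        hs = self.hmap.get(donor, [])
        if self.has_h and not hs:
            return False
        if not hs:
            return True
        return any(angle(self.coords[donor], self.coords[h], self.coords[acceptor])
                   >= self.cfg.hbond_angle_min for h in hs)

    def link(self, i, j):
        """Either-direction hydrogen-bond link (for water bridges)."""
        if dist(self.coords[i], self.coords[j]) > self.cfg.hbond_heavy_cutoff:
            return False
        hs = self.hmap.get(i, []) + self.hmap.get(j, [])
        if not hs:
            return True
        for h in self.hmap.get(i, []):
            if angle(self.coords[i], self.coords[h], self.coords[j]) >= self.cfg.hbond_angle_min:
                return True
        for h in self.hmap.get(j, []):
            if angle(self.coords[j], self.coords[h], self.coords[i]) >= self.cfg.hbond_angle_min:
                return True
        return False

    def bridges(self, lig_polar, res_polar):
        """Exhaustive enumeration of order-1 and order-2 water paths."""
        found = set()
        for lp in lig_polar:
            for w1 in self.water_ox:
                if not self.link(lp, w1):
                    continue
                for rp in res_polar:
                    if self.link(w1, rp):
                        found.add((1, (lp, w1, rp)))
                for w2 in self.water_ox:
                    if w2 == w1 or not self.link(w1, w2):
                        continue
                    for rp in res_polar:
                        if self.link(w2, rp):
                            found.add((2, (lp, w1, w2, rp)))
        return found

    def classify(self, residue_atoms):
        atoms = self.s.atoms
        bits = [False] * 9
        heavy = [i for i in residue_atoms if atoms[i].element != "H"]
        resname = atoms[heavy[0]].residue_name
        names = {atoms[i].name: i for i in heavy}

        # APOLAR
        for ln in self.ligand.nonpolar_atoms:
            for i in heavy:
                if atoms[i].element == "C" and dist(
                        self.coords[self.lig_by_name[ln]], self.coords[i]) <= self.cfg.apolar_cutoff:
                    bits[0] = True

        # aromatic
        for lig_ring in self.ligand.ring_groups:
            lpts = [self.coords[self.lig_by_name[n]] for n in lig_ring]
            for res_ring in RINGS.get(resname, []):
                if not all(n in names for n in res_ring):
                    continue
                rpts = [self.coords[names[n]] for n in res_ring]
                dmin = min(dist(p, q) for p in lpts for q in rpts)
                if dmin > self.cfg.aromatic_cutoff:
                    continue
                n1 = plane_normal(lpts)
                n2 = plane_normal(rpts)
                c = abs(float(np.dot(n1, n2)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, c))))
                if ang <= self.cfg.ftf_normal_angle_max:
                    bits[1] = True
                else:
                    bits[2] = True

        res_polar = [i for i in heavy if atoms[i].element in ("N", "O", "S")]
        # protein as donor
        for rp in res_polar:
            for ln in self.ligand.hbond_acceptors:
                if self.hb(rp, self.lig_by_name[ln]):
                    bits[3] = True
        # protein as acceptor
        for ln in self.ligand.hbond_donors:
            for rp in res_polar:
                if self.hb(self.lig_by_name[ln], rp):
                    bits[4] = True

        # electrostatics
        pos = [names[n] for n in POS_GROUPS.get(resname, ()) if n in names]
        for grp in self.ligand.negative_groups:
            for i in pos:
                for n in grp:
                    if dist(self.coords[i], self.coords[self.lig_by_name[n]]) <= self.cfg.electrostatic_cutoff:
                        bits[5] = True
        neg = [names[n] for n in NEG_GROUPS.get(resname, ()) if n in names]
        for grp in self.ligand.positive_groups:
            for i in neg:
                for n in grp:
                    if dist(self.coords[i], self.coords[self.lig_by_name[n]]) <= self.cfg.electrostatic_cutoff:
                        bits[6] = True

        # water bridges
        lig_polar = [self.lig_by_name[n] for n in
                     dict.fromkeys(list(self.ligand.hbond_donors) + list(self.ligand.hbond_acceptors))]
        for order, _ in self.bridges(lig_polar, res_polar):
            bits[7 if order == 1 else 8] = True
        return "".join("1" if b else "0" for b in bits)

    def all_residues(self):
        return {(rn, num): self.classify(idxs)
                for (rn, num, _ch), idxs in self.residue_groups().items()}


def pore_radius_grid_oracle(coords, vdw, z, grid_half=3.0, resolution=0.05,
                            max_radius=10.0):
    """Dense 2-D grid search for the maximal sphere in the plane at z.

    Assumes the axis is +z through the origin.
    """
    coords = np.asarray(coords, dtype=float)
    vdw = np.asarray(vdw, dtype=float)
    best = -np.inf
    for cx in np.arange(-grid_half, grid_half + 1e-9, resolution):
        for cy in np.arange(-grid_half, grid_half + 1e-9, resolution):
            p = np.array([cx, cy, z])
            r = float(np.min(np.linalg.norm(coords - p, axis=1) - vdw))
            best = max(best, min(r, max_radius))
    return best
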