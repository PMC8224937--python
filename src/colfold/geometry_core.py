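"""Superposition, RMSD, dihedral and contact primitives.

All coordinates are in Å. Rotations are proper (det = +1); dihedrals follow
the IUPAC sign convention with values in (-180, 180] degrees and a trans
peptide bond at 180°.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "kabsch_superpose",
    "rmsd",
    "dihedral",
    "phi_psi",
    "contact_pairs",
]


class DegenerateGeometryError(ValueError):
    """Raised when point sets are too small or degenerate for the operation."""


def _as_points(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"{name} must be an (N, 3) array, got shape {a.shape}")
    return a


def kabsch_superpose(mobile, reference):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    least-squares sense. The rotation is always proper (det = +1).

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or a rank-deficient (collinear/coincident)
        point cloud, where the rotation is not uniquely determined.
    """
    mob = _as_points(mobile, "mobile")
    ref = _as_points(reference, "reference")
    if mob.shape != ref.shape:
        raise ValueError(f"point counts differ: {mob.shape[0]} vs {ref.shape[0]}")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mob - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    # Rank 1 leaves rotation about the degenerate axis free.
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise DegenerateGeometryError("point cloud is rank-deficient (collinear)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = mob @ rot.T + trans
    value = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rot, trans, value


def rmsd(a, b, fit: bool = False) -> float:
    """Root-mean-square deviation between two equally sized point sets.

    With ``fit=True`` the RMSD is minimized over rigid motions (Kabsch);
    with ``fit=False`` it is evaluated in the current frame of reference.
    """
    pa = _as_points(a, "a")
    pb = _as_points(b, "b")
    if pa.shape != pb.shape:
        raise ValueError(f"point counts differ: {pa.shape[0]} vs {pb.shape[0]}")
    if fit:
        return kabsch_superpose(pa, pb)[2]
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle defined by four points, in degrees in (-180, 180].

    Sign follows the IUPAC convention: looking from p2 to p3, a clockwise
    rotation of p4 relative to p1 is positive. A planar trans (zig-zag)
    arrangement gives 180°, a planar cis arrangement 0°.
    """
    p = [np.asarray(x, dtype=float) for x in (p1, p2, p3, p4)]
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    for i, b in enumerate((b1, b2, b3)):
        if np.linalg.norm(b) < 1e-9:
            raise DegenerateGeometryError(f"consecutive points {i}, {i + 1} coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("three consecutive points are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = float(np.degrees(np.arctan2(-y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def phi_psi(model, chain: str, residue: int):
    """Backbone (φ, ψ) in degrees for one residue of a structure.

    φ = C(i−1)–N(i)–CA(i)–C(i); ψ = N(i)–CA(i)–C(i)–N(i+1). A dihedral that
    lacks its neighbour residue (φ at the N-terminus, ψ at the C-terminus)
    is returned as ``None`` rather than a silent 0.
    """

    def atom(res: int, name: str):
        try:
            return model.atom_coord(chain, res, name)
        except KeyError:
            return None

    n, ca, c = atom(residue, "N"), atom(residue, "CA"), atom(residue, "C")
    if n is None or ca is None or c is None:
        raise KeyError(f"residue {chain}{residue} lacks backbone atoms")
    c_prev = atom(residue - 1, "C")
    n_next = atom(residue + 1, "N")
    phi = dihedral(c_prev, n, ca, c) if c_prev is not None else None
    psi = dihedral(n, ca, c, n_next) if n_next is not None else None
    return phi, psi


def contact_pairs(
    model,
    cutoff: float = 4.0,
    heavy_only: bool = True,
    interchain_only: bool = True,
    exclude_residues=None,
):
    """Atom-index pairs in contact (distance ≤ ``cutoff`` Å).

    Returns a set of ``(i, j)`` tuples with ``i < j`` indexing into the
    model's atom table. By default only non-hydrogen atoms from different
    chains are considered. ``exclude_residues`` removes pairs in which both
    atoms belong to the given ``(chain, residue)`` set — used to drop the
    restrained C-terminal nucleus, whose contacts exist by construction.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = model.coords
    n = coords.shape[0]
    keep = np.ones(n, dtype=bool)
    if heavy_only:
        keep &= np.asarray(model.elements) != "H"
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return set()
    tree = cKDTree(coords[idx])
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    chains = np.asarray(model.chain_ids)
    out = set()
    excluded = set(exclude_residues) if exclude_residues else None
    residues = np.asarray(model.res_indices)
    for a, b in raw:
        i, j = int(idx[a]), int(idx[b])
        if interchain_only and chains[i] == chains[j]:
            continue
        if excluded is not None:
            if (chains[i], int(residues[i])) in excluded and (
                chains[j],
                int(residues[j]),
            ) in excluded:
                continue
        out.add((min(i, j), max(i, j)))
    return out
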