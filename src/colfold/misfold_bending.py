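"""Misfold detection (bulge loops, register shifts) and bending anisotropy.

A misfolded triple helix is locally native-like but wrongly registered:
either one chain has looped out a segment (always a multiple of three
residues, ending the repeat on a Gly) with in-register structure on both
sides, or whole chains are shifted along the helix by a multiple of the
repeat. Both are detected from a per-residue register assignment: each
residue's Cα is matched to the nearest reference helix slot of its own
chain, and the maximum-cardinality strictly increasing chain of matches
is kept (register must increase along the chain).

Bending is quantified by projecting the N-terminal half of the helix onto
the plane perpendicular to the C-terminal half's axis; anisotropic
(directional) bending shows up as a correlated, elongated point cloud
across frames, isotropic flexing as an uncorrelated ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .helix_model import StructureModel
from .propagation_analysis import nucleus_superpose
from .trajectory_io import Trajectory

__all__ = [
    "RegisterAssignment",
    "BendingSummary",
    "assign_register",
    "detect_bulge_loops",
    "detect_register_shift",
    "bending_projection",
    "bending_anisotropy_pvalue",
]


@dataclass
class RegisterAssignment:
    """Per-residue mapping of a frame onto reference helix slots.

    ``slots[chain][r-1]`` is the assigned slot of residue r or None;
    ``segments[chain]`` lists ``(start, end, offset)`` runs of contiguous
    assigned residues with constant offset ``slot − residue``.
    """

    slots: dict
    segments: dict = field(default_factory=dict)

    def offset(self, chain: str, residue: int):
        s = self.slots[chain][residue - 1]
        return None if s is None else s - residue


@dataclass
class BendingSummary:
    """Projected bending displacements and their anisotropy."""

    points: np.ndarray  # (F, 2) in Å
    std_x: float
    std_y: float
    pearson_r: float
    skipped_frames: list = field(default_factory=list)


def _longest_increasing(cands):
    """Indices of a maximum-cardinality strictly increasing subsequence of
    the non-None candidate values (O(n²) DP; earliest optimum on ties)."""
    n = len(cands)
    best = [0] * n
    prev = [-1] * n
    for i in range(n):
        if cands[i] is None:
            best[i] = 0
            continue
        best[i] = 1
        for j in range(i):
            if cands[j] is not None and cands[j] < cands[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    if not any(best):
        return []
    end = int(np.argmax(best))
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


def assign_register(
    frame: StructureModel,
    reference: StructureModel,
    capture_radius: float = 3.0,
    presuperposed: bool = False,
) -> RegisterAssignment:
    """Assign every residue of a frame to a reference helix slot (or none).

    The frame is nucleus-superposed onto the reference; each residue's Cα
    is matched to the nearest same-chain slot Cα within
    ``capture_radius`` Å, and the final assignment is the largest strictly
    increasing subsequence of those matches, so the register can only
    move forward along the chain.
    """
    if not presuperposed:
        traj = Trajectory(reference, frame.coords[None, :, :], dt=1.0)
        frame = reference.with_coords(nucleus_superpose(traj, reference)[0])
    slots = {}
    segments = {}
    n_res = int(reference.res_indices.max())
    for chain in reference.chains:
        ref_ca = np.array([reference.atom_coord(chain, r, "CA") for r in range(1, n_res + 1)])
        cands = []
        for r in range(1, n_res + 1):
            try:
                ca = frame.atom_coord(chain, r, "CA")
            except KeyError:
                cands.append(None)
                continue
            d = np.linalg.norm(ref_ca - ca, axis=1)
            j = int(np.argmin(d))
            cands.append(j + 1 if d[j] <= capture_radius else None)
        keep = set(_longest_increasing(cands))
        assigned = [cands[i] if i in keep else None for i in range(n_res)]
        slots[chain] = assigned
        segments[chain] = _offset_segments(assigned)
    return RegisterAssignment(slots=slots, segments=segments)


def _offset_segments(assigned):
    segs = []
    cur = None
    for i, s in enumerate(assigned):
        r = i + 1
        if s is None:
            if cur:
                segs.append(tuple(cur))
                cur = None
            continue
        off = s - r
        if cur and cur[2] == off and r == cur[1] + 1:
            cur[1] = r
        else:
            if cur:
                segs.append(tuple(cur))
            cur = [r, r, off]
    if cur:
        segs.append(tuple(cur))
    return segs


def detect_bulge_loops(assignment: RegisterAssignment):
    """Bulge loops: maximal unassigned runs flanked by assigned residues
    whose register offsets differ by exactly the run length.

    Returns a list of ``(chain, start_residue, length)``.
    """
    loops = []
    for chain, assigned in assignment.slots.items():
        n = len(assigned)
        r = 1
        while r <= n:
            if assigned[r - 1] is not None:
                r += 1
                continue
            start = r
            while r <= n and assigned[r - 1] is None:
                r += 1
            end = r - 1
            if start == 1 or end == n:
                continue  # terminal fray, not a flanked loop
            length = end - start + 1
            off_n = assigned[start - 2] - (start - 1)
            off_c = assigned[end] - (end + 1)
            if abs(off_n - off_c) == length:
                loops.append((chain, start, length))
    return loops


def detect_register_shift(assignment: RegisterAssignment, min_segment: int = 3):
    """Terminal register offset per chain (0 = native register).

    Scanning from the C-terminus, the offset of the first assigned
    segment of at least ``min_segment`` residues is reported — a shorter
    C-terminal stub (the two restrained nucleus residues stay in place
    even when the strand is shifted) does not define the register. Chains
    with no assigned segment at all report None.
    """
    out = {}
    for chain, segs in assignment.segments.items():
        if not segs:
            out[chain] = None
            continue
        offset = None
        for start, end, off in reversed(segs):
            if end - start + 1 >= min_segment:
                offset = off
                break
        if offset is None:
            longest = max(segs, key=lambda s: s[1] - s[0])
            offset = longest[2]
        out[chain] = offset
    return out


# ---------------------------------------------------------------------------
# Bending anisotropy
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O")


def _triplet_centroid(coords, reference, residue):
    idx = reference.select(residues=[residue], atoms=_BACKBONE)
    return coords[..., idx, :].mean(axis=-2)


def bending_projection(traj: Trajectory, reference: StructureModel) -> BendingSummary:
    """Project the N-terminal bending displacement of each frame onto the
    plane perpendicular to the C-terminal helix axis.

    Per frame: a = backbone centroid of the C-terminal triplet, c = of the
    middle triplet, b = of the N-terminal triplet. The axis u and the
    orthonormal in-plane basis {e1, e2} are fixed from the reference (the
    frames are nucleus-superposed), and the reported point is the in-plane
    component of (b − c) relative to the reference's own (b − c), so a
    straight native helix maps to (0, 0) exactly.
    """
    fitted = nucleus_superpose(traj, reference)
    n_res = int(reference.res_indices.max())
    mid = (n_res + 1) // 2
    a_ref = _triplet_centroid(reference.coords, reference, n_res)
    c_ref = _triplet_centroid(reference.coords, reference, mid)
    b_ref = _triplet_centroid(reference.coords, reference, 1)
    u = c_ref - a_ref
    u = u / np.linalg.norm(u)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ u) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    a = _triplet_centroid(fitted, reference, n_res)
    c = _triplet_centroid(fitted, reference, mid)
    b = _triplet_centroid(fitted, reference, 1)
    axis_len = np.linalg.norm(c - a, axis=1)
    ok = axis_len > 1e-6
    skipped = np.flatnonzero(~ok).tolist()
    v = (b - c) - (b_ref - c_ref)
    pts = np.stack([v @ e1, v @ e2], axis=1)[ok]
    if len(pts) >= 2 and pts[:, 0].std() > 0 and pts[:, 1].std() > 0:
        r = float(np.corrcoef(pts[:, 0], pts[:, 1])[0, 1])
    else:
        r = 0.0
    return BendingSummary(
        points=pts,
        std_x=float(pts[:, 0].std()) if len(pts) else 0.0,
        std_y=float(pts[:, 1].std()) if len(pts) else 0.0,
        pearson_r=r,
        skipped_frames=skipped,
    )


def bending_anisotropy_pvalue(summary: BendingSummary, n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for |Pearson r| of the projected cloud: the y
    coordinates are shuffled across frames to build the null."""
    pts = summary.points
    if len(pts) < 3:
        return 1.0
    rng = np.random.default_rng(seed)
    obs = abs(summary.pearson_r)
    x, y = pts[:, 0], pts[:, 1]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        r = np.corrcoef(x, perm)[0, 1]
        if abs(r) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
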