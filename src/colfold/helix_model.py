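"""Idealized collagen triple-helix reference builder and restraint arithmetic.

The reference structure is a (Gly-Pro-Pro)ₙ homotrimer built from internal
coordinates: one chain is grown residue by residue (NeRF) from per-class
backbone dihedrals, the exact per-triplet screw symmetry of that chain is
extracted and aligned with the z axis, and the two partner chains are
images of the first under a single inter-chain screw transform S applied
once and twice. S is the "cube root" of the per-triplet screw T (S³ = T),
so the three chains interdigitate with a one-residue axial stagger and all
residues sharing a residue number form a spatially close triplet.

The default dihedrals approximate a 7/2-symmetry collagen model helix;
they are a documented stand-in for a crystallographic reference, chosen
for geometric self-consistency (exact screw symmetry, inter-chain contacts
at every triplet), not as a claim about any particular crystal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry_core import kabsch_superpose

__all__ = [
    "ChainSequence",
    "HelixParameters",
    "StructureModel",
    "RestraintSpec",
    "build_reference_helix",
    "apply_mutation",
    "restraint_fluctuation_scale",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.987204259e-3

# Backbone covalent geometry (Å, degrees) — standard peptide values.
_BOND = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.530,
    ("CB", "OG1"): 1.430,
    ("CB", "CG2"): 1.521,
}
_ANGLE = {
    "N-CA-C": 111.0,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "N-CA-CB": 110.4,
    "CA-CB-OG1": 109.5,
    "CA-CB-CG2": 111.5,
}
# Improper torsion N-C-CA-CB fixing L-chirality of the Cβ branch.
_CB_IMPROPER = -122.55


class MutationError(ValueError):
    """Raised when a substitution targets a non-Gly position."""


@dataclass(frozen=True)
class ChainSequence:
    """Residue sequence of one strand, 3-letter codes, N→C order."""

    residues: tuple

    def __post_init__(self):
        if len(self.residues) % 3 != 0:
            raise ValueError("chain length must be a multiple of 3")

    @classmethod
    def gly_pro_pro(cls, n_repeats: int) -> "ChainSequence":
        if n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        return cls(tuple(["GLY", "PRO", "PRO"] * n_repeats))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HelixParameters:
    """Internal-coordinate parameters of the idealized triple helix.

    ``phi_psi`` maps the three residue classes of the Gly-X-Y repeat to
    backbone (φ, ψ) in degrees; ω is fixed all-trans at 180°. The
    inter-chain screw applies ``stagger`` residue steps of the per-residue
    screw plus a ``branch``·120° turn about the helix axis; the branch is
    the one of the three cube roots of the per-triplet screw that packs
    the chains into contact without steric overlap.
    """

    phi_psi: dict = field(
        default_factory=lambda: {
            "GLY": (-81.5, 174.0),
            "PRO_X": (-75.0, 172.5),
            "PRO_Y": (-59.5, 157.5),
        }
    )
    omega: float = 180.0
    stagger: int = 1
    branch: int = 1

    def residue_class(self, position: int) -> str:
        """Class of 1-based position ``position`` in the Gly-X-Y repeat."""
        m = position % 3
        return {1: "GLY", 2: "PRO_X", 0: "PRO_Y"}[m]


@dataclass
class StructureModel:
    """Atom-level model of the three-chain peptide (or one frame of it).

    Parallel arrays over atoms; chains are labelled A, B, C and residues
    are numbered 1-based from the N-terminus.
    """

    chain_ids: np.ndarray
    res_indices: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.res_indices = np.asarray(self.res_indices, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U4")
        self.atom_names = np.asarray(self.atom_names, dtype="U4")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        self._index = None

    # -- lookup ---------------------------------------------------------
    def _build_index(self):
        if self._index is None:
            self._index = {
                (c, int(r), a): i
                for i, (c, r, a) in enumerate(
                    zip(self.chain_ids, self.res_indices, self.atom_names)
                )
            }
        return self._index

    def atom_index(self, chain: str, residue: int, atom: str) -> int:
        try:
            return self._build_index()[(chain, residue, atom)]
        except KeyError:
            raise KeyError(f"no atom {atom} in residue {chain}{residue}") from None

    def atom_coord(self, chain: str, residue: int, atom: str) -> np.ndarray:
        return self.coords[self.atom_index(chain, residue, atom)]

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def chains(self):
        seen = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def n_residues_per_chain(self) -> int:
        c0 = self.chain_ids[0]
        return len(np.unique(self.res_indices[self.chain_ids == c0]))

    def mask(self, chain=None, residues=None, atoms=None, heavy_only=False):
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            chains = (chain,) if isinstance(chain, str) else tuple(chain)
            m &= np.isin(self.chain_ids, chains)
        if residues is not None:
            m &= np.isin(self.res_indices, np.asarray(list(residues)))
        if atoms is not None:
            m &= np.isin(self.atom_names, np.asarray(list(atoms)))
        if heavy_only:
            m &= self.elements != "H"
        return m

    def select(self, **kwargs) -> np.ndarray:
        """Indices of atoms matching the given chain/residue/atom filters."""
        return np.flatnonzero(self.mask(**kwargs))

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        out = StructureModel(
            self.chain_ids.copy(),
            self.res_indices.copy(),
            self.res_names.copy(),
            self.atom_names.copy(),
            self.elements.copy(),
            np.array(coords, dtype=float),
        )
        return out

    def copy(self) -> "StructureModel":
        return self.with_coords(self.coords.copy())


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic positional restraint on the Cα atoms of the C-terminal
    nucleus (last two residues of each chain)."""

    k: float = 0.5  # kcal·mol⁻¹·Å⁻²
    temperature: float = 310.0  # K
    restrained_residues: int = 2
    restrained_atom: str = "CA"

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("force constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def restraint_fluctuation_scale(spec: RestraintSpec):
    """Displacement x (Å) at which the restraint energy reaches RT.

    Uses the restraint convention E = k·x² (not ½k·x²), so
    x = sqrt(RT / k). Returns ``(x, rt)`` with RT in kcal·mol⁻¹.
    """
    rt = GAS_CONSTANT_KCAL * spec.temperature
    return float(np.sqrt(rt / spec.k)), float(rt)


# ---------------------------------------------------------------------------
# Internal-coordinate chain construction (NeRF)
# ---------------------------------------------------------------------------


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given reference atoms A, B, C and internal coordinates
    (|CD|, ∠BCD, torsion ABCD)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_single_chain(sequence: ChainSequence, params: HelixParameters):
    """Grow one chain N→C from per-class dihedrals.

    Returns (atom rows, coords) with atoms N, CA, C, O (+CB for non-Gly).
    """
    n_res = len(sequence)
    phi = np.empty(n_res)
    psi = np.empty(n_res)
    for i in range(n_res):
        cls = params.residue_class(i + 1)
        phi[i], psi[i] = params.phi_psi[cls]

    backbone = {}  # (res, name) -> coord
    # Seed residue 1: N at origin, CA on x, C in the xy plane.
    backbone[(1, "N")] = np.zeros(3)
    backbone[(1, "CA")] = np.array([_BOND[("N", "CA")], 0.0, 0.0])
    ang = np.radians(_ANGLE["N-CA-C"])
    backbone[(1, "C")] = backbone[(1, "CA")] + _BOND[("CA", "C")] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(2, n_res + 1):
        n_prev, ca_prev, c_prev = (
            backbone[(i - 1, "N")],
            backbone[(i - 1, "CA")],
            backbone[(i - 1, "C")],
        )
        n_i = _nerf(n_prev, ca_prev, c_prev, _BOND[("C", "N")], _ANGLE["CA-C-N"], psi[i - 2])
        ca_i = _nerf(ca_prev, c_prev, n_i, _BOND[("N", "CA")], _ANGLE["C-N-CA"], params.omega)
        c_i = _nerf(c_prev, n_i, ca_i, _BOND[("CA", "C")], _ANGLE["N-CA-C"], phi[i - 1])
        backbone[(i, "N")], backbone[(i, "CA")], backbone[(i, "C")] = n_i, ca_i, c_i

    rows = []
    coords = []
    for i in range(1, n_res + 1):
        res_name = sequence.residues[i - 1]
        n_i, ca_i, c_i = backbone[(i, "N")], backbone[(i, "CA")], backbone[(i, "C")]
        # Carbonyl O anti to the next amide N (torsion ψ+180 about CA-C).
        o_i = _nerf(n_i, ca_i, c_i, _BOND[("C", "O")], _ANGLE["CA-C-O"], psi[i - 1] + 180.0)
        for name, el, xyz in (("N", "N", n_i), ("CA", "C", ca_i), ("C", "C", c_i), ("O", "O", o_i)):
            rows.append((i, res_name, name, el))
            coords.append(xyz)
        if res_name != "GLY":
            cb = _nerf(n_i, c_i, ca_i, _BOND[("CA", "CB")], _ANGLE["N-CA-CB"], _CB_IMPROPER)
            rows.append((i, res_name, "CB", "C"))
            coords.append(cb)
            if res_name == "THR":
                og1 = _nerf(c_i, ca_i, cb, _BOND[("CB", "OG1")], _ANGLE["CA-CB-OG1"], -60.0)
                cg2 = _nerf(c_i, ca_i, cb, _BOND[("CB", "CG2")], _ANGLE["CA-CB-CG2"], -180.0)
                rows.append((i, res_name, "OG1", "O"))
                coords.append(og1)
                rows.append((i, res_name, "CG2", "C"))
                coords.append(cg2)
    return rows, np.array(coords)


def _screw_from_transform(rot: np.ndarray, trans: np.ndarray):
    """Decompose a rigid transform into screw axis, angle and axial rise.

    Returns (axis unit vector, point on axis, angle in radians, rise)."""
    w, v = np.linalg.eig(rot)
    axis = None
    for i in range(3):
        if abs(w[i] - 1.0) < 1e-8:
            axis = np.real(v[:, i])
    if axis is None:
        raise ValueError("transform has no rotation axis")
    axis /= np.linalg.norm(axis)
    cos_t = (np.trace(rot) - 1.0) / 2.0
    angle = float(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    # Fix the sign of the angle relative to the chosen axis direction.
    test = np.array([1.0, 0.0, 0.0])
    if abs(axis @ test) > 0.9:
        test = np.array([0.0, 1.0, 0.0])
    perp = test - (test @ axis) * axis
    perp /= np.linalg.norm(perp)
    if np.cross(perp, rot @ perp) @ axis < 0:
        angle = -angle
    rise = float(trans @ axis)
    # Point on the axis: solve (I - R) p = t_perp.
    t_perp = trans - rise * axis
    a_mat = np.eye(3) - rot
    point, *_ = np.linalg.lstsq(a_mat, t_perp, rcond=None)
    point -= (point @ axis) * axis
    return axis, point, angle, rise


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def single_chain_screw(sequence: ChainSequence, params: HelixParameters):
    """Build one chain, align its per-triplet screw axis with z.

    Returns (rows, aligned coords, triplet twist rad, triplet rise Å).
    The screw T maps the atoms of triplet k onto triplet k+1."""
    rows, coords = _build_single_chain(sequence, params)
    res_of = np.array([r[0] for r in rows])
    n_res = len(sequence)
    if n_res < 6:
        # Too short to measure the triplet screw from two full triplets;
        # extend virtually with the same dihedral pattern.
        ext_seq = ChainSequence.gly_pro_pro(3)
        ext_rows, ext_coords = _build_single_chain(ext_seq, params)
        m1 = np.array([r[0] in (1, 2, 3) for r in ext_rows])
        m2 = np.array([r[0] in (4, 5, 6) for r in ext_rows])
        rot, trans, _ = kabsch_superpose(ext_coords[m1], ext_coords[m2])
    else:
        m1 = np.isin(res_of, (1, 2, 3))
        m2 = np.isin(res_of, (4, 5, 6))
        rot, trans, _ = kabsch_superpose(coords[m1], coords[m2])
    axis, point, angle, rise = _screw_from_transform(rot, trans)
    # Orthonormal frame with the screw axis as +z (rise made positive).
    if rise < 0:
        axis, angle, rise = -axis, -angle, -rise
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    basis = np.stack([e1, e2, axis])  # world -> helix frame
    aligned = (coords - point) @ basis.T
    return rows, aligned, angle, rise


def _assemble_trimer(rows, chain_a_coords, angle, rise, params: HelixParameters):
    """Replicate the aligned chain with the inter-chain screw S, S²."""
    step = params.stagger
    alpha = angle * step / 3.0 + params.branch * 2.0 * np.pi / 3.0
    dz = rise * step / 3.0
    s_rot = _rot_z(alpha)

    chain_ids, res_idx, res_names, atom_names, elements, coords = [], [], [], [], [], []
    for c_i, chain in enumerate("ABC"):
        rot = np.linalg.matrix_power(s_rot, c_i)
        shift = np.array([0.0, 0.0, dz * c_i])
        xyz = chain_a_coords @ rot.T + shift
        for (ri, rn, an, el), p in zip(rows, xyz):
            chain_ids.append(chain)
            res_idx.append(ri)
            res_names.append(rn)
            atom_names.append(an)
            elements.append(el)
            coords.append(p)
    return StructureModel(
        np.array(chain_ids),
        np.array(res_idx),
        np.array(res_names),
        np.array(atom_names),
        np.array(elements),
        np.array(coords),
    )


def interchain_screw(params: HelixParameters, angle: float, rise: float):
    """The single inter-chain screw S (rotation matrix, z-shift) whose
    0/1/2-fold application generates chains A, B, C."""
    alpha = angle * params.stagger / 3.0 + params.branch * 2.0 * np.pi / 3.0
    return _rot_z(alpha), rise * params.stagger / 3.0


def build_reference_helix(
    n_repeats: int,
    mutations=None,
    params: HelixParameters | None = None,
) -> StructureModel:
    """Build the idealized (Gly-Pro-Pro)ₙ triple-helix reference.

    ``mutations`` is an iterable of ``(chain, residue_position, new_residue)``
    with residue codes ALA or THR; only Gly positions may be substituted.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    params = params or HelixParameters()
    seq = ChainSequence.gly_pro_pro(n_repeats)
    rows, aligned, angle, rise = single_chain_screw(seq, params)
    model = _assemble_trimer(rows, aligned, angle, rise, params)
    if mutations:
        for chain, pos, new in mutations:
            model = apply_mutation(model, chain, pos, new)
    return model


def apply_mutation(model: StructureModel, chain, position: int, residue: str) -> StructureModel:
    """Substitute a Gly by Ala or Thr, keeping the backbone fixed.

    ``chain`` may be a single chain id or an iterable of ids ("ABC" mutates
    every strand). The Cβ (and Thr Oγ1/Cγ2 stubs) are placed by ideal
    tetrahedral geometry off the existing backbone.
    """
    residue = residue.upper()
    if residue not in ("ALA", "THR"):
        raise MutationError(f"unsupported substitution {residue!r}; use ALA or THR")
    chains = [chain] if isinstance(chain, str) and len(chain) == 1 else list(chain)

    out = model.copy()
    for ch in chains:
        sel = out.select(chain=ch, residues=[position])
        if sel.size == 0:
            raise MutationError(f"no residue {position} in chain {ch}")
        current = out.res_names[sel[0]]
        if current != "GLY":
            raise MutationError(
                f"cannot mutate {ch}{position}: residue is {current}, not GLY"
            )
        n_i = out.atom_coord(ch, position, "N")
        ca_i = out.atom_coord(ch, position, "CA")
        c_i = out.atom_coord(ch, position, "C")
        cb = _nerf(n_i, c_i, ca_i, _BOND[("CA", "CB")], _ANGLE["N-CA-CB"], _CB_IMPROPER)
        new_rows = [("CB", "C", cb)]
        if residue == "THR":
            og1 = _nerf(c_i, ca_i, cb, _BOND[("CB", "OG1")], _ANGLE["CA-CB-OG1"], -60.0)
            cg2 = _nerf(c_i, ca_i, cb, _BOND[("CB", "CG2")], _ANGLE["CA-CB-CG2"], -180.0)
            new_rows += [("OG1", "O", og1), ("CG2", "C", cg2)]
        out.res_names[sel] = residue
        insert_at = sel[-1] + 1
        out = StructureModel(
            np.insert(out.chain_ids, insert_at, [ch] * len(new_rows)),
            np.insert(out.res_indices, insert_at, [position] * len(new_rows)),
            np.insert(out.res_names, insert_at, [residue] * len(new_rows)),
            np.insert(out.atom_names, insert_at, [r[0] for r in new_rows]),
            np.insert(out.elements, insert_at, [r[1] for r in new_rows]),
            np.insert(out.coords, insert_at, np.array([r[2] for r in new_rows]), axis=0),
        )
    return out


def mutation_label(mutations) -> str:
    """Construct-style label, e.g. [("A", 7, "ALA")] -> "G7aA",
    three-chain Ala at 7 -> "G7abcA"."""
    if not mutations:
        return "WT"
    by_code = {}
    for chain, pos, new in mutations:
        by_code.setdefault((pos, new[0]), []).append(chain.lower())
    parts = []
    for (pos, letter), chains in sorted(by_code.items()):
        parts.append(f"G{pos}{''.join(sorted(chains))}{letter}")
    return "+".join(parts)
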