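"""Folding-propagation statistics on triple-helix trajectories.

All per-triplet and probe RMSDs share one superposition convention: each
frame is rigidly fitted onto the reference using the backbone atoms of the
C-terminal nucleus (the last two residues of every chain) — the restrained,
always-native anchor — and triplet RMSDs are then evaluated without
refitting, so they measure displacement relative to the growing helix.
A "triplet" is the set of residues sharing one residue number across the
three chains; a "unit" is one Gly-X-Y repeat (three consecutive triplets),
the elementary step of zipper propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry_core import phi_psi, rmsd, contact_pairs
from .helix_model import StructureModel
from .trajectory_io import ScalarSeries, Trajectory

__all__ = [
    "TripletRmsdProfile",
    "FoldingReport",
    "nucleus_superpose",
    "triplet_rmsd_profile",
    "native_contact_fraction",
    "folding_time",
    "dihedral_state",
    "triplet_fold_state",
    "propagation_times",
    "outcome_classify",
    "gaussian_smooth",
    "endpoint_delta",
    "outcome_table",
    "tabulate_outcomes",
]

#: Sliding-window length (frames) of the folding-time detector.
DEFAULT_WINDOW = 50
#: RMSD threshold (Å) under which a window mean counts as folded.
DEFAULT_THRESHOLD = 1.0
#: Residue number probed for the folding time (the third triplet is
#: preferred over the first to avoid end fraying).
DEFAULT_PROBE_RESIDUE = 4


@dataclass
class TripletRmsdProfile:
    """(L triplets × F frames) matrix of triplet RMSDs vs. the reference."""

    values: np.ndarray  # (L, F), Å
    times: np.ndarray  # (F,), ps
    dt: float

    @property
    def n_triplets(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def triplet(self, t: int) -> ScalarSeries:
        """Series of one triplet (1-based index, 1 = N-terminal)."""
        if not 1 <= t <= self.n_triplets:
            raise IndexError(f"triplet {t} out of range 1..{self.n_triplets}")
        return ScalarSeries(
            self.values[t - 1],
            dt=self.dt,
            t0=float(self.times[0]) if len(self.times) else 0.0,
            units="A",
            name=f"triplet_{t}",
        )


@dataclass
class FoldingReport:
    """Outcome classification of one trajectory."""

    outcome: str  # FOLDED / PARTIAL / TRANSIENT / UNFOLDED
    folding_time: float | None  # ps
    final_rmsd: float  # Å, whole-molecule heavy-atom fitted, last frame
    unit_times: dict = field(default_factory=dict)  # unit -> completion ps
    mean_unit_time: float | None = None  # ps

    def as_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "folding_time_ns": None if self.folding_time is None else self.folding_time / 1000.0,
            "final_rmsd_A": self.final_rmsd,
            "mean_unit_time_ns": None
            if self.mean_unit_time is None
            else self.mean_unit_time / 1000.0,
        }


# ---------------------------------------------------------------------------
# Superposition helpers
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O")


def _nucleus_indices(reference: StructureModel):
    n_res = int(reference.res_indices.max())
    return reference.select(residues=[n_res - 1, n_res], atoms=_BACKBONE)


def nucleus_superpose(traj: Trajectory, reference: StructureModel) -> np.ndarray:
    """Superpose every frame onto the reference via the nucleus backbone.

    Returns the full coordinate array (F, N, 3) in the reference frame.
    Uses a batched Kabsch fit over the backbone atoms of the last two
    residues of each chain."""
    _check_topology(traj.topology, reference)
    idx = _nucleus_indices(reference)
    mob = traj.coords[:, idx, :]  # (F, n, 3)
    ref = reference.coords[idx]  # (n, 3)
    mc = mob.mean(axis=1, keepdims=True)
    rc = ref.mean(axis=0)
    h = np.einsum("fni,nj->fij", mob - mc, ref - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(vt, (0, 2, 1)), np.transpose(u, (0, 2, 1)))))
    flip = np.repeat(np.eye(3)[None], len(d), axis=0)
    flip[:, 2, 2] = d
    rot = np.einsum("fij,fjk,fkl->fil", np.transpose(vt, (0, 2, 1)), flip, np.transpose(u, (0, 2, 1)))
    trans = rc - np.einsum("fij,fj->fi", rot, mc[:, 0, :])
    return np.einsum("fij,fnj->fni", rot, traj.coords) + trans[:, None, :]


def _check_topology(topology: StructureModel, reference: StructureModel):
    if topology.n_atoms != reference.n_atoms or not (
        np.array_equal(topology.atom_names, reference.atom_names)
        and np.array_equal(topology.chain_ids, reference.chain_ids)
        and np.array_equal(topology.res_indices, reference.res_indices)
    ):
        raise ValueError("trajectory topology does not match the reference")


# ---------------------------------------------------------------------------
# Per-triplet RMSD course
# ---------------------------------------------------------------------------


def triplet_rmsd_profile(traj: Trajectory, reference: StructureModel) -> TripletRmsdProfile:
    """Heavy-atom RMSD of every residue triplet vs. the reference, per frame.

    Frames are first nucleus-superposed; each triplet's RMSD is evaluated
    in that common frame without refitting, so unfolded triplets far from
    their native slots read large."""
    fitted = nucleus_superpose(traj, reference)
    n_res = int(reference.res_indices.max())
    values = np.empty((n_res, traj.n_frames))
    for t in range(1, n_res + 1):
        idx = reference.select(residues=[t], heavy_only=True)
        diff = fitted[:, idx, :] - reference.coords[idx]
        values[t - 1] = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    return TripletRmsdProfile(values, traj.times, traj.dt)


def probe_rmsd_series(
    traj: Trajectory, reference: StructureModel, probe_residue: int = DEFAULT_PROBE_RESIDUE
) -> ScalarSeries:
    """Per-frame RMSD of the probe triplet after nucleus superposition."""
    fitted = nucleus_superpose(traj, reference)
    idx = reference.select(residues=[probe_residue], heavy_only=True)
    diff = fitted[:, idx, :] - reference.coords[idx]
    vals = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    return ScalarSeries(vals, dt=traj.dt, t0=traj.t0, units="A", name=f"triplet_{probe_residue}")


# ---------------------------------------------------------------------------
# Native contacts
# ---------------------------------------------------------------------------


def native_contact_fraction(
    traj: Trajectory,
    reference: StructureModel,
    cutoff: float = 4.0,
    exclude_nucleus: bool = True,
    tolerance_factor: float = 1.0,
):
    """Fraction (and count) of reference contacts formed in each frame.

    The reference contact set is the inter-chain heavy-atom pairs within
    ``cutoff`` Å of the reference structure, excluding pairs lying
    entirely inside the restrained nucleus (configurable) since those are
    formed by construction. A frame forms a contact when that pair's
    distance is ≤ cutoff × tolerance_factor.
    """
    _check_topology(traj.topology, reference)
    exclude = None
    if exclude_nucleus:
        n_res = int(reference.res_indices.max())
        exclude = {(c, r) for c in reference.chains for r in (n_res - 1, n_res)}
    pairs = contact_pairs(reference, cutoff=cutoff, exclude_residues=exclude)
    if not pairs:
        raise ValueError(
            "reference contact set is empty; review the cutoff and the "
            "nucleus exclusion (the reference may not be a folded helix)"
        )
    arr = np.array(sorted(pairs))
    d = np.linalg.norm(traj.coords[:, arr[:, 0], :] - traj.coords[:, arr[:, 1], :], axis=2)
    formed = (d <= cutoff * tolerance_factor).sum(axis=1)
    frac = formed / len(pairs)
    series = ScalarSeries(frac, dt=traj.dt, t0=traj.t0, units="fraction", name="native_contacts")
    return series, formed


# ---------------------------------------------------------------------------
# Folding time
# ---------------------------------------------------------------------------


def window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Mean of every contiguous window; index i = window starting at i."""
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def folding_time(
    obj,
    reference: StructureModel | None = None,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    probe_residue: int = DEFAULT_PROBE_RESIDUE,
):
    """First time a sliding window of the probe RMSD has mean < threshold.

    ``obj`` may be a Trajectory (with ``reference``), a TripletRmsdProfile
    or a ScalarSeries. A window of ``window`` frames (2.5 ns at 50 ps
    spacing) is shifted through the probe series — the RMSD of the three
    residues numbered ``probe_residue`` — and the time of the first frame
    of the first window whose mean is below ``threshold`` is returned, or
    None when no window qualifies.
    """
    series = _resolve_probe(obj, reference, probe_residue)
    n = len(series)
    if n < window:
        raise ValueError(f"trajectory has {n} frames, shorter than the {window}-frame window")
    means = window_means(series.values, window)
    below = np.flatnonzero(means < threshold)
    if below.size == 0:
        return None
    return float(series.t0 + series.dt * below[0])


def _resolve_probe(obj, reference, probe_residue) -> ScalarSeries:
    if isinstance(obj, ScalarSeries):
        return obj
    if isinstance(obj, TripletRmsdProfile):
        return obj.triplet(probe_residue)
    if isinstance(obj, Trajectory):
        if reference is None:
            raise ValueError("a reference structure is required with a Trajectory")
        return probe_rmsd_series(obj, reference, probe_residue)
    raise TypeError(f"cannot derive a probe series from {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Dihedral / template states
# ---------------------------------------------------------------------------


def circular_difference(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def gly_positions(reference: StructureModel):
    """Repeat-anchor positions (1, 4, 7, ...) of the Gly-X-Y pattern."""
    n_res = int(reference.res_indices.max())
    return list(range(1, n_res + 1, 3))


def dihedral_state(
    frame: StructureModel,
    reference: StructureModel,
    tolerance: float = 30.0,
):
    """Native/non-native call of the flexible dihedral pair per chain and
    repeat anchor: φ of the Gly position and ψ of the preceding residue.

    Returns ``(states, skipped)``: ``states[(chain, pos)]`` is True when
    both angles lie within ±tolerance (circular) of the reference values;
    positions whose dihedrals are undefined (chain termini) are listed in
    ``skipped`` instead of being silently classified.
    """
    states = {}
    skipped = []
    for chain in reference.chains:
        for pos in gly_positions(reference):
            try:
                phi_f, _ = phi_psi(frame, chain, pos)
                phi_r, _ = phi_psi(reference, chain, pos)
            except KeyError:
                skipped.append((chain, pos))
                continue
            if pos == 1:
                skipped.append((chain, pos))
                continue
            _, psi_f = phi_psi(frame, chain, pos - 1)
            _, psi_r = phi_psi(reference, chain, pos - 1)
            if phi_f is None or psi_f is None or phi_r is None or psi_r is None:
                skipped.append((chain, pos))
                continue
            states[(chain, pos)] = bool(
                circular_difference(phi_f, phi_r) <= tolerance
                and circular_difference(psi_f, psi_r) <= tolerance
            )
    return states, skipped


def triplet_fold_state(
    frame: StructureModel,
    reference: StructureModel,
    triplet: int,
    tolerance: float = 30.0,
    position_cutoff: float = 1.5,
    presuperposed: bool = False,
):
    """UNFOLDED / TEMPLATE / FOLDED call of one triplet.

    A chain's residue counts as native when the hinge dihedral pair at
    the C-terminal edge of its unit — φ of the next unit's Gly and ψ of
    the preceding Pro, the pair that flips when the unit folds onto the
    already-helical C-terminal side — is native (where defined), and the
    residue's heavy atoms lie within ``position_cutoff`` Å RMSD of the
    reference after nucleus superposition. FOLDED requires all three
    chains native, TEMPLATE exactly two (the two-chain template
    intermediate), anything less is UNFOLDED.
    """
    n_res = int(reference.res_indices.max())
    if not 1 <= triplet <= n_res:
        raise IndexError(f"triplet {triplet} out of range 1..{n_res}")
    if not presuperposed:
        traj = Trajectory(reference, frame.coords[None, :, :], dt=1.0)
        frame = reference.with_coords(nucleus_superpose(traj, reference)[0])
    anchor = 3 * ((triplet + 2) // 3) + 1  # Gly of the next unit C-ward
    dih, _ = dihedral_state(frame, reference, tolerance)
    native = 0
    for chain in reference.chains:
        idx = reference.select(chain=chain, residues=[triplet], heavy_only=True)
        pos_ok = (
            rmsd(frame.coords[idx], reference.coords[idx], fit=False) < position_cutoff
        )
        key = (chain, anchor)
        dih_ok = dih.get(key, True)  # undefined terminal dihedrals: position rules
        if pos_ok and dih_ok:
            native += 1
    if native == 3:
        return "FOLDED"
    if native == 2:
        return "TEMPLATE"
    return "UNFOLDED"


# ---------------------------------------------------------------------------
# Per-unit propagation times and outcome classification
# ---------------------------------------------------------------------------


def propagation_times(
    traj: Trajectory,
    reference: StructureModel,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Completion time of every repeat unit and the mean per-unit time.

    A unit's completion time is the folding time of its repeat-anchor
    (Gly-position) triplet under the same window/threshold detector. The
    mean per-unit propagation time is the mean of successive differences
    between completion times of completed units, taken in C→N order;
    never-completed units are ignored. Returns ``(unit_times, mean)``
    where ``unit_times`` maps unit index (1 = N-terminal) to ps or None.
    """
    profile = triplet_rmsd_profile(traj, reference)
    n_units = profile.n_triplets // 3
    unit_times = {}
    for k in range(1, n_units + 1):
        anchor = 3 * k - 2
        unit_times[k] = folding_time(
            profile, window=window, threshold=threshold, probe_residue=anchor
        )
    completed = [unit_times[k] for k in range(n_units, 0, -1) if unit_times[k] is not None]
    if len(completed) < 2:
        mean = 0.0 if len(completed) == 1 else None
    else:
        mean = float(np.mean(np.diff(completed)))
    return unit_times, mean


def outcome_classify(
    traj: Trajectory,
    reference: StructureModel,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    probe_residue: int = DEFAULT_PROBE_RESIDUE,
    partial_min_units: int = 2,
) -> FoldingReport:
    """Classify a trajectory as FOLDED, TRANSIENT, PARTIAL or UNFOLDED.

    FOLDED: a folding time exists and the final window of the probe RMSD
    is still below threshold. TRANSIENT: a folding time exists but the
    final window fails (folded, then unfolded again). PARTIAL: no folding
    time, but a contiguous C-terminal block of at least
    ``partial_min_units`` units beyond the nucleus is folded in the final
    window. Otherwise UNFOLDED. ``final_rmsd`` is the whole-molecule
    heavy-atom fitted RMSD of the last frame.
    """
    profile = triplet_rmsd_profile(traj, reference)
    ft = folding_time(profile, window=window, threshold=threshold, probe_residue=probe_residue)
    probe = profile.triplet(probe_residue).values
    if len(probe) < window:
        raise ValueError("trajectory shorter than the detection window")
    final_ok = float(np.mean(probe[-window:])) < threshold

    unit_times, mean_unit = propagation_times(traj, reference, window, threshold)
    n_units = profile.n_triplets // 3

    heavy = reference.select(heavy_only=True)
    final_rmsd = rmsd(traj.coords[-1][heavy], reference.coords[heavy], fit=True)

    if ft is not None and final_ok:
        outcome = "FOLDED"
    elif ft is not None:
        outcome = "TRANSIENT"
    else:
        # contiguous folded block from the C-terminal unit inward
        stable = 0
        for k in range(n_units, 0, -1):
            anchor = 3 * k - 2
            if float(np.mean(profile.values[anchor - 1, -window:])) < threshold:
                stable += 1
            else:
                break
        outcome = "PARTIAL" if stable >= partial_min_units else "UNFOLDED"
    if outcome not in ("FOLDED", "TRANSIENT"):
        ft = None
    return FoldingReport(
        outcome=outcome,
        folding_time=ft,
        final_rmsd=final_rmsd,
        unit_times=unit_times,
        mean_unit_time=mean_unit,
    )


# ---------------------------------------------------------------------------
# Scalar-series bookkeeping (energy-style time courses)
# ---------------------------------------------------------------------------


def gaussian_smooth(series: ScalarSeries, sigma: float = 25.0) -> ScalarSeries:
    """Gaussian filter with σ in frames, truncated at ±4σ and renormalized
    at the edges so constants pass through unchanged."""
    if len(series) < 1:
        raise ValueError("series is empty")
    half = int(np.ceil(4 * sigma))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    num = np.convolve(series.values, kernel, mode="same")
    den = np.convolve(np.ones_like(series.values), kernel, mode="same")
    return ScalarSeries(num / den, dt=series.dt, t0=series.t0, units=series.units, name=series.name)


def endpoint_delta(series: ScalarSeries, n: int = 20) -> float:
    """mean(last n frames) − mean(first n frames)."""
    if len(series) < 2 * n:
        raise ValueError(f"series of length {len(series)} is shorter than 2n = {2 * n}")
    v = series.values
    return float(np.mean(v[-n:]) - np.mean(v[:n]))


# ---------------------------------------------------------------------------
# Multi-run tabulation
# ---------------------------------------------------------------------------


def outcome_table(reports, labels=None) -> pd.DataFrame:
    """Per-run table (final RMSD Å, folding time ns, outcome) from
    FoldingReports; ``labels`` optionally names the runs/constructs."""
    rows = []
    for i, rep in enumerate(reports):
        row = {"run": i + 1}
        if labels is not None:
            row["construct"] = labels[i]
        row.update(rep.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def tabulate_outcomes(
    table: pd.DataFrame,
    rmsd_correct_max: float = 2.0,
    group: str = "construct",
) -> pd.DataFrame:
    """Bookkeeping summary of many runs, grouped by construct.

    ``table`` needs columns ``final_rmsd_A`` and ``folding_time_ns``
    (NaN/None when the run never completed). Reports, per construct:
    ``n_runs``, ``n_completed`` (a completion time exists),
    ``n_correct`` (completed and final RMSD < ``rmsd_correct_max`` Å —
    folds that also reached the native structure), and the mean
    completion time of the completed runs.
    """
    out = []
    for name, sub in table.groupby(group, sort=False):
        completed = sub["folding_time_ns"].notna()
        correct = completed & (sub["final_rmsd_A"] < rmsd_correct_max)
        times = sub.loc[completed, "folding_time_ns"]
        out.append(
            {
                group: name,
                "n_runs": len(sub),
                "n_completed": int(completed.sum()),
                "n_correct": int(correct.sum()),
                "mean_folding_time_ns": float(times.mean()) if len(times) else np.nan,
            }
        )
    return pd.DataFrame(out)
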