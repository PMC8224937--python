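"""Stochastic zipper-model generator of synthetic folding trajectories.

The generator emulates the phenomenology of collagen triple-helix folding
propagation as observed in MD: starting from a restrained C-terminal
nucleus, the folding front advances one Gly-Pro-Pro unit at a time toward
the N-terminus. Each propagation step first forms a transient two-chain
"template" after an exponential waiting time; the template either decays
(and the step is retried) or the third chain locks onto it after a second
exponential waiting time, extending the helix by one unit. Folded units
never fray. Optional misfold modes reproduce the characteristic defects:
bulge loops of one chain (always a multiple of three residues) and
inter-chain register shifts (likewise multiples of three), plus collapse
of the folded state for triple-mutant emulation and nucleus-disruption
events for weak-restraint emulation.

This is a phenomenological stand-in for MD — no forces, solvent or
temperatures — that renders coordinate frames on the ideal reference
helix with Gaussian noise, so every downstream analysis can be validated
against the generator's exact event log.

Default kinetic parameters are calibrated so the expected time per
completed unit is 75 ns (2 expected template attempts x 25 ns waiting
+ 1 expected reverted-template lifetime of 12.5 ns + 12.5 ns locking),
matching the mean propagation rate the analyses are designed to recover.
All times are picoseconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .geometry_core import kabsch_superpose
from .helix_model import HelixParameters, StructureModel, build_reference_helix
from .trajectory_io import Trajectory

__all__ = [
    "ZipperConfig",
    "EventLog",
    "UnitRecord",
    "MisfoldRecord",
    "SlotAtlas",
    "FrameState",
    "simulate",
    "render_frame",
    "UNFOLDED",
    "TEMPLATE",
    "FOLDED",
    "LOOPED_OUT",
]

# Residue state codes.
UNFOLDED = "U"
TEMPLATE = "T"
FOLDED = "F"
LOOPED_OUT = "L"

_CHAINS = ("A", "B", "C")


@dataclass(frozen=True)
class ZipperConfig:
    """Parameters of the synthetic zipper simulation (times in ps)."""

    n_repeats: int = 5
    dt: float = 50.0
    total_time: float = 1_000_000.0  # 1 us
    tau_template: float = 25_000.0  # mean wait per template attempt
    p_revert: float = 0.5  # template decays before locking
    tau_revert: float = 12_500.0  # lifetime of a reverted template
    tau_lock: float = 12_500.0  # mean wait for third-chain locking
    p_loop: float = 0.0
    loop_lengths: tuple = (3, 6, 9)
    loop_weights: tuple = (0.6, 0.3, 0.1)
    p_shift: float = 0.0
    shift_values: tuple = (-3, -6)
    shift_weights: tuple = (0.7, 0.3)
    mutation_sites: tuple = ()  # ((chain, residue), ...)
    mutation_residue: str = "ALA"
    barrier_factor: float = 1.0
    unfold_rate: float = 0.0  # per-ps collapse rate of the folded state
    # Folded-state noise of total per-coordinate width sigma_folded (A),
    # split into a displacement field smoothed along the chain (collective
    # motion) plus a small independent per-atom jitter, so positional
    # fluctuations are MD-like without scrambling backbone dihedrals.
    sigma_folded: float = 0.3
    jitter_fraction: float = 0.15  # per-atom share of sigma_folded
    field_smoothing: float = 1.5  # residues, width of the collective field
    # The restrained nucleus anchors every downstream superposition; its
    # atoms are rendered at a fraction of sigma_folded so anchor jitter
    # does not project a lever-arm error onto distal triplets.
    nucleus_noise_factor: float = 1.0 / 3.0
    excursion_scale: float = 3.8  # A, CA step of the unfolded random walk
    nucleus_stability: str = "stable"  # or "weak"
    nucleus_disrupt_rate: float = 5.0e-6  # per ps, weak mode only
    shift_on_disrupt: float = 0.5  # prob. a disruption seeds a register shift
    seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.dt <= 0 or self.total_time <= 0:
            raise ValueError("dt and total_time must be positive")
        for name in ("tau_template", "tau_revert", "tau_lock"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_revert", "p_loop", "p_shift", "shift_on_disrupt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(l % 3 != 0 or l <= 0 for l in self.loop_lengths):
            raise ValueError("loop lengths must be positive multiples of 3")
        if any(s % 3 != 0 or s == 0 for s in self.shift_values):
            raise ValueError("shift values must be nonzero multiples of 3")
        if len(self.loop_weights) != len(self.loop_lengths):
            raise ValueError("loop_weights must match loop_lengths")
        if len(self.shift_weights) != len(self.shift_values):
            raise ValueError("shift_weights must match shift_values")
        if self.unfold_rate < 0 or self.nucleus_disrupt_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.nucleus_stability not in ("stable", "weak"):
            raise ValueError("nucleus_stability must be 'stable' or 'weak'")
        if self.barrier_factor <= 0:
            raise ValueError("barrier_factor must be positive")

    @property
    def n_residues(self) -> int:
        return 3 * self.n_repeats

    @property
    def mean_unit_time(self) -> float:
        """Expected time per completed unit, counting reversions (ps)."""
        n_attempts = 1.0 / (1.0 - self.p_revert) if self.p_revert < 1 else np.inf
        return (
            n_attempts * self.tau_template
            + (n_attempts - 1.0) * self.tau_revert
            + self.tau_lock
        )

    def mutations(self):
        return tuple(
            (chain, pos, self.mutation_residue) for chain, pos in self.mutation_sites
        )


@dataclass
class UnitRecord:
    """Kinetic record of one propagation unit within one folding epoch."""

    unit: int
    epoch: int
    template_times: list = field(default_factory=list)
    template_chains: list = field(default_factory=list)
    revert_times: list = field(default_factory=list)
    lock_time: float | None = None


@dataclass
class MisfoldRecord:
    kind: str  # "loop" or "shift"
    chain: str
    position: int  # first residue (loop) / 0 (whole-chain shift)
    length: int  # loop length or shift offset (slot = residue + offset)
    time: float


@dataclass
class EventLog:
    """Ground truth emitted by the generator."""

    units: list
    misfolds: list
    unfold_events: list
    disruption_events: list
    outcome: str
    seed: int
    config: dict

    def surviving_lock_times(self) -> dict:
        """unit -> lock time, for locks not undone by a later collapse.

        Folded units never revert within an epoch; a collapse or nucleus
        disruption ends the epoch and voids its locks."""
        resets = sorted(self.unfold_events + self.disruption_events)
        out = {}
        for rec in self.units:
            if rec.lock_time is None:
                continue
            if any(r > rec.lock_time for r in resets):
                continue
            out[rec.unit] = rec.lock_time
        return out

    def to_json(self, path) -> None:
        payload = {
            "outcome": self.outcome,
            "seed": self.seed,
            "config": self.config,
            "units": [dataclasses.asdict(u) for u in self.units],
            "misfolds": [dataclasses.asdict(m) for m in self.misfolds],
            "unfold_events": self.unfold_events,
            "disruption_events": self.disruption_events,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Slot atlas: ideal coordinates for every (chain, slot), slots extended
# beyond the chain ends so shifted/looped registers stay renderable.
# ---------------------------------------------------------------------------


class SlotAtlas:
    """Reference coordinates per (chain, helix slot).

    Slot ``r`` of a chain is where residue ``r`` sits in the native
    register. Slots outside 1..L are taken from an internally built longer
    helix rigidly aligned onto the reference, so defect registers (slot =
    residue + 3k) can be rendered.
    """

    PAD_REPEATS = 3  # extra repeats on each side

    def __init__(self, reference: StructureModel, n_repeats: int, params=None, mutations=()):
        self.reference = reference
        self.n_residues = 3 * n_repeats
        pad = 3 * self.PAD_REPEATS
        ext_mut = tuple((c, p + pad, r) for c, p, r in mutations)
        extended = build_reference_helix(
            n_repeats + 2 * self.PAD_REPEATS, mutations=ext_mut, params=params
        )
        # Rigidly align the extended helix onto the reference via the
        # atoms they share (extended residue i+pad == reference residue i).
        ref_idx = np.argsort(
            [self._key(reference, i) for i in range(reference.n_atoms)]
        )
        shared = extended.mask(
            residues=range(pad + 1, pad + self.n_residues + 1)
        )
        ext_sub_idx = np.flatnonzero(shared)
        ext_keys = [
            (extended.chain_ids[i], int(extended.res_indices[i]) - pad, extended.atom_names[i])
            for i in ext_sub_idx
        ]
        order = np.argsort(np.array([f"{c}_{r:04d}_{a}" for c, r, a in ext_keys]))
        ref_keys = [
            (reference.chain_ids[i], int(reference.res_indices[i]), reference.atom_names[i])
            for i in ref_idx
        ]
        ext_coords = extended.coords[ext_sub_idx[order]]
        ref_coords = reference.coords[ref_idx]
        if [ext_keys[i] for i in order] != ref_keys:
            raise ValueError("atlas/reference atom tables do not correspond")
        rot, trans, err = kabsch_superpose(ext_coords, ref_coords)
        if err > 1e-6:
            raise ValueError(f"atlas alignment residual {err:.2e} A")
        aligned = extended.coords @ rot.T + trans
        self._atoms = {}
        for i in range(extended.n_atoms):
            key = (extended.chain_ids[i], int(extended.res_indices[i]) - pad)
            self._atoms.setdefault(key, {})[extended.atom_names[i]] = aligned[i]
        self.min_slot = 1 - pad
        self.max_slot = self.n_residues + pad

    @staticmethod
    def _key(model, i):
        return f"{model.chain_ids[i]}_{int(model.res_indices[i]):04d}_{model.atom_names[i]}"

    def atom(self, chain: str, slot: int, name: str) -> np.ndarray:
        res = self._atoms[(chain, slot)]
        if name in res:
            return res[name]
        return res["CA"]  # fallback for side-chain atoms absent at the slot

    def ca(self, chain: str, slot: int) -> np.ndarray:
        return self._atoms[(chain, slot)]["CA"]


@dataclass
class FrameState:
    """Per-(chain, residue) state of one frame.

    ``status[c][r-1]`` is one of the state codes; ``slot[c][r-1]`` the
    helix slot the residue occupies when structured (ignored for U)."""

    status: dict
    slot: dict


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


def _simulate_kinetics(cfg: ZipperConfig, rng: np.random.Generator):
    """Continuous-time event simulation. Returns (unit records, misfolds,
    unfold events, disruptions, shifts per chain, loops per chain)."""
    n_units = cfg.n_repeats
    mutated_units = {(r + 2) // 3 for _, r in cfg.mutation_sites}
    units: list[UnitRecord] = []
    misfolds: list[MisfoldRecord] = []
    unfold_events: list[float] = []
    disruptions: list[float] = []
    chain_shift = {c: 0 for c in _CHAINS}
    chain_loop = {c: None for c in _CHAINS}  # (start, length, time)

    # Register shifts are nucleus-association events: drawn per chain at
    # the start of each epoch, at most one defect per chain.
    def maybe_shift(t: float):
        for c in _CHAINS:
            if chain_shift[c] == 0 and chain_loop[c] is None and rng.random() < cfg.p_shift:
                s = int(rng.choice(cfg.shift_values, p=_norm(cfg.shift_weights)))
                chain_shift[c] = s
                misfolds.append(MisfoldRecord("shift", c, 0, s, t))

    def next_disruption(t: float) -> float:
        if cfg.nucleus_stability == "weak" and cfg.nucleus_disrupt_rate > 0:
            return t + rng.exponential(1.0 / cfg.nucleus_disrupt_rate)
        return np.inf

    t = 0.0
    epoch = 0
    ever_complete = False
    complete_at_end = False
    maybe_shift(0.0)
    t_disrupt = next_disruption(0.0)
    while t < cfg.total_time:
        # one folding epoch: propagate units C->N
        epoch_done = True
        for k in range(n_units, 0, -1):
            barrier = cfg.barrier_factor if k in mutated_units else 1.0
            rec = UnitRecord(unit=k, epoch=epoch)
            units.append(rec)
            locked = False
            while not locked:
                t += rng.exponential(cfg.tau_template * barrier)
                if t >= min(cfg.total_time, t_disrupt):
                    break
                pair = sorted(rng.choice(3, size=2, replace=False).tolist())
                rec.template_times.append(t)
                rec.template_chains.append([_CHAINS[i] for i in pair])
                if rng.random() < cfg.p_revert:
                    t += rng.exponential(cfg.tau_revert * barrier)
                    if t >= min(cfg.total_time, t_disrupt):
                        break
                    rec.revert_times.append(t)
                else:
                    t += rng.exponential(cfg.tau_lock * barrier)
                    if t >= min(cfg.total_time, t_disrupt):
                        break
                    rec.lock_time = t
                    locked = True
            if not locked:
                epoch_done = False
                break
            # misfold emission: as propagation passes this unit, one chain
            # may bulge out the next unit(s) N-ward of the locked front
            if rng.random() < cfg.p_loop and k >= 3:
                c = _loop_candidate(rng, chain_shift, chain_loop)
                if c is not None:
                    length = int(
                        rng.choice(cfg.loop_lengths, p=_norm(cfg.loop_weights))
                    )
                    # room needed: the loop units plus >= 1 unit N-ward
                    # to flank it once propagation continues
                    length = min(length, 3 * (k - 2))
                    if length >= 3:
                        start = 3 * (k - 1) + 1 - length
                        chain_loop[c] = (start, length, t)
                        misfolds.append(MisfoldRecord("loop", c, start, length, t))

        if t >= t_disrupt and t_disrupt < cfg.total_time:
            # nucleus disruption: epoch collapses, may seed a shift
            t = t_disrupt
            disruptions.append(t)
            if rng.random() < cfg.shift_on_disrupt:
                maybe_shift_forced(cfg, rng, chain_shift, chain_loop, misfolds, t)
            t_disrupt = next_disruption(t)
            epoch += 1
            continue

        if not epoch_done:
            break  # ran out of time mid-propagation

        ever_complete = True
        complete_at_end = True
        if cfg.unfold_rate > 0:
            t_collapse = t + rng.exponential(1.0 / cfg.unfold_rate)
            if t_collapse < min(cfg.total_time, t_disrupt):
                t = t_collapse
                unfold_events.append(t)
                complete_at_end = False
                epoch += 1
                continue
        # folded state persists to the end (or to a disruption)
        if t_disrupt < cfg.total_time:
            t = t_disrupt
            disruptions.append(t)
            complete_at_end = False
            if rng.random() < cfg.shift_on_disrupt:
                maybe_shift_forced(cfg, rng, chain_shift, chain_loop, misfolds, t)
            t_disrupt = next_disruption(t)
            epoch += 1
            continue
        break

    return (
        units,
        misfolds,
        unfold_events,
        disruptions,
        chain_shift,
        chain_loop,
        ever_complete,
        complete_at_end,
    )


def _norm(w):
    w = np.asarray(w, dtype=float)
    return w / w.sum()


def _loop_candidate(rng, chain_shift, chain_loop):
    free = [c for c in _CHAINS if chain_shift[c] == 0 and chain_loop[c] is None]
    if not free:
        return None
    return free[int(rng.integers(len(free)))]


def maybe_shift_forced(cfg, rng, chain_shift, chain_loop, misfolds, t):
    free = [c for c in _CHAINS if chain_shift[c] == 0 and chain_loop[c] is None]
    if not free:
        return
    c = free[int(rng.integers(len(free)))]
    s = int(rng.choice(cfg.shift_values, p=_norm(cfg.shift_weights)))
    chain_shift[c] = s
    misfolds.append(MisfoldRecord("shift", c, 0, s, t))


# ---------------------------------------------------------------------------
# State reconstruction and rendering
# ---------------------------------------------------------------------------


def _state_at(cfg: ZipperConfig, log_parts, t: float) -> FrameState:
    """Per-residue state at time t, reconstructed from the event stream."""
    units, misfolds, unfold_events, disruptions, chain_shift, chain_loop = log_parts
    n_res = cfg.n_residues
    nucleus = {n_res, n_res - 1}
    resets = sorted(unfold_events + disruptions)
    # active epoch = number of resets at or before t
    epoch = sum(1 for r in resets if r <= t)

    # shift active if its record time <= t
    shift_now = {c: 0 for c in _CHAINS}
    loop_now = {c: None for c in _CHAINS}
    for m in misfolds:
        if m.time <= t:
            if m.kind == "shift":
                shift_now[m.chain] = m.length
            else:
                loop_now[m.chain] = (m.position, m.length)

    locked_units = set()
    template = None  # (unit, chains)
    for rec in units:
        if rec.epoch != epoch:
            continue
        if rec.lock_time is not None and rec.lock_time <= t:
            locked_units.add(rec.unit)
        else:
            # is a template alive at t?
            for i, tt in enumerate(rec.template_times):
                if tt > t:
                    continue
                t_end = (
                    rec.revert_times[i]
                    if i < len(rec.revert_times)
                    else (rec.lock_time if rec.lock_time is not None else np.inf)
                )
                if t < t_end:
                    template = (rec.unit, rec.template_chains[i])
    status = {c: [UNFOLDED] * n_res for c in _CHAINS}
    slot = {c: [0] * n_res for c in _CHAINS}
    for c in _CHAINS:
        s_off = shift_now[c]
        loop = loop_now[c]
        for r in range(1, n_res + 1):
            unit = (r + 2) // 3
            if loop is not None and loop[0] <= r < loop[0] + loop[1]:
                status[c][r - 1] = LOOPED_OUT
                continue
            # the restrained nucleus never leaves its native slots; a
            # register shift displaces the strand only N-ward of it
            off = s_off if r not in nucleus else 0
            if loop is not None and r < loop[0]:
                off += loop[1]
            structured = r in nucleus or unit in locked_units
            is_template = (
                template is not None
                and unit == template[0]
                and c in template[1]
                and r not in nucleus
            )
            if structured:
                status[c][r - 1] = FOLDED
                slot[c][r - 1] = r + off
            elif is_template:
                status[c][r - 1] = TEMPLATE
                slot[c][r - 1] = r + off
    return FrameState(status=status, slot=slot)


def _residue_atoms(topology: StructureModel, chain: str, residue: int):
    idx = topology.select(chain=chain, residues=[residue])
    return idx, [topology.atom_names[i] for i in idx]


def render_frame(
    state: FrameState,
    topology: StructureModel,
    atlas: SlotAtlas,
    cfg: ZipperConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one coordinate frame from a per-residue state vector.

    Folded/template residues sit at their slot's ideal coordinates plus
    isotropic Gaussian noise of width ``sigma_folded``; unfolded residues
    follow a tethered random walk (CA step ``excursion_scale``) from the
    last structured residue toward the N-terminus, each residue rigidly
    reoriented at random; looped-out residues lie on an off-axis arc
    between their flanking slots.
    """
    return _render_frames([state], topology, atlas, cfg, rng)[0]


def _random_rotations(rng, n):
    """n uniform random rotation matrices (via normalized quaternions)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=1,
    )


def _render_frames(states, topology, atlas, cfg, rng):
    """Render a list of FrameStates.

    Frames sharing one FrameState object (one event interval) are
    rendered together so the noise draws vectorize over frames."""
    n_frames = len(states)
    coords = np.empty((n_frames, topology.n_atoms, 3))
    sigma = cfg.sigma_folded
    n_res = max(int(r) for r in topology.res_indices)

    # Pre-extract atom indices / local geometry per residue
    res_info = {}
    for c in _CHAINS:
        for r in range(1, n_res + 1):
            idx, names = _residue_atoms(topology, c, r)
            ca_ref = atlas.ca(c, r)
            local = np.array([atlas.atom(c, r, nm) for nm in names]) - ca_ref
            res_info[(c, r)] = (np.asarray(idx), names, local)

    groups = []  # (state, frame index array) in first-appearance order
    seen = {}
    for fi, st in enumerate(states):
        key = id(st)
        if key not in seen:
            seen[key] = len(groups)
            groups.append((st, []))
        groups[seen[key]][1].append(fi)

    for st, frames in groups:
        fidx = np.asarray(frames)
        nf = len(fidx)
        for c in _CHAINS:
            unknown = set(st.status[c]) - {FOLDED, TEMPLATE, LOOPED_OUT, UNFOLDED}
            if unknown:
                raise ValueError(f"unknown residue state code(s): {sorted(unknown)}")
            field = _smooth_field(rng, nf, n_res, sigma, cfg) if sigma > 0 else None
            sig_j = sigma * cfg.jitter_fraction
            for r in range(1, n_res + 1):
                code = st.status[c][r - 1]
                idx, names, local = res_info[(c, r)]
                if code in (FOLDED, TEMPLATE):
                    slot = st.slot[c][r - 1]
                    base = np.array([atlas.atom(c, slot, nm) for nm in names])
                    block = np.broadcast_to(base, (nf,) + base.shape).copy()
                    if sigma > 0:
                        if r >= n_res - 1:
                            # positional restraints suppress collective
                            # motion of the nucleus: damped jitter only
                            block += rng.normal(
                                scale=sigma * cfg.nucleus_noise_factor,
                                size=block.shape,
                            )
                        else:
                            block += field[:, r - 1, None, :]
                            block += rng.normal(scale=sig_j, size=block.shape)
                    coords[np.ix_(fidx, idx)] = block
                elif code == LOOPED_OUT:
                    ca, _ = _loop_arc_position(st, c, r, atlas)
                    rots = _random_rotations(rng, nf)
                    block = ca + np.einsum("ak,fjk->faj", local, rots)
                    block += rng.normal(scale=max(sigma, 0.1), size=block.shape)
                    coords[np.ix_(fidx, idx)] = block
            # tethered random walks for unfolded runs, all frames at once
            unfolded = [r for r in range(1, n_res + 1) if st.status[c][r - 1] == UNFOLDED]
            if not unfolded:
                continue
            for run in _contiguous_runs(unfolded):
                u = len(run)
                anchor_res = run[-1] + 1
                if anchor_res <= n_res and st.status[c][anchor_res - 1] in (FOLDED, TEMPLATE):
                    anchor = atlas.ca(c, st.slot[c][anchor_res - 1])
                elif anchor_res <= n_res and st.status[c][anchor_res - 1] == LOOPED_OUT:
                    anchor = _loop_arc_position(st, c, anchor_res, atlas)[0]
                else:
                    anchor = atlas.ca(c, min(run[-1], atlas.max_slot))
                steps = rng.normal(size=(nf, u, 3))
                steps /= np.linalg.norm(steps, axis=2, keepdims=True)
                # walk grows N-ward: residue run[-1] is one step from the
                # anchor, run[0] is u steps away
                walk = anchor + cfg.excursion_scale * np.cumsum(steps[:, ::-1], axis=1)[:, ::-1]
                rots = _random_rotations(rng, nf * u).reshape(nf, u, 3, 3)
                for j, r in enumerate(run):
                    idx, names, local = res_info[(c, r)]
                    block = walk[:, j, None, :] + np.einsum("ak,fjk->faj", local, rots[:, j])
                    coords[np.ix_(fidx, idx)] = block
    return coords


def _smooth_field(rng, nf, n_res, sigma, cfg):
    """Per-residue collective displacement field (nf, n_res, 3): white
    noise smoothed along the residue index and rescaled so its
    per-coordinate standard deviation complements the atomic jitter."""
    from scipy.ndimage import gaussian_filter1d

    sig_field = sigma * np.sqrt(max(1.0 - cfg.jitter_fraction**2, 0.0))
    pad = int(np.ceil(4 * cfg.field_smoothing))
    raw = rng.normal(size=(nf, n_res + 2 * pad, 3))
    smooth = gaussian_filter1d(raw, cfg.field_smoothing, axis=1, mode="nearest")
    smooth = smooth[:, pad : pad + n_res, :]  # crop: uniform variance
    # restore unit variance lost to smoothing (interior-kernel norm)
    m = n_res + 2 * pad
    k = np.zeros(m)
    k[m // 2] = 1.0
    k = gaussian_filter1d(k, cfg.field_smoothing, mode="constant")
    norm = np.sqrt((k**2).sum())
    return smooth * (sig_field / norm)


def _contiguous_runs(sorted_values):
    runs = []
    cur = [sorted_values[0]]
    for v in sorted_values[1:]:
        if v == cur[-1] + 1:
            cur.append(v)
        else:
            runs.append(cur)
            cur = [v]
    runs.append(cur)
    return runs


def _loop_arc_position(st, chain, r, atlas):
    """CA position of a looped-out residue on an off-axis arc between the
    flanking helix slots. Returns (position, loop length)."""
    status = st.status[chain]
    start = r
    while start > 1 and status[start - 2] == LOOPED_OUT:
        start -= 1
    end = r
    n_res = len(status)
    while end < n_res and status[end] == LOOPED_OUT:
        end += 1
    length = end - start + 1
    # flanks: C-ward neighbour at its own slot, N-ward neighbour at slot+length
    slot_c = end + 1 if end + 1 <= n_res else end
    a_c = atlas.ca(chain, min(slot_c, atlas.max_slot))
    slot_n = start - 1 + length if start > 1 else start + length
    slot_n = int(np.clip(slot_n, atlas.min_slot, atlas.max_slot))
    a_n = atlas.ca(chain, slot_n)
    j = r - start + 1
    frac = j / (length + 1)
    base = a_n + (a_c - a_n) * frac
    radial = base - np.array([0.0, 0.0, base[2]])
    nrm = np.linalg.norm(radial)
    radial = radial / nrm if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])
    bulge = (2.5 + 1.0 * length) * np.sin(np.pi * frac)
    return base + radial * bulge, length


# ---------------------------------------------------------------------------
# Top-level simulate
# ---------------------------------------------------------------------------


def simulate_kinetics(cfg: ZipperConfig) -> EventLog:
    """Run only the continuous-time kinetics (no coordinate rendering).

    Useful for waiting-time statistics over many seeds; uses the same
    event stream a full :func:`simulate` with the same seed would
    produce."""
    rng = np.random.default_rng(cfg.seed)
    (
        units,
        misfolds,
        unfold_events,
        disruptions,
        _shift,
        _loop,
        ever_complete,
        complete_at_end,
    ) = _simulate_kinetics(cfg, rng)
    log = EventLog(
        units=units,
        misfolds=misfolds,
        unfold_events=unfold_events,
        disruption_events=disruptions,
        outcome="",
        seed=cfg.seed,
        config=dataclasses.asdict(cfg),
    )
    log.outcome = _label_outcome(log, ever_complete, complete_at_end)
    return log


def _label_outcome(log: EventLog, ever_complete: bool, complete_at_end: bool) -> str:
    if complete_at_end and not log.misfolds:
        return "folded"
    if complete_at_end:
        return "misfolded"
    if ever_complete:
        return "transient"
    return "partial" if log.surviving_lock_times() else "unfolded"


def simulate(cfg: ZipperConfig, reference: StructureModel | None = None):
    """Run one stochastic zipper trajectory.

    Returns ``(trajectory, event_log)``. Deterministic given
    ``cfg.seed`` and the configuration. The trajectory's topology is the
    (possibly mutated) ideal reference helix; frames are spaced
    ``cfg.dt`` ps apart from t=0 to ``cfg.total_time`` inclusive.
    """
    rng = np.random.default_rng(cfg.seed)
    params = HelixParameters()
    if reference is None:
        reference = build_reference_helix(
            cfg.n_repeats, mutations=cfg.mutations(), params=params
        )
    atlas = SlotAtlas(reference, cfg.n_repeats, params=params, mutations=cfg.mutations())

    (
        units,
        misfolds,
        unfold_events,
        disruptions,
        chain_shift,
        chain_loop,
        ever_complete,
        complete_at_end,
    ) = _simulate_kinetics(cfg, rng)

    log_parts = (units, misfolds, unfold_events, disruptions, chain_shift, chain_loop)

    n_frames = int(round(cfg.total_time / cfg.dt)) + 1
    times = cfg.dt * np.arange(n_frames)

    # Event-interval grouping: state changes only at event times.
    event_times = sorted(
        {0.0}
        | {t for rec in units for t in rec.template_times}
        | {t for rec in units for t in rec.revert_times}
        | {rec.lock_time for rec in units if rec.lock_time is not None}
        | {m.time for m in misfolds}
        | set(unfold_events)
        | set(disruptions)
    )
    frame_states = []
    state_cache = {}
    marks = np.searchsorted(event_times, times, side="right") - 1
    for fi in range(n_frames):
        mark = int(marks[fi])
        if mark not in state_cache:
            state_cache[mark] = _state_at(cfg, log_parts, event_times[mark])
        frame_states.append(state_cache[mark])

    coords = _render_frames(frame_states, reference, atlas, cfg, rng)
    traj = Trajectory(reference, coords, dt=cfg.dt, t0=0.0)

    log = EventLog(
        units=units,
        misfolds=misfolds,
        unfold_events=unfold_events,
        disruption_events=disruptions,
        outcome="",
        seed=cfg.seed,
        config=dataclasses.asdict(cfg),
    )
    log.outcome = _label_outcome(log, ever_complete, complete_at_end)
    return traj, log
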