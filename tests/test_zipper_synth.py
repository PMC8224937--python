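"""Synthetic zipper generator: kinetics, rendering, ground truth."""

import dataclasses

import numpy as np
import pytest

from colfold.geometry_core import rmsd
from colfold.propagation_analysis import nucleus_superpose
from colfold.trajectory_io import Trajectory
from colfold.zipper_synth import (
    FOLDED,
    LOOPED_OUT,
    TEMPLATE,
    UNFOLDED,
    FrameState,
    SlotAtlas,
    ZipperConfig,
    render_frame,
    simulate,
    simulate_kinetics,
)

FAST = dict(
    total_time=60_000.0,
    tau_template=2_000.0,
    tau_revert=1_000.0,
    tau_lock=1_000.0,
)


class TestConfigValidation:
    def test_defaults_mean_unit_time(self):
        cfg = ZipperConfig()
        # 2 attempts x 25 ns + 1 reverted lifetime x 12.5 + lock 12.5
        assert cfg.mean_unit_time == pytest.approx(75_000.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(loop_lengths=(4,)),
            dict(shift_values=(2,)),
            dict(shift_values=(0,)),
            dict(p_revert=1.5),
            dict(tau_lock=-1.0),
            dict(nucleus_stability="wobbly"),
            dict(loop_lengths=(3, 6), loop_weights=(1.0,)),
        ],
    )
    def test_inconsistent_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ZipperConfig(**kwargs)


class TestKinetics:
    def test_locks_progress_c_to_n_in_time(self):
        cfg = ZipperConfig(**FAST, seed=0)
        log = simulate_kinetics(cfg)
        locks = log.surviving_lock_times()
        assert log.outcome == "folded"
        # unit index decreases toward N while lock times strictly increase
        units_by_time = [u for u, _ in sorted(locks.items(), key=lambda kv: kv[1])]
        assert units_by_time == sorted(locks, reverse=True)
        times = sorted(locks.values())
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_folded_units_never_revert_without_collapse(self):
        # folded state is absorbing when unfolding is disabled
        for seed in range(10):
            log = simulate_kinetics(ZipperConfig(**FAST, seed=seed))
            assert log.unfold_events == []
            for rec in log.units:
                if rec.lock_time is not None:
                    assert all(t < rec.lock_time for t in rec.revert_times)

    def test_lock_interval_mean_matches_exponential_model(self):
        # waiting-time oracle: sample mean of per-unit lock intervals over
        # many seeds within 3 standard errors of the configured mean
        intervals = []
        for seed in range(50):
            log = simulate_kinetics(ZipperConfig(seed=seed))
            ts = sorted(log.surviving_lock_times().values())
            intervals.extend(np.diff([0.0] + ts))
        intervals = np.asarray(intervals)
        cfg = ZipperConfig()
        sem = intervals.std() / np.sqrt(len(intervals))
        assert abs(intervals.mean() - cfg.mean_unit_time) <= 3 * sem

    def test_same_seed_bitwise_identical(self):
        cfg = ZipperConfig(**FAST, p_loop=0.3, seed=42)
        a = simulate_kinetics(cfg)
        b = simulate_kinetics(cfg)
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_barrier_slows_mutated_unit(self):
        slow, fast = [], []
        for seed in range(30):
            base = dict(**FAST, seed=seed)
            log_f = simulate_kinetics(ZipperConfig(**base))
            log_s = simulate_kinetics(
                ZipperConfig(**base, mutation_sites=(("A", 7),), barrier_factor=8.0)
            )

            def unit3_interval(log):
                locks = log.surviving_lock_times()
                if 3 in locks and 4 in locks:
                    return locks[3] - locks[4]
                return None

            f, s = unit3_interval(log_f), unit3_interval(log_s)
            if f is not None:
                fast.append(f)
            if s is not None:
                slow.append(s)
        assert np.mean(slow) > 2 * np.mean(fast)

    def test_loop_and_shift_defects_are_multiples_of_three(self):
        for seed in range(30):
            log = simulate_kinetics(
                ZipperConfig(**FAST, p_loop=0.5, p_shift=0.3, seed=seed)
            )
            for m in log.misfolds:
                assert m.length % 3 == 0 and m.length != 0

    def test_unfold_rate_produces_collapse_events(self):
        log = simulate_kinetics(
            ZipperConfig(**{**FAST, "total_time": 200_000.0}, unfold_rate=1 / 20_000.0, seed=1)
        )
        assert len(log.unfold_events) >= 1
        assert log.outcome in ("transient", "partial", "unfolded", "folded")


class TestRendering:
    def test_all_folded_zero_noise_is_exact_reference(self, reference):
        cfg = ZipperConfig(sigma_folded=0.0, seed=0)
        atlas = SlotAtlas(reference, 5)
        state = FrameState(
            status={c: [FOLDED] * 15 for c in "ABC"},
            slot={c: list(range(1, 16)) for c in "ABC"},
        )
        coords = render_frame(state, reference, atlas, cfg, np.random.default_rng(0))
        assert np.abs(coords - reference.coords).max() < 1e-9

    def test_unfolded_tail_is_far_from_reference(self, reference):
        cfg = ZipperConfig(seed=0)
        atlas = SlotAtlas(reference, 5)
        status = {c: [UNFOLDED] * 13 + [FOLDED] * 2 for c in "ABC"}
        slot = {c: list(range(1, 16)) for c in "ABC"}
        rng = np.random.default_rng(5)
        far = 0
        for _ in range(20):
            coords = render_frame(FrameState(status, slot), reference, atlas, cfg, rng)
            nuc = reference.select(residues=[14, 15])
            assert np.abs(coords[nuc] - reference.coords[nuc]).max() < 1.0
            rest = reference.select(residues=range(1, 13))
            far += rmsd(coords[rest], reference.coords[rest]) >= 2.0
        assert far >= 18  # random-walk tail clears 2 A nearly always

    def test_template_rendering_places_two_chains(self, reference):
        cfg = ZipperConfig(seed=0)
        atlas = SlotAtlas(reference, 5)
        status = {
            "A": [UNFOLDED] * 9 + [TEMPLATE] * 3 + [FOLDED] * 3,
            "B": [UNFOLDED] * 9 + [TEMPLATE] * 3 + [FOLDED] * 3,
            "C": [UNFOLDED] * 12 + [FOLDED] * 3,
        }
        slot = {c: list(range(1, 16)) for c in "ABC"}
        coords = render_frame(
            FrameState(status, slot), reference, atlas, cfg, np.random.default_rng(3)
        )
        for chain in "AB":
            idx = reference.select(chain=chain, residues=[10, 11, 12])
            assert rmsd(coords[idx], reference.coords[idx]) < 1.5
        idx = reference.select(chain="C", residues=[10, 11, 12])
        assert rmsd(coords[idx], reference.coords[idx]) >= cfg.excursion_scale / 2

    def test_unknown_state_code_rejected(self, reference):
        cfg = ZipperConfig(seed=0)
        atlas = SlotAtlas(reference, 5)
        status = {c: ["?"] + [FOLDED] * 14 for c in "ABC"}
        slot = {c: list(range(1, 16)) for c in "ABC"}
        with pytest.raises(ValueError):
            render_frame(FrameState(status, slot), reference, atlas, cfg, np.random.default_rng(0))


class TestSimulate:
    def test_trajectory_shape_and_determinism(self):
        cfg = ZipperConfig(**FAST, seed=7)
        t1, l1 = simulate(cfg)
        t2, l2 = simulate(cfg)
        assert t1.n_frames == int(cfg.total_time // cfg.dt) + 1
        np.testing.assert_array_equal(t1.coords, t2.coords)
        assert dataclasses.asdict(l1) == dataclasses.asdict(l2)

    def test_forced_loop_shows_in_final_frame(self, reference):
        cfg = ZipperConfig(**FAST, p_loop=1.0, loop_lengths=(3,), loop_weights=(1.0,), seed=4)
        traj, log = simulate(cfg)
        loops = [m for m in log.misfolds if m.kind == "loop"]
        assert loops, "forced loop did not occur"
        m = loops[0]
        fitted = nucleus_superpose(traj, traj.topology)[-1]
        idx = traj.topology.select(
            chain=m.chain, residues=range(m.position, m.position + m.length)
        )
        # looped-out residues sit off their native slots
        assert rmsd(fitted[idx], traj.topology.coords[idx]) > 2.0

    def test_mutated_topology_carries_substitution(self):
        cfg = ZipperConfig(**FAST, mutation_sites=(("A", 7),), mutation_residue="ALA", seed=0)
        traj, _ = simulate(cfg)
        i = traj.topology.select(chain="A", residues=[7])[0]
        assert traj.topology.res_names[i] == "ALA"
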