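"""Folding statistics: profiles, contacts, folding times, states, outcomes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from colfold import (
    ScalarSeries,
    Trajectory,
    ZipperConfig,
    dihedral_state,
    endpoint_delta,
    folding_time,
    gaussian_smooth,
    native_contact_fraction,
    outcome_classify,
    propagation_times,
    simulate,
    triplet_fold_state,
    triplet_rmsd_profile,
)
from colfold.propagation_analysis import window_means

FAST = dict(
    total_time=60_000.0,
    tau_template=2_000.0,
    tau_revert=1_000.0,
    tau_lock=1_000.0,
)


@pytest.fixture(scope="module")
def folding_run():
    traj, log = simulate(ZipperConfig(**FAST, seed=3))
    return traj, log


class TestProfile:
    def test_reference_profile_all_zero(self, reference, reference_trajectory):
        profile = triplet_rmsd_profile(reference_trajectory, reference)
        assert profile.n_triplets == 15
        assert profile.values.max() < 1e-9

    def test_folded_final_frame_below_one_angstrom(self, folding_run):
        traj, log = folding_run
        assert log.outcome == "folded"
        profile = triplet_rmsd_profile(traj, traj.topology)
        assert profile.values[:, -1].max() < 1.0

    def test_locality_of_single_residue_displacement(self, reference):
        coords = np.repeat(reference.coords[None], 1, axis=0).copy()
        idx = reference.select(chain="A", residues=[7])
        coords[0, idx] += np.array([10.0, 0.0, 0.0])
        traj = Trajectory(reference, coords, dt=50.0)
        profile = triplet_rmsd_profile(traj, reference)
        assert profile.values[6, 0] > 3.0
        others = np.delete(profile.values[:, 0], 6)
        assert others.max() < 3.0

    def test_topology_mismatch_rejected(self, reference):
        from colfold import build_reference_helix

        other = build_reference_helix(4)
        traj = Trajectory(other, other.coords[None], dt=50.0)
        with pytest.raises(ValueError):
            triplet_rmsd_profile(traj, reference)


class TestNativeContacts:
    def test_reference_frame_fraction_one(self, reference, reference_trajectory):
        series, counts = native_contact_fraction(reference_trajectory, reference)
        assert series.values[0] == pytest.approx(1.0)

    def test_separated_chains_fraction_zero(self, reference):
        coords = reference.coords.copy()
        coords[reference.chain_ids == "B"] += 100.0
        coords[reference.chain_ids == "C"] += 200.0
        traj = Trajectory(reference, coords[None], dt=50.0)
        series, _ = native_contact_fraction(traj, reference)
        assert series.values[0] == 0.0

    def test_fraction_increases_during_folding(self, folding_run):
        traj, _ = folding_run
        series, _ = native_contact_fraction(traj, traj.topology)
        rho = spearmanr(np.arange(len(series)), series.values).statistic
        assert rho > 0.8

    def test_empty_reference_set_is_an_error(self, reference):
        scattered = reference.copy()
        scattered.coords[reference.chain_ids == "B"] += 500.0
        scattered.coords[reference.chain_ids == "C"] += 900.0
        traj = Trajectory(scattered, scattered.coords[None], dt=50.0)
        with pytest.raises(ValueError, match="contact set is empty"):
            native_contact_fraction(traj, scattered)


class TestFoldingTime:
    def test_constant_low_series_returns_t0(self):
        s = ScalarSeries(np.full(200, 0.5), dt=50.0, t0=0.0)
        assert folding_time(s) == 0.0

    def test_constant_high_series_returns_none(self):
        s = ScalarSeries(np.full(200, 5.0), dt=50.0)
        assert folding_time(s) is None

    def test_step_series_window_arithmetic(self):
        # 10 A for frames 0-999 then 0.2 A: the first qualifying window
        # starts at frame 996 (mean (4*10 + 46*0.2)/50 = 0.984 < 1)
        values = np.concatenate([np.full(1000, 10.0), np.full(200, 0.2)])
        s = ScalarSeries(values, dt=50.0)
        assert folding_time(s) == pytest.approx(996 * 50.0)

    def test_equals_brute_force_window_scan(self, rng):
        for _ in range(50):
            values = rng.uniform(0, 3, size=rng.integers(60, 300))
            s = ScalarSeries(values, dt=50.0)
            got = folding_time(s)
            expected = None
            for start in range(len(values) - 50 + 1):
                if values[start : start + 50].mean() < 1.0:
                    expected = start * 50.0
                    break
            assert got == expected

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            folding_time(ScalarSeries(np.zeros(10), dt=50.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_threshold(self, seed):
        """Raising the threshold never increases the folding time."""
        r = np.random.default_rng(seed)
        s = ScalarSeries(r.uniform(0, 3, size=120), dt=50.0)
        t_low = folding_time(s, threshold=0.8)
        t_high = folding_time(s, threshold=1.5)
        if t_low is not None:
            assert t_high is not None and t_high <= t_low


class TestDihedralState:
    def test_reference_frame_all_native(self, reference):
        states, skipped = dihedral_state(reference, reference)
        assert states and all(states.values())
        assert ("A", 1) in skipped  # N-terminal phi undefined

    def test_single_rotated_dihedral_flagged(self, reference):
        # rotate phi(Gly7) of chain A by 120 deg: rotate N-ward part of
        # the chain about the N(7)-CA(7) bond
        frame = reference.copy()
        n7 = reference.atom_coord("A", 7, "N")
        ca7 = reference.atom_coord("A", 7, "CA")
        axis = n7 - ca7
        axis /= np.linalg.norm(axis)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec(np.radians(120.0) * axis).as_matrix()
        moving = [
            i
            for i in frame.select(chain="A")
            if frame.res_indices[i] < 7
            or (frame.res_indices[i] == 7 and frame.atom_names[i] == "N")
        ]
        # keep N(7) fixed on the axis; rotate everything N-ward of it
        moving = [i for i in moving if not (frame.res_indices[i] == 7)]
        frame.coords[moving] = (frame.coords[moving] - ca7) @ rot.T + ca7
        # N(7) lies on the axis through CA(7)? It does not; rotate it too
        i_n7 = frame.atom_index("A", 7, "N")
        frame.coords[i_n7] = (frame.coords[i_n7] - ca7) @ rot.T + ca7
        states, _ = dihedral_state(frame, reference)
        assert states[("A", 7)] is False
        others = {k: v for k, v in states.items() if k != ("A", 7)}
        assert all(others.values())

    def test_agrees_with_direct_angular_check(self, reference, rng):
        from colfold.geometry_core import phi_psi
        from colfold.propagation_analysis import circular_difference

        for _ in range(100):
            frame = reference.with_coords(
                reference.coords + rng.normal(scale=0.15, size=reference.coords.shape)
            )
            states, _ = dihedral_state(frame, reference, tolerance=30.0)
            for (chain, pos), value in states.items():
                phi_f, _ = phi_psi(frame, chain, pos)
                phi_r, _ = phi_psi(reference, chain, pos)
                _, psi_f = phi_psi(frame, chain, pos - 1)
                _, psi_r = phi_psi(reference, chain, pos - 1)
                expected = (
                    circular_difference(phi_f, phi_r) <= 30.0
                    and circular_difference(psi_f, psi_r) <= 30.0
                )
                assert value == expected


class TestTripletFoldState:
    def test_reference_frame_folded(self, reference):
        for triplet in (1, 4, 8, 13):
            assert triplet_fold_state(reference, reference, triplet) == "FOLDED"

    def test_rendered_template_classified(self, reference):
        from colfold.zipper_synth import (
            FOLDED,
            TEMPLATE,
            UNFOLDED,
            FrameState,
            SlotAtlas,
            render_frame,
        )

        cfg = ZipperConfig(seed=0)
        atlas = SlotAtlas(reference, 5)
        status = {
            "A": [UNFOLDED] * 9 + [TEMPLATE] * 3 + [FOLDED] * 3,
            "B": [UNFOLDED] * 9 + [TEMPLATE] * 3 + [FOLDED] * 3,
            "C": [UNFOLDED] * 12 + [FOLDED] * 3,
        }
        slot = {c: list(range(1, 16)) for c in "ABC"}
        rng = np.random.default_rng(8)
        calls = []
        for _ in range(10):
            coords = render_frame(FrameState(status, slot), reference, atlas, cfg, rng)
            frame = reference.with_coords(coords)
            calls.append(triplet_fold_state(frame, reference, 10))
        assert calls.count("TEMPLATE") >= 8

    def test_template_precedes_folding_in_lock_events(self):
        # the two-chain template intermediate is visible before most locks
        hits = 0
        total = 0
        for seed in range(4):
            traj, log = simulate(ZipperConfig(**FAST, seed=seed))
            ref = traj.topology
            for rec in log.units:
                if rec.lock_time is None or not rec.template_times:
                    continue
                f0 = int(np.ceil(rec.template_times[-1] / traj.dt))
                f1 = int(rec.lock_time // traj.dt)
                if f1 < f0:
                    continue
                total += 1
                anchor = 3 * rec.unit - 2
                for f in range(f0, min(f1 + 1, traj.n_frames)):
                    if triplet_fold_state(traj.frame(f), ref, anchor) == "TEMPLATE":
                        hits += 1
                        break
        assert total >= 10
        assert hits / total >= 0.8


class TestPropagationTimes:
    def test_reference_trajectory_all_units_at_t0(self, reference, reference_trajectory):
        unit_times, mean = propagation_times(reference_trajectory, reference)
        assert all(t == 0.0 for t in unit_times.values())
        assert mean == 0.0

    def test_recovers_ground_truth_locks(self, folding_run):
        traj, log = folding_run
        locks = log.surviving_lock_times()
        unit_times, _ = propagation_times(traj, traj.topology)
        for unit, t_true in locks.items():
            est = unit_times[unit]
            assert est is not None
            assert abs(est - t_true) <= 2500.0

    def test_units_complete_c_to_n(self, folding_run):
        traj, _ = folding_run
        unit_times, _ = propagation_times(traj, traj.topology)
        ts = [unit_times[k] for k in sorted(unit_times, reverse=True)]
        assert all(t is not None for t in ts)
        assert all(b >= a for a, b in zip(ts, ts[1:]))


class TestOutcomeClassify:
    def test_reference_trajectory_is_folded(self, reference, reference_trajectory):
        report = outcome_classify(reference_trajectory, reference)
        assert report.outcome == "FOLDED"
        assert report.folding_time == 0.0
        assert report.final_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_transient_fold_then_unfold(self):
        # folds, collapses, stays unfolded: folding time exists but the
        # final window fails (the triple-mutant phenotype)
        from colfold import simulate_kinetics

        cfg = None
        for seed in range(40):
            cand = ZipperConfig(
                **{**FAST, "total_time": 120_000.0},
                unfold_rate=1 / 30_000.0,
                seed=seed,
            )
            if simulate_kinetics(cand).outcome == "transient":
                cfg = cand
                break
        assert cfg is not None, "no transient scenario among the probed seeds"
        traj, log = simulate(cfg)
        assert log.outcome == "transient"
        report = outcome_classify(traj, traj.topology)
        assert report.outcome == "TRANSIENT"
        assert report.folding_time is not None

    def test_halted_propagation_is_partial(self):
        # truncate a successful run mid-propagation: the C-terminal block
        # is folded, the probe unit is not
        from colfold import simulate_kinetics

        gap_ps = 3 * 50 * 50.0  # three detection windows of slack
        chosen = None
        for seed in range(30):
            cfg = ZipperConfig(**FAST, seed=seed)
            locks = simulate_kinetics(cfg).surviving_lock_times()
            if len(locks) < 5:
                continue
            for k in (4, 3):  # keep >= 2 folded units beyond the nucleus
                if locks[k - 1] - locks[k] >= gap_ps:
                    chosen = (cfg, locks[k - 1])
                    break
            if chosen:
                break
        assert chosen is not None, "no usable mid-propagation gap found"
        cfg, t_next_lock = chosen
        traj, _ = simulate(cfg)
        cut = int((t_next_lock - traj.dt) // traj.dt)
        part = Trajectory(traj.topology, traj.coords[:cut], dt=traj.dt)
        report = outcome_classify(part, traj.topology)
        assert report.outcome == "PARTIAL"
        assert report.folding_time is None

    def test_never_transient_without_collapse(self):
        # with misfolds and unfolding disabled the folded state is absorbing
        for seed in range(8):
            traj, _ = simulate(ZipperConfig(**FAST, seed=seed))
            report = outcome_classify(traj, traj.topology)
            assert report.outcome != "TRANSIENT"


class TestSeriesBookkeeping:
    def test_constant_series_unchanged_by_smoothing(self):
        s = ScalarSeries(np.full(300, 7.25), dt=50.0)
        out = gaussian_smooth(s, sigma=25.0)
        np.testing.assert_allclose(out.values, 7.25, atol=1e-12)

    def test_impulse_response_is_normalized_kernel(self):
        n = 500
        values = np.zeros(n)
        values[250] = 1.0
        out = gaussian_smooth(ScalarSeries(values, dt=50.0), sigma=25.0)
        half = int(np.ceil(4 * 25.0))
        x = np.arange(-half, half + 1)
        kernel = np.exp(-0.5 * (x / 25.0) ** 2)
        kernel /= kernel.sum()
        assert out.values[250] == pytest.approx(kernel[half])
        np.testing.assert_allclose(out.values[250 - 20 : 250], out.values[250 + 20 : 250 : -1])
        # interior-supported impulse: total mass preserved
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_endpoint_delta_linear_ramp(self):
        s = ScalarSeries(np.arange(100, dtype=float), dt=50.0)
        assert endpoint_delta(s, n=20) == pytest.approx(80.0)

    def test_endpoint_delta_constant_zero(self):
        s = ScalarSeries(np.full(60, 3.0), dt=50.0)
        assert endpoint_delta(s) == 0.0

    def test_endpoint_delta_matches_direct_slicing(self, rng):
        for _ in range(20):
            v = rng.normal(size=rng.integers(40, 120))
            s = ScalarSeries(v, dt=50.0)
            assert endpoint_delta(s, n=20) == pytest.approx(v[-20:].mean() - v[:20].mean())

    def test_endpoint_delta_short_series_rejected(self):
        with pytest.raises(ValueError):
            endpoint_delta(ScalarSeries(np.zeros(30), dt=50.0), n=20)

    def test_window_means_match_bruteforce(self, rng):
        v = rng.normal(size=97)
        wm = window_means(v, 10)
        for i in range(len(v) - 9):
            assert wm[i] == pytest.approx(v[i : i + 10].mean())
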