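# colfold

Trajectory analysis of collagen triple-helix folding propagation, with a
synthetic zipper-trajectory generator for validating every analysis stage
against exact ground truth.

## The problem

Collagen folds by zipper-like propagation: after a C-terminal nucleus has
formed, the triple helix grows one Gly-X-Y repeat at a time toward the
N-terminus. In each elementary step, two chains first form a transient
near-native *template* for a 3-residue segment; the third chain then locks
onto that template, extending the helix by one repeat. Misfolding takes
characteristic forms — bulge loops in which one strand loops out a multiple
of three residues, and register shifts in which strands associate offset by
a multiple of the repeat — and Gly→Ala/Thr substitutions slow or abort
propagation. MD studies of (Gly-Pro-Pro)₅ homotrimers quantify this
kinetics frame by frame; `colfold` packages the analysis machinery those
studies need, for people who have such trajectories (or want controlled
synthetic ones) and want reproducible folding statistics.

## What's inside

| module | contents |
| --- | --- |
| `colfold.helix_model` | internal-coordinate builder for an idealized (Gly-Pro-Pro)ₙ triple-helix reference (exact screw symmetry, Gly→Ala/Thr substitutions), harmonic-restraint arithmetic `x = √(RT/k)` under the `E = k·x²` convention |
| `colfold.trajectory_io` | multi-model PDB trajectories, CSV series/matrices, YAML configs |
| `colfold.geometry_core` | Kabsch superposition, RMSD, IUPAC dihedrals, φ/ψ, inter-chain heavy-atom contacts (≤ 4.0 Å) |
| `colfold.zipper_synth` | stochastic zipper generator: exponential template/lock waiting times (default mean 75 ns per completed unit), template reversion, bulge loops, register shifts, collapse and nucleus-disruption modes; emits a ground-truth `EventLog` |
| `colfold.propagation_analysis` | per-triplet RMSD profiles, native-contact fraction, sliding-window folding times (50 frames = 2.5 ns, 1 Å threshold, probe residue 4), dihedral/template state calls, per-unit propagation times, FOLDED/PARTIAL/TRANSIENT/UNFOLDED outcome classification, Gaussian series smoothing (σ = 25 frames) and endpoint deltas, multi-run tabulation |
| `colfold.misfold_bending` | register assignment (nearest-slot matching + longest increasing subsequence), bulge-loop and register-shift detection, bending-anisotropy projection |

A key design point: the analyses never see the generator's internals.
Folding times, per-unit propagation times, misfold taxonomy and state
calls are recomputed purely from coordinates and checked against the
generator's event log in the test suite.

## Worked example

```python
import colfold as cf

cfg = cf.ZipperConfig(total_time=500_000.0, seed=3)   # 0.5 us, 50 ps frames
traj, log = cf.simulate(cfg)                          # trajectory + ground truth
report = cf.outcome_classify(traj, traj.topology)

print(report.outcome)                  # FOLDED
print(report.folding_time / 1000)      # 300.05   (ns)
print(round(report.final_rmsd, 2))     # 0.41     (A, heavy-atom fitted)
print({u: round(t / 1000, 1) for u, t in sorted(report.unit_times.items())})
# {1: 346.8, 2: 300.1, 3: 232.3, 4: 192.6, 5: 140.8}
print({u: round(t / 1000, 1) for u, t in sorted(log.surviving_lock_times().items())})
# {1: 346.9, 2: 300.2, 3: 232.6, 4: 192.7, 5: 141.2}
```

The folding time (300.05 ns) is the first moment a 50-frame window of the
probe-triplet RMSD (residue 4 of each chain, after superposition on the
restrained C-terminal nucleus) has mean below 1 Å. The per-unit completion
times estimated from coordinates alone track the generator's true lock
times (bottom line) to within a fraction of the 2.5 ns detection window;
units complete in C→N order, as the zipper mechanism requires.

The same operations are available from the shell:

```sh
colfold simulate --config cfg.yaml --seed 3 --out-prefix run
colfold analyze  --traj run_traj.pdb --ref run_ref.pdb --out-prefix run
colfold misfold  --traj run_traj.pdb --ref run_ref.pdb --out-prefix run
colfold report   --table runs.csv
```

`colfold.datasets.md_reference_outcomes()` bundles the per-run outcomes
(final RMSD, folding time) of ten 1 μs MD folding simulations per
construct; `colfold report` / `tabulate_outcomes` reduces such tables to
per-construct completion and correct-fold counts.

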