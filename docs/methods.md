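# Methods

## Scope and conventions

`colfold` analyses trajectories of a three-chain (Gly-Pro-Pro)ₙ collagen
model peptide relative to a native triple-helix reference. Coordinates are
in Å and times in ps throughout (ns appear only in reports; 1 ns =
1000 ps). Chains are labelled A, B, C; residues are numbered 1-based from
the N-terminus. A *triplet* is the set of residues sharing one residue
number across the three chains; a *unit* is one Gly-X-Y repeat (three
consecutive triplets), the elementary step of zipper propagation; the
*nucleus* is the two C-terminal residues of each chain, which in the MD
protocol being emulated are held near-native by harmonic positional
restraints on their Cα atoms.

## The reference helix

The reference is built from internal coordinates rather than loaded from a
crystal structure, so the package is self-contained; an external PDB
reference can be substituted through `trajectory_io.read_structure_pdb`.
One chain is grown residue by residue (NeRF) from per-class backbone
dihedrals — defaults φ/ψ = (−81.5°, 174.0°) for Gly, (−75.0°, 172.5°) for
the X-position Pro, (−59.5°, 157.5°) for the Y-position Pro, all peptide
bonds trans (ω = 180°) — giving an exactly repeating helix whose
per-triplet screw transform T (twist ≈ −61.5°, rise ≈ 8.51 Å per triplet,
i.e. ≈ 2.84 Å per residue) is extracted analytically and aligned with the
z axis. Chains B and C are the images of chain A under a single
inter-chain screw S with S³ = T (one-residue stagger); of the three cube
roots of T, the branch is fixed to the one that packs the chains into
inter-chain heavy-atom contact (every triplet has contacts within 4.0 Å;
minimum inter-chain atom distance ≈ 3.2 Å). The default dihedrals were
chosen by a packing search over the collagen region of the Ramachandran
map and are a geometric idealization, not a claim about any particular
crystal structure; all of them are overridable through `HelixParameters`.

Residues carry backbone atoms N, CA, C, O plus an ideal tetrahedral Cβ for
non-Gly residues (Thr additionally Oγ1/Cγ2 at χ₁ = −60°). Side chains
beyond Cβ stubs are deliberately omitted: every analysis in the package
operates at triplet resolution, where only backbone geometry and
near-backbone sterics matter. Gly→Ala/Thr substitutions rename the residue
and add the stub atoms without touching the backbone.

## Restraint arithmetic

The fluctuation scale of a restrained atom is x = √(RT/k), i.e. the
displacement at which the restraint energy reaches the thermal energy
RT (0.616 kcal·mol⁻¹ at 310 K). This uses the restraint convention
E = k·x², the convention of the MD engine being emulated — under the
alternative ½k·x² convention the weak restraint (k = 0.05
kcal·mol⁻¹·Å⁻²) would allow ~5 Å rather than the ~3.5 Å ("up to 4 Å")
that the analyses assume.

## The synthetic zipper generator

The generator is a phenomenological stand-in for MD — no forces, solvent
or temperatures — that produces coordinate trajectories *plus the exact
event log that generated them*, so every downstream estimator can be
validated as a measurement: the analyses see only coordinates, and the
tests compare their output with the log.

Kinetics are sampled in continuous time and only then quantized to the
50 ps frame grid, so waiting-time statistics are exact. For each unit,
C-terminal first:

1. a two-chain template forms after an exponential waiting time
   (`tau_template`, default 25 ns per attempt; the two chains are chosen
   at random);
2. with probability `p_revert` (default 0.5) the template decays after an
   exponential lifetime (`tau_revert`, default 12.5 ns) and the step is
   retried;
3. otherwise the third chain locks after an exponential waiting time
   (`tau_lock`, default 12.5 ns). Locked units never revert (the folded
   state is absorbing unless a collapse mode is enabled).

The expected time per completed unit is then
2 × 25 + 1 × 12.5 + 12.5 = 75 ns, the mean propagation rate the analyses
are designed to recover. Only this aggregate is empirically constrained;
the split between template formation, reversion and locking is a modelling
choice, flagged as such (template lifetimes are not quantified by the MD
observations being emulated). At units containing a configured mutation
site all waiting times are multiplied by `barrier_factor`, emulating the
steric barrier of a Gly→Ala/Thr substitution.

Misfold modes:

* **Bulge loops** (`p_loop`): as propagation passes a unit, one chain may
  loop out the next 3, 6 or 9 residues; its remaining N-terminal residues
  continue in a register shifted by the loop length. At most one defect
  per chain; loops are only emitted where at least one unit of in-register
  structure can still form on the N-terminal side, since an unflanked
  terminal loop is indistinguishable from fraying.
* **Register shifts** (`p_shift`): a chain associates with the nucleus
  offset by −3 or −6 residues and propagates in that register. The two
  restrained nucleus residues themselves stay in place (strands are
  *partially* shifted), which also keeps the analysis superposition anchor
  meaningful.
* **Collapse** (`unfold_rate`): after full completion the folded state
  may collapse at a constant rate, whereupon propagation restarts from the
  nucleus — the transient-folding phenotype of triple-mutant chains.
* **Weak nucleus** (`nucleus_stability="weak"`): a Poisson disruption
  process aborts propagation and may seed a register shift, reproducing
  the efficiency drop and misfold accumulation seen under weak restraints
  qualitatively; no quantitative claim is attached.

Rendering: folded and template residues sit at their helix-slot
coordinates plus noise; unfolded residues follow a tethered random walk
(Cα step `excursion_scale` = 3.8 Å) from the last structured residue
toward the N-terminus, each residue rigidly reoriented at random;
looped-out residues lie on an arc bulging radially away from the helix
axis between their flanking slots. Shifted registers are rendered from an
internally built longer helix aligned onto the reference, so out-of-range
slots exist. Frames are statistically independent given the state — there
is no intra-state temporal correlation, which is the main respect in which
the synthetic data are *easier* than MD (no slow collective modes, no
autocorrelated noise). Passing tests therefore demonstrate estimator
correctness on the stated model, not robustness to every artifact of real
trajectories.

The folded-state noise (total per-coordinate width `sigma_folded`,
default 0.3 Å) is decomposed into a displacement field smoothed along the
chain (correlation width 1.5 residues) plus a small independent per-atom
jitter (fraction 0.15 of the total width). Pure
per-atom white noise of 0.3 Å would scramble backbone dihedrals by tens of
degrees, which MD does not do; the collective field keeps positional
fluctuations at the configured width while dihedral fluctuations stay
within ~±15°. The restrained nucleus is rendered with damped, purely
atomic noise (`nucleus_noise_factor` = 1/3, no collective field): the
restraints suppress collective motion of the anchor, and without this the
superposition jitter of the anchor projects a lever-arm error onto distal
triplets that restrained MD fits do not show.

Everything is driven by one seeded generator; the same seed and
configuration reproduce the event log and trajectory bit for bit.

## Analyses

**Superposition convention.** All per-triplet and probe RMSDs superpose
each frame onto the reference using the backbone atoms (N, CA, C, O) of
the nucleus — the restrained, always-native anchor — and then evaluate
RMSDs *without refitting*, so unfolded triplets far from their slots read
large. The whole-molecule `final_rmsd` of a report instead uses a full
Kabsch fit over all heavy atoms, matching the convention of end-state
tables.

**Per-triplet RMSD profile.** Heavy-atom RMSD of each triplet versus the
reference, per frame; the profile of the reference against itself is
identically zero, and displacing a single residue perturbs only its own
triplet's row.

**Native contacts.** The reference contact set is all inter-chain
heavy-atom pairs within 4.0 Å of the reference structure ("minimum
distance of 4.0 Å" is read as *distance ≤ 4.0 Å defines a contact*, the
only reading under which contacts increase on folding). Pairs lying
entirely inside the restrained nucleus are excluded by default — they
exist by construction and would compress the dynamic range of the
fraction; the exclusion and a multiplicative distance tolerance (default
1.0) are configurable. Whether intra-chain pairs should also be counted is
not settled by the source observations; this implementation counts
inter-chain pairs only.

**Folding time.** The probe series is the per-frame RMSD of the three
residues numbered `probe_residue` (default 4 — the third triplet is
probed rather than the first to avoid end fraying, and the explicit
residue number is used where ordinal and number could disagree). A window
of 50 frames (2.5 ns at 50 ps spacing) slides through the series; the
reported time is the time of the *first frame of the first window* whose
mean is below 1 Å — the earliest evidence of sustained folding. (The
alternative convention, the window's last frame, differs by one window
width and is available by adding `window × dt`.) Raising the threshold
can only move the folding time earlier, never later.

**Dihedral and template states.** The flexible hinge of each repeat is the
pair (φ of Glyᵢ, ψ of Proᵢ₋₁); a position is dihedral-native when both
angles lie within ±30° (circular distance) of the reference values.
Undefined terminal dihedrals are reported as skipped, never silently
classified. For the per-triplet fold-state call the relevant hinge is the
one at the *C-terminal edge* of the triplet's unit (φ of the next unit's
Gly and ψ of the preceding Pro): those are the angles that flip when the
unit folds onto the already-helical C-terminal side, whereas the hinge at
the unit's own Gly still borders disordered residues. A chain's residue is
native when that hinge is native (where defined) and its heavy atoms lie
within 1.5 Å RMSD of the reference after nucleus superposition; FOLDED =
3 native chains, TEMPLATE = exactly 2 (the two-chain template
intermediate), else UNFOLDED.

**Per-unit propagation times and outcomes.** A unit's completion time is
the folding time of its Gly-position triplet under the same detector; the
mean per-unit propagation time is the mean of successive differences of
completed units in C→N order (never-completed units are ignored).
Outcome classification: FOLDED if a folding time exists and the final
window of the probe RMSD is still below threshold; TRANSIENT if a folding
time exists but the final window fails (folded, then unfolded); PARTIAL
if there is no folding time but a contiguous C-terminal block of at least
2 units beyond the nucleus is folded in the final window (the threshold
of 2 units is this package's choice — "partly helical" is not otherwise
quantified); else UNFOLDED.

**Energy-style series bookkeeping.** Gaussian smoothing uses an explicit
kernel with σ in frames (default 25), truncated at ±4σ and renormalized
at the edges so constants pass through unchanged (library filter modes
pad rather than renormalize, which biases edges). The endpoint delta is
mean(last n frames) − mean(first n frames), default n = 20.

**Tabulation.** `tabulate_outcomes` reduces a per-run table to
per-construct counts: `n_completed` (a completion time exists) and
`n_correct` (completed *and* final RMSD < 2.0 Å). The two are reported
separately because a run can reach a completely folded state transiently
yet end misfolded; the 2 Å correctness filter reproduces the distinction
drawn in the weak-restraint bookkeeping of the bundled MD outcome table.

## Misfold detection and bending

**Register assignment.** After nucleus superposition, each residue's Cα
is matched to the nearest same-chain reference slot Cα within a capture
radius (default 3.0 Å — comfortably above the folded noise of ~0.3–1 Å
and below the ≥3.8 Å inter-slot spacing); the final assignment is the
maximum-cardinality strictly increasing subsequence of matches (register
can only move forward along a chain), computed by dynamic programming and
verified against exhaustive search on short chains. Unmatched residues
are unassigned.

**Loops and shifts.** A bulge loop is a maximal unassigned run flanked by
assigned residues whose register offsets differ by exactly the run
length. The terminal register offset of a chain is the offset of the
first assigned segment of ≥3 residues scanning from the C-terminus (the
2-residue restrained nucleus stub is skipped — it stays in place even
when the strand is shifted). Detection operates on single frames;
trajectory-level calls evaluate the final frame, since misfold taxonomy
classifies end states.

**Bending projection.** Per frame, with a = backbone centroid of the
C-terminal triplet, c = of the middle triplet, b = of the N-terminal
triplet: the reported point is the component of (b − c) − (b_ref − c_ref)
in a fixed orthonormal basis perpendicular to the reference helix axis
(u = normalize(c_ref − a_ref)). Fixing the basis and subtracting the
reference's own offset makes the straight reference map to exactly (0,0)
and makes x/y comparable across frames; the Pearson correlation r of the
point cloud is therefore basis-dependent but reproducible. Whether the
"center" should be the middle triplet's centroid or the centroid of all
folded residues is unresolved in the source description; the middle
triplet is used. Frames with a degenerate axis (|c − a| ≈ 0) are skipped
and reported. Anisotropic (directional) bending yields an elongated,
correlated cloud; isotropic flexing a ring with |r| near 0; significance
is assessed by a permutation test shuffling y across frames.

## Problem sizes and numerical choices

The validation suite runs the generator at reduced trajectory lengths
(60–600 ns instead of 1 μs) and, for waiting-time statistics, uses the
kinetics-only path (`simulate_kinetics`), which reproduces the full
simulation's event stream for the same seed without rendering frames.
Parameter-recovery checks use 50 seeds at the default kinetics; the
misfold and bending suites use 25–30 seeds. Kabsch superposition refuses
rank-deficient point sets (< 3 points or collinear); dihedrals refuse
coincident or collinear consecutive points; contact detection uses a k-d
tree and is verified against brute-force enumeration. Dihedral
comparisons always use circular distance (wrap at ±180°).

## Known limitations

* The reference helix is an idealization; analyses against a
  crystallographic reference will see small systematic offsets in
  dihedral-state calls if its φ/ψ differ from the configured classes.
* Synthetic frames are temporally uncorrelated given the state; detector
  variance on real, autocorrelated MD data will be larger than on
  synthetic data at the same noise level.
* The generator allows at most one register defect per chain; compound
  misfolds (a loop downstream of a shift in the same chain) are not
  modelled, and the detectors have not been validated on them.
* Continuum-solvent energetics are out of scope; only the series
  bookkeeping (smoothing, endpoint deltas) is provided.
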