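# Methods

`emligfit` implements the simulation half of an AI + density-guided
ligand-building workflow for cryo-EM: given candidate models of a
protein–ligand complex (for example a batch of AlphaFold3-class
predictions) and an experimental map, it rigid-body aligns each candidate,
selects the most promising one by ligand model-to-map cross-correlation,
refines it by Langevin dynamics with map-derived forces, and reports
per-entity accuracies against a ground-truth structure when one is
available. This note records the model, its assumptions, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Density model

A model density is simulated by placing an isotropic 3-D Gaussian on each
heavy atom:

    rho(v) = sum_i  A_i / ((2 pi)^{3/2} sigma^3) * exp(-|v - x_i|^2 / (2 sigma^2))

evaluated at voxel centres and truncated on the sphere `r <= 4 sigma`
(dropping at most ~3e-4 of relative amplitude). The width is tied to the
nominal map resolution through the FWHM convention, `sigma =
resolution / (2 sqrt(2 ln 2))`; at 3.2 Å, `sigma ≈ 1.36 Å`. Amplitudes
default to atomic numbers (a scattering-mass proxy); a uniform mode exists
for tests. Hydrogens never contribute: maps in the 2.7–3.7 Å range carry
no hydrogen signal. Voxel values are point evaluations, not volume
integrals — the difference is absorbed by the correlation normalisation.

## Masked cross-correlation and its two readings

Fit quality is the Pearson correlation between a simulated density and
the target map, restricted to the *model-support mask*: all voxels within
the truncation radius of any selected heavy atom. Mean subtraction is on
by default (an uncentred dialect is available via
`MapSimParams(mean_subtract=False)` because external CC tools support
both conventions).

Per-entity CC (`entity_cc`) admits two readings, and the package
implements both:

* **Entity-only (default).** The entity's own atoms are simulated and
  correlated over the entity's mask. This is the semantics of
  per-selection CC checks in density-fitting practice. A correctly placed
  ligand then scores *below* 1 whenever neighbouring protein density or
  map noise falls inside its mask; on the default synthetic complex the
  ground-truth ligand scores ~0.5 against its own noiseless map. All
  monitoring traces, ranking and reports use this reading.
* **Full-model context (`context="full"`).** The whole model's density is
  correlated over the entity's mask — a local-fit measure for which a
  perfect model scores exactly 1 for every entity. The synthetic-fixture
  generator uses it as its self-consistency invariant (≥ 0.99 on a
  noiseless map).

Accuracy relative to ground truth follows the benchmark convention

    accuracy(%) = (1 - |CC_model - CC_groundtruth| / CC_max) * 100

with `CC_max = 1` for all CC-based accuracies; it compares two models'
CCs computed the same way, so it is insensitive to which reading is used
as long as it is used consistently.

## Analytic CC gradient

The gradient of the masked CC with respect to atomic coordinates is
computed analytically. With `F`, `G` the mean-centred masked model and
target vectors, `d cc / d f_v = G_v/(|F||G|) - cc * F_v/|F|^2` (the
mean-subtraction chain term vanishes because both centred fields have
zero mask mean), and `d f_v / d x_i` is the Gaussian kernel derivative
`w_iv (v - x_i)/sigma^2`. The mask is held fixed within one evaluation
and recomputed whenever atoms move. Sphere truncation makes the masked CC
only piecewise-smooth: the kernel jumps by `exp(-R^2/2 sigma^2)` at the
truncation boundary, so finite-difference checks are run at a 6-sigma
truncation (jump ~1.5e-8) where agreement to relative 1e-4 is a sharp
test of the analytic path; production runs keep the spec'd 4-sigma
truncation.

Hot paths (Gaussian rasterisation, gradient accumulation, nonbonded
loops) are numba-compiled with a pure-numpy fallback; both paths are
cross-checked to float64 rounding in the tests.

## Rigid-body alignment

`fit_rigid` maximises the global (all-heavy-atom) CC over rotations about
the model centroid plus translation. The rotation gradient is obtained by
the rigid-body torque identity `g_omega = sum_i (x_i - c) x g_i` from the
per-atom CC gradients; ascent uses a backtracking line search with an
adaptive trial step (initial 0.5 Å equivalent displacement, growth 1.5x,
halving on rejection) and stops after three consecutive accepted steps
improving CC by under 1e-6, after which the winning pose is polished with
a triple budget. Restarts: the input pose plus seeded uniform random
rotations (default 12 in `fit_rigid`; the ranking stage defaults to a
single local fit because AI candidates arrive roughly pre-placed).
On self-map recovery problems at 3 Å resolution the fitter recovers
displacements of ~8 degrees / ~1 Å to better than 0.05 degrees and
0.01 Å.

## Restraint force field

During flexible fitting the internal force field's only job is to
preserve stereochemistry against the (deliberately large) density
forces, so transferable force-field accuracy is unnecessary. The package
derives *structure-native* restraints from the input model itself:

* bonds by element-dependent distance cutoffs (`d < 1.3 (r_cov,i +
  r_cov,j)`), with equilibrium lengths set to the observed distances
  (`k_b = 2000 kJ/mol/Å^2`);
* harmonic angles on every bonded triplet, equilibrium at the observed
  angle (`k_theta = 200 kJ/mol/rad^2`);
* Lennard-Jones with a per-element parameter table and Lorentz–Berthelot
  combination; 1-2/1-3 pairs excluded, 1-4 pairs scaled by 0.5;
* optional cutoff Coulomb electrostatics (charges default to zero;
  dielectric 15 damps bare charges when they are supplied).

Nonbonded interactions are smoothed to zero between 10 and 12 Å with the
CHARMM-style potential-switching function (energy multiplied by a C1
switch; forces are the exact negative energy gradient, and pairs beyond
the cutoff contribute exactly zero). No dihedral terms by default — the
bond/angle network of ring-and-chain ligands is rigid enough at the
force scales involved.

The protein–ligand interaction energy (PLIE) monitor is the same
LJ + Coulomb sum over interface pairs only, reported per ligand heavy
atom. It is a plausibility check — favourable packing shows as a
negative value — not a binding free energy; with zero default charges
and no solvent it cannot reproduce absolute interaction energies from
explicit-solvent simulations, and only its sign and trends are
interpreted.

## Density-guided Langevin dynamics

`run_flexfit` integrates Langevin dynamics (BAOAB splitting) at 310 K
with friction 1/ps and a 2 fs timestep, in vacuum. The external force on
each heavy atom is `k * d cc/d x_i` with `k = 10^3 kJ/mol` initially;
following common practice the density force is recomputed every N = 2
steps and held in between. Per-atom density forces are capped at
10^4 kJ/mol/Å; if more than 1% of atoms exceed the cap the run terminates
gracefully with a `force_cap_exceeded` event and the last valid frame —
the signature of a pose the map force cannot repair (for example a
flipped ligand), which should be fixed by better starting models rather
than brute force.

**Adaptive force scaling.** Whenever the global CC improves by less than
1e-4 over 50 consecutive density-force applications, `k` grows by 5%
(never decreasing, capped at 100x). The responsiveness matters: at
`k = 10^3` the 310 K thermal fluctuations of a ~20-atom ligand put its
stationary CC at only ~0.86 of the static ground-truth value on the
default benchmark complex, and a schedule that cannot lift `k` by an
order of magnitude within a 50 ps run leaves the refinement short of its
ceiling. With the default schedule `k` typically saturates and the
fitted ligand's CC reaches 0.95–1.0 of the ground-truth self-CC.

Optional restrained pre-relaxation (5000 steepest-descent steps with
400 / 40 kJ/mol/nm^2 position restraints on protein backbone / everything
else) removes steric clashes inherited from imperfect candidates before
dynamics begins.

Traces (ligand/pocket/protein CC, PLIE per heavy atom, current k) are
sampled every 50 fs; frames every 1 ps. The "fitted" value of a run can
be reduced either as the final frame or as the mean over the final 20
saved frames; both reducers are provided and the benchmark reporting
uses the final-20-frame mean, which averages over thermal jitter.

## Synthetic benchmark fixtures

No experimental data ships with the package; every test input is
generated. `make_fixture` builds:

* a pseudo-protein of `n_residues` (default 40) 4-atom residues
  (N, CA, C, O) wound as a helical wall (radius 6.7 Å, 36°/residue,
  0.9 Å rise) around an axial channel — enough geometry to define a
  binding pocket, a backbone, and realistic density overlap, at a size
  where a 50 ps run takes well under a minute;
* a rigid ring-plus-tail ligand (default 18 heavy atoms: a hexagonal
  ring plus an aperiodic zigzag tail — aperiodic so that axially
  displaced poses do not spuriously overlap their own density) docked
  off-axis by a deterministic search maximising sub-4 Å protein contacts
  (≥ 3 guaranteed) at ≥ 2.9 Å clearance;
* a target map simulated at 3.2 Å on 1 Å voxels (optionally with seeded
  Gaussian voxel noise as a fraction of the map peak);
* five candidate models emulating an AI prediction batch. All candidates
  share one seeded *error mode* — a ligand displacement direction biased
  along the channel, a rotation axis, a protein twist axis and a
  smoothed per-residue noise field — with magnitudes graded as
  (1.0, 1.3, 1.6, 1.9, 2.2) x the spec targets (defaults: ligand 3 Å
  RMSD, protein 1.5 Å RMSD), tuned by bisection to ±10%. Sharing the
  direction emulates the empirical tendency of independent predictions
  to share a systematic error mode, and makes "least-perturbed
  candidate" well defined for ranking checks.

The default regime (3.2 Å map, 3 Å ligand error, 1.5 Å protein error)
reproduces the hardest-but-solvable band of real benchmarks: initial
ligand CCs of roughly 0.05–0.35 against ground-truth self-CCs of
~0.5, recovering to ≥ 0.9 of self-CC within 50 ps.

What the fixtures do *not* emulate: real cryo-EM noise structure (CTF
envelopes, solvent flattening, B-factor variation), side-chain
chemistry, ligand internal flexibility beyond the restraint network, and
prediction errors that change topology rather than pose. Passing the
synthetic benchmark therefore demonstrates the mechanics of the
pipeline — ranking, map forces, adaptive scaling, bookkeeping — not
performance on experimental maps.

## Numerical and design choices

* Coordinates in Å, energies in kJ/mol, times in ps, masses in amu;
  `1 (kJ/mol/Å)/amu = 100 Å/ps²`.
* Map I/O is MRC/CCP4 mode 2 via gemmi; axis order is normalised to
  x,y,z on read and the origin is taken from the ORIGIN words, falling
  back to start-index arithmetic. Non-orthogonal cells are rejected.
* PDB is the write format; chain ids longer than one character raise
  rather than silently truncate. Altloc collapse keeps the
  highest-occupancy conformer (ties: first encountered). A minimal
  mmCIF `atom_site` reader covers prediction outputs.
* "Protein" means polymer (non-HETATM) atoms; waters and ions are
  excluded everywhere. Ligand auto-selection takes the largest non-water
  hetero residue by heavy-atom count, skipping single-atom residues
  (ions).
* The pocket is every protein residue with any atom within 4 Å of any
  ligand atom (whole residues). The curation filter's contact threshold
  is strict (< 4.0 passes): a closest contact at exactly 4 Å is read as
  a non-conclusive binding site. Both cutoffs are configurable.
* Ranking ties break by pocket CC, then input order; rigid-fit restart
  ties break by earliest restart.
* The pipeline manifest contains no timestamps — configuration, seeds,
  package version, stage statuses and SHA-256 checksums only — so two
  runs with the same seed produce bit-identical manifests; wall-clock
  notes go to a separate `runtime.log` excluded from the checksum
  inventory.
* The reported benchmark reference table (per-entity CCs and PLIE for
  ten complexes) ships with the evaluation module as the input to the
  accuracy bookkeeping; `scripts/acceptance.py` recomputes the group
  accuracy summaries from it at run time.

## Known limitations

* The restraint field preserves geometry but not chemistry: no torsional
  preferences, no hydrogen bonding, no electrostatics unless charges are
  supplied. PLIE values are comparable only within a run.
* Entity-only CC depends on the environment inside the mask, so absolute
  values are not comparable across proteins with different pocket
  density; accuracies (differences against ground truth) are.
* The rigid fitter is a local optimiser; for blindly placed models it
  relies on random-rotation restarts and can settle in a
  pseudo-symmetric local optimum.
* Adaptive scaling trades fidelity for fit: at saturated `k` the
  density term dominates the restraints by design, and the final model
  should be treated as a template for standard refinement rather than a
  final structure.
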