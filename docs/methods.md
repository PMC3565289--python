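# Methods

This note documents the models implemented in `mqsar`, the choices made
where the underlying methodology is published only in outline, and what
the synthetic benchmarks do and do not demonstrate.

## Nonbonded energy model

Ligand–protein energetics use three terms:

- **van der Waals:** 12-6 Lennard-Jones, `4ε[(σ/r)¹² − (σ/r)⁶]`, with
  arithmetic-mean σ and geometric-mean ε combining rules and a bundled
  element-keyed parameter table (OPLS-like values for H, C, N, O, S, P and
  the halogens; overridable from a CSV).
- **electrostatics:** Coulomb with k = 332.06 kcal·Å/(mol·e²), either a
  constant dielectric (default ε = 1) or the distance-dependent form
  ε_eff = ε·r. Partial charges come from a sidecar CSV
  (`serial,charge_e`), from PDB occupancy columns, or from a crude
  single-pass electronegativity-difference assigner used by the
  generators; the charge provenance is the caller's responsibility to log.
- **hydrogen bond:** a directional 10-12 term,
  `ε_hb[5(σ_hb/r_DA)¹² − 6(σ_hb/r_DA)¹⁰]·cos²θ_DHA`, zero for θ ≤ 90°,
  with defaults ε_hb = 2.0 kcal/mol, σ_hb = 2.9 Å. This term enters only
  the whole-complex score `ligand_protein_energy`; the *per-residue*
  interaction energy is defined as vdW + electrostatics only, matching the
  convention of the MD analysis tooling this profiler follows.

The original framework's polarization and metal–ligand terms are not
implemented. Absolute agreement with any specific published force field
is therefore not claimed; the package's guarantees are structural
(closed-form limits, pair symmetry, exact decomposition conservation).

Default nonbonded cutoff: 12 Å, no switching function — energies are
reported per residue, not integrated over a periodic box. Pairs beyond
the cutoff contribute exactly zero, which is what makes a displaced
residue's profile column drop to exactly 0 after a contact-loss event.

## Binding free-energy decomposition

ΔG_bind = E_interaction + E_strain + ΔG_desolv + TΔS_rotors + E_induced-fit,
all in kcal/mol, costs entered as positive numbers, favourable terms
negative, so a binder has ΔG < 0. Components:

- **strain:** `max(0, E_pose − E_global-min)` of the conformer energies
  (the global-minimum conformer is an input, not searched for here).
- **desolvation:** Σ_atoms ASP(element) × SASA(atom), a solvent-accessible
  surface-area continuum surrogate with Eisenberg-style atomic solvation
  parameters. SASA is Shrake–Rupley (default probe 1.4 Å, 960 sphere
  points, Bondi-type radii), computed via biotite with per-atom radius
  overrides. A generalized-Born treatment would slot in behind the same
  interface but is out of scope.
- **rotor entropy:** n_rotors × fraction_constrained × 0.4 kcal/mol.
  The per-rotor constant is configurable; 0.4 sits in the middle of the
  0.3–0.6 range commonly used for fully immobilised rotors. Rotatable
  bonds are acyclic heavy–heavy single bonds whose both ends carry at
  least one further heavy neighbour, excluding amide C–N (detected as a
  C–N bond whose carbon carries a terminal oxygen).
- **conversion:** pIC50 = −ΔG/(ln 10·R·T) with R = 0.0019872
  kcal/(mol·K), T = 300 K, i.e. 1.373 kcal/mol per log unit; IC50 is
  treated as a proxy for Kd, consistent with how the packaged affinity
  table reports pIC50.

Pose ensembles are pre-filtered by the energy window: poses within
10 kcal/mol (default) of the lowest-energy structure are retained.

## Receptor-surrogate mQSAR

The published description of the quasi-atomistic surrogate method names
its ingredients but not their functional forms, so the following are this
package's committed design, isolated behind small constants and the
scenario abstraction:

- **Envelope.** Fibonacci sphere points at r_vdw + 1.4 Å per atom of the
  training poses' union, occluded points removed, survivors thinned to a
  minimum spacing (default 0.8 Å for display-quality envelopes; the QSAR
  benchmark uses a much coarser envelope, see below). Deterministic for a
  fixed input order.
- **Scoring.** Each particle interacts with its nearest ligand atom
  within 4.5 Å: E_p = T[label_p, class(atom)] · exp(−(d−3.0)²/2·1.0²),
  where T is a fixed 7×6 property-compatibility table (donor–acceptor
  −1.5, charge pairs −2.5/+2.0, hydrophobic contact −0.8, void/neutral 0,
  mismatches mildly repulsive). Atom classes are assigned from element,
  bonded hydrogens and partial charge (|q| ≥ 0.5 e → charged).
- **4D (poses).** Per-pose scores ΔG_i are combined with Boltzmann
  weights w_i from the conformer energies via
  ΔG = −RT ln Σ w_i exp(−ΔG_i/RT). Exact duplicate poses are collapsed at
  ensemble construction — an identical microstate listed twice must not
  double its statistical weight — which makes the prediction invariant
  under pose duplication and permutation.
- **5D (induced fit).** Six scenarios = envelope dilation of
  0.0–0.5 Å in 0.1 Å steps, implemented as a uniform offset on the
  particle–atom distances, with a linear penalty of 2.0 kcal/mol per Å.
- **6D (solvation).** Two scenarios, buried vs solvent-exposed site; the
  exposed scenario adds a fixed 0.5 kcal/mol incomplete-desolvation
  correction per pose.
- **Calibration.** Each model carries a linear map pIC50 = a·raw + b
  fitted by least squares on the training compounds; the raw score's
  absolute scale is not meaningful because the compatibility-table units
  are arbitrary.

### Genetic algorithm

Chromosome = one property label per particle plus the two scenario genes.
Selection is by tournament (size 4), recombination by uniform crossover
(rate 0.8), mutation per gene (rate 0.02, annealed from 0.15 at the start
of the run). Fitness = −RMSE(train) − 0.25·(1 − q²_LOO), where q²_LOO is
the closed-form leave-one-out r² of the linear calibration. Three
reliability mechanisms were added after plain generational GA proved
unreliable on fold-level retraining: (i) a memetic steepest-ascent
coordinate sweep applied each generation to the elite *and* to one random
individual (the latter keeps alternative basins alive); (ii) 10% random
immigrants per generation; (iii) a stall of 30 generations triggers a
soft restart (elite kept, population redrawn) instead of early
termination, so the configured generation budget is actually spent.
Defaults: population 400, 300 generations, family size 200. Everything is
driven by one `numpy` Generator, so a (seed, config) pair reproduces a
family bitwise.

The returned consensus family contains the *distinct* chromosomes within
0.05 fitness units of the best individual (clones of one optimum carry no
information; far-from-optimal members add only noise to the consensus
mean). Consensus predictions are the family mean with the population
standard deviation as the uncertainty estimate.

### Validation

- **q² (cross-validated r²)** = 1 − PRESS/SS_tot over held-out
  predictions, 5 folds by default, folds stratified by affinity with
  seeded shuffling. When a trainer is supplied the family is retrained on
  each fold's complement — the honest protocol; a pre-trained family can
  also be scored directly, which measures fit rather than predictivity
  and is documented as such.
- **Predictive r²** = 1 − Σ(pred−exp)²/Σ(exp−ȳ_train)² on the external
  test set, together with the fraction of compounds predicted within a
  factor of 10 (|Δlog10| ≤ 1.0, inclusive).
- **Y-scrambling** permutes the training affinities, retrains with a
  reduced GA budget and records the cross-validated q² per round; a real
  model's scrambled q² collapses to ≤ 0.
- **Consensus flags** accept a prediction only if the direct force-field
  score is favourable and the ligand does not prefer bulk water over the
  site (ties resolved toward binding); flags annotate rather than alter
  the predicted value.

## MD profiler

Site residues are defined once, from the first frame (all residues with
any atom within 8 Å of any ligand atom, waters excluded by default).
Defining the site per frame would change column identity mid-series;
fixing it keeps columns comparable and makes enlarging the cutoff purely
additive. Each profile row therefore sums exactly to the whole-site
vdW+electrostatic interaction energy of its frame. Hydrogen-bond
occupancy uses d(D,A) ≤ 3.5 Å and, when the donor carries a polar
hydrogen, θ(D–H···A) ≥ 120°; the first frame failing the criteria is
reported as the break point. MD execution itself is out of scope: the
profiler consumes multi-model PDB trajectories, and the simulation
protocol its outputs are designed around (TIP3P box +10 Å, 0.15 M NaCl,
minimization to 1.0 kcal/(mol·Å), NPT at 300 K, 24 ps relaxation) is
recorded as provenance metadata only. DCD/XTC readers are extension
points, not features.

## Synthetic data and what the benchmarks show

The generators exist because the experimental dataset behind the
published surrogate model (108 mannose-based FimH inhibitors, IC50
220 µM–2.4 nM) is only partially disclosed; its headline statistics
(q² = 0.805, predictive r² = 0.596, 23/24 test compounds within a factor
of 10) are consequently not desk-reproducible. The package instead
demonstrates the same *quality regime* on data whose ground truth is
known by construction.

- **Toy pocket:** three-atom pseudo-residues placed on a sphere of
  radius ≈ 7 Å around a small polar ligand, one residue flipped so its
  carbonyl oxygen faces the ligand hydroxyl at 3.2 Å (a ready-made
  donor–acceptor pair). Geometry is guaranteed clash-free (non-bonded
  inter-fragment contacts ≥ 2.2 Å), charges come from the
  electronegativity assigner, and every emitted structure parses,
  perceives bonds and yields a detectable ligand.
- **QSAR benchmark:** 40 random-walk ligands (5–9 heavy atoms from C/N/O,
  hydrogens on half the polar atoms), 3 rigid-body poses each, conformer
  energies U(0,6) kcal/mol, 70/30 train/test split. The ground-truth
  model is drawn on the envelope built from the training poses (the
  envelope must derive from poses, so a caller-supplied model is used
  as-is but the default truth is drawn after pose generation). Affinities
  are the truth's predictions, rescaled to a realistic lead-series spread
  (sd 1.2 pIC50 units centred at 7) plus optional Gaussian noise
  (log-normal in IC50). Draws whose raw prediction spread is below 0.4
  are rejected and redrawn — a truth without structure–activity variance
  benchmarks nothing but noise amplification.
- **Benchmark envelope resolution:** spacing 5.5 Å, giving roughly 5–10
  particles, i.e. ~3–5 training compounds per adjustable particle —
  the identifiable regime a sound QSAR requires. At display-grade
  resolutions (hundreds of particles for 28 training compounds) the label
  assignment is under-determined and any optimiser, genetic or otherwise,
  fits the training set while generalising at chance; that regime is a
  statement about over-parameterisation, not about this implementation.
- **Scripted trajectories:** Gaussian coordinate jitter per frame plus an
  optional event displacing one residue (or the ligand) rigidly outward
  from a given frame onward — emulating the kinetic instability of a
  docking-predicted hydrogen bond that breaks early in a simulation and
  never re-forms.

What passing these benchmarks shows: the GA reliably recovers a model
family equivalent to a hidden ground truth of matched capacity
(train RMSE ≤ 0.2 pIC50, fold-retrained q² ≥ 0.8, external r² ≥ 0.7
across generator seeds), the validation metrics behave (scrambling
collapses q² by far more than 0.5), and the profiler's decomposition and
event detection are exact. What it does not show: performance on real
chemistry — the synthetic ligands have no torsional strain, conformer
energies are independent of geometry, the pose generator is rigid-body,
and the ground truth shares the implementation's own functional form, so
the benchmark cannot detect model misspecification against nature.

## Numerical and interface choices

- PDB I/O is MODEL/ENDMDL-aware; CONECT records are ignored and bonds are
  re-perceived geometrically (d ≤ r_cov(i)+r_cov(j)+0.45 Å, Pauling-type
  radii, H–H never bonded). Frame times are 0-based ns from a configured
  snapshot interval (default 0.1 ns).
- Ligand detection: largest connected hetero component after excluding
  waters (HOH/WAT/TIP*/SOL) and single-atom residues (ions); ties break
  toward the lowest atom serial. This is a committed interpretation of
  "ligand-like"; it fails loudly on apo structures.
- Degenerate inputs raise typed errors (`PreconditionError`,
  `NoLigandError`, `UndefinedMetricError` on zero-variance test sets,
  `SingularityError` at r = 0, checksum failure on the packaged table).
- All stochastic operations take explicit integer seeds; derived seeds
  stay below 2³¹.
- The command-line tool is a thin layer over these functions: layered
  configuration (YAML file overridden by flags), the resolved config's
  SHA-256 hash and the seed logged on every run, exit code 2 for usage
  errors and 1 with a one-line reason for domain errors. Training and
  prediction share one code path, so a training compound pushed through
  its own family reproduces `family_predict` exactly.
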