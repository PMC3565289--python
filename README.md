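# mqsar

Receptor-surrogate multi-dimensional QSAR and per-residue MD interaction
profiling for protein–ligand complexes.

## What this package does

Two computational engines for structure-based ligand design, aimed at the
situation where a binding site is known but a fast, trainable affinity
model is needed:

1. **Binding-affinity estimation.** Each candidate ligand is represented by
   an ensemble of up to 8 docking poses (the 4D axis of the QSAR). The
   binding site is replaced by a *receptor surrogate*: an envelope of
   property-labelled virtual particles (hydrophobic, H-bond donor/acceptor,
   charged, neutral, void) wrapped around the union of the training poses.
   A genetic algorithm evolves a *family* of such models against
   experimental affinities, additionally selecting per-model induced-fit
   (5D) and solvation (6D) scenarios. Predictions are consensus scores —
   family mean ± sd on the pIC50 scale (pIC50 = −log10 IC50 [M]) — and are
   cross-checked by a direct force-field score and a water-reference
   comparison. The binding free energy is decomposed as

   ΔG_bind = E_interaction + E_strain + ΔG_desolvation + TΔS_rotors + E_induced-fit

   with pIC50 = −ΔG / (ln 10 · R · T); desolvation is a SASA × atomic
   solvation parameter surrogate, and the rotor-entropy term charges a
   fixed cost (default 0.4 kcal/mol) per rotatable bond immobilised on
   binding. Model quality is reported as cross-validated q²
   (1 − PRESS/SS_tot with per-fold retraining), external predictive r² and
   a Y-scrambling control.

2. **MD interaction profiling.** Given a multi-model PDB trajectory of a
   complex, the profiler identifies the ligand, fixes the binding-site
   residues (all residues within 8 Å of the ligand, from the first frame)
   and computes the ligand–residue interaction energy — the sum of the
   Lennard-Jones van der Waals and Coulomb electrostatic terms — for every
   frame and residue. The time × residue matrix is written as a CSV time
   series, residues can be overlaid across simulations in cumulative
   plots, hydrogen-bond occupancy (3.5 Å / 120° criteria) with
   first-break times is reported, and a VMD visualization-state file can
   be generated for the extracted frames.

Because the experimental datasets this class of models was built on are
not public, the package ships a first-class synthetic-data module: toy
pockets, scripted trajectories with contact-loss events, and QSAR datasets
generated from a *known* surrogate model, so that ground-truth recovery,
Y-scrambling collapse and profiler event detection are all testable
end-to-end. A packaged 52-compound affinity table (experimental/predicted
pIC50 and residuals for a published FimH antagonist series; structures not
disclosed) is included as a checksummed fixture.

## Worked example

```python
import numpy as np
from mqsar import (GAConfig, ga_train, family_predict, cross_validated_r2,
                   make_trainer, predictive_r2)
from mqsar.synthetic import simulate_qsar_dataset

# 40 ligands, 3 poses each, affinities computed from a hidden ground-truth
# surrogate model (no noise)
dataset, truth, manifest = simulate_qsar_dataset(
    n_ligands=40, poses_per_ligand=3, noise_sd=0.0, seed=1)

config = GAConfig(population=100, generations=100, family_size=20)
family = ga_train(dataset, config, seed=1001)

q2 = cross_validated_r2(make_trainer(config), dataset, n_folds=5, seed=1)
test = dataset.subset("test")
preds = [family_predict(family, e.ensemble)[0] for e in test]
train_mean = np.mean([e.exp_pic50 for e in dataset.subset("train")])
r2, frac10 = predictive_r2(preds, [e.exp_pic50 for e in test], train_mean)
print(f"q2 = {q2:.3f}  r2_pred = {r2:.3f}  within 10x: {frac10:.2f}")
```

Output:

```
q2 = 1.000  r2_pred = 1.000  within 10x: 1.00
```

meaning the genetic algorithm recovered a model family equivalent to the
hidden ground truth: cross-validated q² ≈ 1 on the 28 training compounds
and perfect external prediction of the 12 held-out compounds, every one
within a factor of 10 in IC50 (1.0 pIC50 unit). With scrambled labels the
same protocol collapses to strongly negative q² — the standard evidence
that the model learns structure–activity signal rather than noise.

The same pipeline is available from the shell:

```sh
mqsar synth qsar --seed 1 --out data/
mqsar train --data data/ --population 100 --generations 100 --out family.json
mqsar validate --data data/ --folds 5 --out report.json
mqsar synth traj --event-residue 2 --event-frame 5 --out traj.pdb
mqsar profile run --traj traj.pdb --charges traj_charges.csv --out prof/
mqsar profile hbond --traj traj.pdb --donor 32 --acceptor 0
```

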