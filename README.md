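# alfkrig

Atomic-local-frame features and kriging models for atomic multipole
moments in peptides.

## What this is for

Multipolar machine-learning force fields describe each atom's
electrostatics by atom-centred multipole moments Q_lm (rank 0–4; rank 0 is
the atomic charge) obtained by integrating an *ab initio* electron density
over atomic basins.  Those moments depend strongly on molecular geometry,
and the practical question for anyone parameterizing peptides is how to
learn that dependence once and reuse it everywhere: across conformations,
across tripeptides with different neighbors, and from small training
molecules to long chains.

`alfkrig` implements that stack for computational chemists:

- **Features.**  Each conformation becomes 3N−6 rotation-invariant
  descriptors seen from a per-atom local frame (ALF) spanned by the atom
  and its two highest-priority bonded neighbors.  Restricting to a
  conserved fragment (e.g. the 10-atom unit around a central alanine's
  alpha carbon: 3×10−6 = 24 features) makes the description — and any
  model built on it — portable to every molecule containing the fragment.
- **Targets.**  Real spherical-tensor moments (25 per atom) are rotated
  into the same local frames with exact rank-l rotation matrices, so
  targets are orientation-free too.
- **Model.**  Ordinary kriging,

      ŷ(x*) = μ̂ + Σᵢ aᵢ φ(x* − xᵢ),   φ(d) = exp(−Σⱼ θⱼ|dⱼ|^{pⱼ}),

  with a = R⁻¹(y − 1μ̂) and μ̂ the generalized least-squares mean; the
  kernel hyperparameters (θ, p) are found by a seeded particle swarm
  maximizing the concentrated log-likelihood.  The predictor interpolates
  its training data and reverts to μ̂ far from it — which makes **mu-fix
  transfer** (replacing μ̂ with a related system's mean, shifting every
  prediction by the difference) a one-number model transfer.
- **Grouping and routing.**  Neighbor residues are classed A–E by how much
  they perturb a central residue's alpha-carbon charge (ΔQ00, threshold
  0.005 au) and kinetic energy (ΔT, threshold 10 kJ/mol), with proline
  always its own group; the packaged evidence table for all 20 canonical
  residues ships with the package.  Routing then maps any of the
  20³ = 8000 tripeptides onto 5×20×5 = 500 model keys.
- **Synthetic data.**  Capped peptide templates (Ace-…-NMe), bounded
  conformer distortion (no bond or valence angle ever beyond ±15% of its
  template value), paired tripeptide families sharing an identical
  central-fragment geometry per frame, and analytic "moment surfaces" with
  known ground truth — so the whole pipeline runs and is tested without
  any electronic-structure package.

See `docs/methods.md` for the models, conventions and design decisions in
detail.

## Worked example

Generate 300 distorted trialanine conformers with a synthetic charge
surface over the central fragment, train a kriging model for the central
alpha carbon, and inspect the neighbor grouping:

```bash
$ alfkrig simulate --template AAA --n-frames 300 --seed 4 --out-dir demo/sim
300 frames of AAA written to demo/sim

$ alfkrig train --xyz demo/sim/frames.xyz --moments demo/sim/moments.csv \
      --atom 18 --fragment-yaml demo/sim/fragment.yaml \
      --n-train 240 --seed 4 --out-dir demo/train
model written to demo/train/model.json (60 PSO iterations)

$ cat demo/train/training_log.json
{
 "n_input": 300,
 "n_remaining": 300,
 "n_train": 240,
 "n_test": 60,
 "pso_iterations": 60,
 "log_likelihood": 2115.5452752243136,
 "test_mean_abs_error": 5.742641736499373e-05
}
```

Atom 18 is the central residue's alpha carbon (`demo/sim/fragment.yaml`
lists the fragment's 0-based indices).  All 300 frames pass the net-charge
and integration-error filters, 240 train the model, and the 60 held-out
conformers are predicted with a mean absolute error of 5.7e-05 au — about
0.1% of the synthetic surface's range, i.e. the model has learned the
surface rather than memorized it.

```bash
$ alfkrig group --out-dir demo/groups
5 groups over 20 residues written to demo/groups

$ head -4 demo/groups/groups.csv
residue,q00,T,dq00,dT,group
A,0.5506,98288.0,0.0,0.0,A
C,0.5481,98302.46,0.0024,14.46,B
D,0.5604,98309.59,0.0098,21.59,D
```

Cysteine barely moves the central charge (ΔQ00 = 0.0024 au < 0.005) but
shifts the kinetic energy by 14.46 kJ/mol (> 10), so it lands in group B;
aspartate crosses both thresholds and lands in D.

The same operations are available as a library (`ALFFeaturizer`,
`KrigingRegressor`, `reduce_to_fragment`, `group_table`, `route_model`,
…) with scikit-learn-style fit/transform/predict semantics.

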