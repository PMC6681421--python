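# Methods

This note documents the models and procedures implemented in `alfkrig`,
their assumptions, the parameters that matter, and the design choices made
where several reasonable options existed.

## The modelling problem

Atom-centred multipole moments obtained by partitioning an *ab initio*
electron density into atomic basins (quantum chemical topology) are highly
sensitive to molecular geometry.  `alfkrig` implements the machinery needed
to learn that geometry dependence with interpolating Gaussian-process
models (ordinary kriging), in a way that transfers between peptides:

1. geometries are described by rotation-invariant features seen from a
   per-atom local frame;
2. moments are rotated into the same local frame, so targets are also
   orientation-free;
3. features can be restricted to a conserved molecular fragment, so one
   model serves every molecule containing that fragment;
4. neighbor residues are classed into influence groups so a handful of
   models covers the full tripeptide space;
5. a trained model can be transferred to a related system by replacing its
   global mean (the "mu fix").

The package deliberately contains no electronic-structure code.  Atomic
moments enter through a documented CSV schema, and a synthetic-data module
supplies geometry ensembles and analytic ground-truth "moment surfaces" so
every code path can be exercised and tested on its own.

## Atomic local frames and features

For atom *i*, the local frame (ALF) is spanned by *i* and its two
highest-priority bonded neighbors.  Priority is a simplified
Cahn–Ingold–Prelog rule: atomic number first, then the summed atomic
numbers of the candidate's own neighbors (one bond out), then lowest atom
index.  The full CIP cascade is unnecessary for the backbone and sidechain
atoms in scope (the two rules agree there) and the index tie-break makes
the ordering total and deterministic — important because kriging requires
one frozen feature schema across a trajectory.  Atoms with a single bond
(e.g. an amide hydrogen) borrow the best neighbor of their x-axis atom as
the third frame-defining atom.

The frame is orthonormalized Gram–Schmidt style: local x along
*i* → x-axis atom, local y in the plane of the three atoms, z = x × y.
Collinear defining atoms (within 1e-6 rad) are a hard error.

A conformation of an N-atom molecule becomes 3N−6 numbers: the two ALF
bond distances and the enclosed angle, followed by spherical polar
coordinates (r, θ, φ) of every remaining atom in ascending index order
(θ ∈ [0, π] from local z; φ ∈ (−π, π] by atan2).  Distances are in
ångström, angles in radians.  Fragment features recompute the same
construction over the fragment's atoms only (3n−6 values); recomputation
and column masking coincide whenever the ALF atoms lie inside the
fragment, which the code enforces.  Rigid-motion invariance to 1e-8 is
property-tested over random rotations and translations.

Bonds are inferred from covalent radii (Cordero consensus values) with a
scale factor of 1.2; a disconnected graph is an error because an ALF needs
a well-defined molecular neighborhood.

## Multipole moments and rotation

Moments are real spherical-tensor components Q_lm, ranks 0–4
(1+3+5+7+9 = 25 per atom), stored in m = −l…+l order, atomic units
throughout.  The Condon–Shortley phase is folded into the real harmonics,
so the rank-1 basis (m = −1, 0, +1) carries the Cartesian directions
(y, z, x).  Global-frame moments are rotated into an atom's ALF with the
orthogonal rank-l matrices D_l built by the standard recursion on rank
from D_1 (the Ivanic–Ruedenberg construction); D_1 is the Cartesian
rotation re-expressed in harmonic ordering.  The implementation is checked
in the tests against an independent numerical oracle that projects rotated
harmonics (built directly from scipy's complex spherical harmonics) onto a
random angular grid; agreement is at machine precision, far inside the
1e-6 tolerance asserted.  Rank-0 components are untouched by rotation and
per-rank Euclidean norms are conserved to 1e-10 by orthogonality.

Moments from other software may use a different sign/ordering convention
for the m ≠ 0 components; such data must be permuted into the documented
ordering on ingestion.

## Ordinary kriging

The predictor is ŷ(x*) = μ̂ + Σᵢ aᵢ φ(x* − xᵢ) with the generalized
exponential kernel φ(d) = exp(−Σⱼ θⱼ |dⱼ|^{pⱼ}), per-feature widths
θⱼ > 0 and exponents pⱼ ∈ [1, 2].  For fixed hyperparameters,
μ̂ = (1ᵀR⁻¹y)/(1ᵀR⁻¹1) and a = R⁻¹(y − 1μ̂), solved through one Cholesky
factorization of the correlation matrix R (never an explicit inverse).
Hyperparameters maximize the concentrated log-likelihood
−n/2·ln σ̂² − ½·ln det R with σ̂² = (y−1μ̂)ᵀR⁻¹(y−1μ̂)/n, verified in the
tests against a brute-force implementation (explicit inverse and
determinant) for n ≤ 6.

*Nugget.*  A diagonal regularizer (default 1e-10, escalated ×10 to at most
1e-6 on factorization failure, logged) keeps R positive definite when
distorted conformers nearly coincide.  The predictor then passes through
each training point up to nugget·|aᵢ|; tests assert interpolation at this
nugget-limited tolerance.  Far from all training points the prediction
reverts to μ̂, which is what makes the mean meaningful for transfer.

*Search.*  A seeded global-best particle swarm optimizes
(log₁₀θ ∈ [−4, 2], p ∈ [1, 2]) with the standard constriction constants
(inertia 0.729, cognitive = social = 1.494).  Defaults are 20 particles,
at most 60 iterations, early stop after 12 stagnant iterations at 1e-8
relative tolerance.  These sizes were chosen for the smooth, low-noise
surfaces in scope, where the likelihood landscape is benign and the swarm
converges in tens of iterations; they make an 800-point, 24-feature
training run take on the order of a minute.  Rougher real-data surfaces
may warrant more particles and iterations, at linear cost in both.  The
condensed per-feature |Δ| table is precomputed once per training set, so
each likelihood evaluation costs one exponentiation pass plus one
Cholesky.

*Normalization.*  Features are min-max scaled to [0, 1] column-wise using
training rows only (test rows may fall outside); a constant column keeps
unit scale with a logged warning.  Min-max was preferred over z-scoring
because bounded features match the fixed θ search box; z-scoring can be
applied upstream by the caller if desired.  Targets are not scaled — the
moment values in scope are already O(1) in atomic units.

*Mean transfer (mu fix).*  `mu_fix(mu_new, mode="shift")` replaces μ̂ and
keeps the weights, displacing every prediction by exactly
mu_new − μ̂_old; this is the faithful reading of transferring a model by
correcting its background value, and it is exact for a target that differs
by a constant.  A `refit` mode that also recomputes a = R⁻¹(y − 1·mu_new)
is provided because the algebra admits either choice; refit preserves
interpolation of the *original* targets and differs from shift only away
from the training points.  Shift is the default.

*Targets.*  One model per (atom, rank, component), matching the
one-output-per-model structure of the predictor.  Kinetic energy is used
only as grouping evidence, never as a kriging target here.

## Dataset assembly

Frames are filtered before training: a frame is dropped if its molecular
net charge deviates from the expected value by more than 0.001 au
(default; the expected value is 0 for neutral peptides) or if its
integration-error diagnostic L(Ω) exceeds a threshold (default 0.001 au —
a config-exposed choice, since only the charge tolerance has a canonical
value).  A frame failing both checks counts under the charge removal; the
report's counts always conserve.  The default split reserves 800 rows for
training, uniformly at random by seed, with the remainder for testing.

## Neighbor-residue grouping and routing

The packaged evidence table lists, for each residue X in the AAX series
(alanine–alanine–X, identical backbone geometry), the central alpha
carbon's charge Q00 (au) and kinetic energy T (kJ/mol) together with the
tabulated absolute differences ΔQ00, ΔT against the AAA reference.  The
grouping criteria are

| ΔQ00 < 0.005 au | ΔT < 10 kJ/mol | group |
|---|---|---|
| yes | yes | A |
| yes | no | B |
| no | yes | C |
| no | no | D |

with proline unconditionally group E.  Thresholds printed as strict
inequalities leave the exact boundary unassigned; the implementation uses
`<` on the low side and `>=` on the high side so the criteria partition
the plane (no tabulated residue sits on a boundary, so this choice does
not affect the reference regrouping).  The tabulated Δ columns derive from
unrounded source values and are not always equal to the difference of the
rounded Q00/T columns at the last digit (glycine is the clearest case);
the table is therefore grouped on its tabulated deltas, while
`deltas_vs_reference` recomputes |q00 − q00_ref|, |T − T_ref| for user
data.  Deltas are absolute values: tyrosine's charge lies *below* the
reference yet its tabulated ΔQ00 is positive.

Routing maps a tripeptide XYZ to the key (group(X), Y, group(Z)):
20³ = 8000 tripeptides collapse to 5 × 20 × 5 = 500 keys.  Registries are
side-symmetric by default (a missing key falls back to the flank-swapped
key), reflecting that the side on which a flank is substituted has little
effect on the central residue; this is overridable.

## Synthetic data

*Templates.*  Capped chains Ace-(residues)-NMe are constructed from
idealized internal coordinates (standard equilibrium bond lengths and
angles, extended backbone φ = −135°, ψ = 135°) by natural-extension
reference-frame placement.  The residue library covers glycine, alanine
and valine — enough for the template families used throughout (ALA, AAA,
GAG, GAA, VAA, VAV).  Trialanine is 42 atoms; its central-residue fragment
(N, H, Cα, Hα, Cβ + 3H, C, O) is 10 atoms.  Templates are idealized, not
energy-minimized: all in-repo training targets are analytic surfaces, not
physical charges, so template realism matters only through connectivity
and rough geometry.

*Distortion.*  Conformers are generated by perturbing the internal
coordinates along a spanning tree of the bond graph with per-coordinate
uniform draws, then rebuilding Cartesians.  The hard guarantee is that no
bond length or valence angle in any emitted frame deviates by more than
±15% (defaults) from its template value; every frame is verified against
the full bond/angle list (not just the tree coordinates), checked for
atom clashes (< 0.5 Å non-bonded) and for unchanged inferred connectivity,
and rejected/redrawn on violation (at most 100 attempts).  Primary angle
draws use 60% of the bound as an internal margin so that secondary angles
— those between two dihedral-placed substituents — rarely trip the
verifier; dihedrals are drawn within ±8° by default (they carry no
fractional guardrail, since a fraction of a dihedral is not
scale-meaningful).  True normal-mode sampling would need a Hessian and is
out of scope; the uniform scheme preserves the one quantitative constraint
that matters for the feature ranges.

*Paired systems.*  `make_paired_systems` builds tripeptide families
(e.g. GAG/GAA/AAA/VAA/VAV) in which, per frame index, every system shares
the identical draw for every central-residue internal coordinate while
flanks are drawn per system.  Because each central-fragment atom is placed
relative to atoms whose relative geometry is itself determined by shared
coordinates, the fragment's internal geometry — and hence its 24 features
— agree across systems to floating-point precision (asserted at 1e-8).
Central draws are pre-validated against the center's own internal angle
bounds (flank redraws cannot repair those) and then frozen for the frame.

*Surfaces.*  Ground truth comes from analytic forms over feature vectors
(linear, Gaussian bump, sum of cosines) with coefficients either supplied
or calibrated to an observed feature sample (`SurfaceSpec.from_features`
places the bump center inside the sampled cloud and sets its width from
the median distance, so the surface varies meaningfully whatever the
feature units).  Observations are ground truth plus seeded Gaussian noise;
truth is always returned separately, so recovery errors are measured
against the noise-free surface.

What the synthetic route does *not* emulate: real charge surfaces are not
analytic functions of 24 coordinates (they feel the whole molecule and its
electronics), distorted conformers are not Boltzmann-weighted, and no
hydrogen-bonding or long-range polarization structure is present.  Passing
recovery tests therefore demonstrates the correctness of the pipeline and
the interpolation machinery, not the attainable accuracy on quantum-
chemical data.

## Problem sizes and numerical choices

The surface-recovery study (tests and `scripts/acceptance.py`) uses 1000
distorted trialanine conformers — 800 for training, 200 held out — over
the 24 fragment features, with a seeded Gaussian-bump surface; held-out
RMSE is reported as a percentage of the noise-free surface range and is
required to stay below 5%.  Typical runs land near 2%.  The grid-
projection oracle uses 400 random directions per rank.  Tolerances: ALF
orthonormality 1e-10, feature invariance 1e-8, rank-norm conservation
1e-10, rotation-oracle agreement 1e-6 (observed: ~1e-15), brute-force
likelihood agreement 1e-8.

## Known limitations

- The residue library covers G/A/V sidechains only; other residues can be
  routed and grouped but not built as synthetic templates.
- Kriging cost is cubic in training rows; the implementation is dense and
  single-threaded.
- Model serialization stores the full training set in JSON — simple and
  auditable, but not compact for large models.
- The CSV moment schema is the only ingestion path; parsers for specific
  integration programs' native outputs are out of scope.
- Grouping quality is inherited from the packaged evidence table; the
  package makes no claim that those five groups are optimal.
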