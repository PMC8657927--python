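# Methods

This note records the models implemented in `grindqsar`, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the numerical conventions a user should know before trusting
or extending the results.

## Activity arithmetic and curation

pIC₅₀ is always on the molar scale, pIC₅₀ = −log₁₀(IC₅₀[µM]·10⁻⁶), and
LipE = pIC₅₀ − clogP. Published activity tables for this compound family
mix µM- and molar-scaled potency columns; the LipE arithmetic only
reconciles on the molar scale, so that is the package-wide convention.
clogP is always an input column — lipophilicity prediction is out of scope.

The activity threshold (default 160 µM) is a property of the dataset's
activity landscape, not of the method, and is exposed as a parameter.
Curation removes fragments below 200 Da and connectivity duplicates
(canonical SMILES when the structure sanitizes, otherwise a deterministic
Weisfeiler-Lehman-style hash over element/bond-order neighbourhoods). Note
that connectivity-keyed deduplication deliberately ignores geometry: two
conformers, or two synthetic compounds built from the same class template,
are duplicates.

Template selection implements the oral-drug rule (clogP between 2 and 3,
LipE above 5). When no in-range compound reaches the LipE bar the best
in-range LipE wins anyway and the relaxation is flagged — the canonical
template of this compound family (clogP 2.71, LipE 4.6) is exactly such a
case.

The diverse split is MaxMin selection on internally standardized
descriptors: a seed-chosen start, then repeatedly the compound with the
largest minimum distance to the selected set. Ties break on the lowest
input index; the split is a pure function of (descriptor table, fraction,
seed).

## Interaction fields

Each probe's energy at a grid point is the sum over atoms of

- a 12-6 Lennard-Jones term, `eps_ij [(rmin_ij/r)^12 − 2 (rmin_ij/r)^6]`,
  with geometric-mean well depths and additive radii (Lorentz-Berthelot);
- electrostatics with a distance-dependent dielectric, ε(r) = 4r, i.e.
  `332.06 q_p q_a / (4 r²)` kcal/mol — note the resulting 1/r² asymptote;
- a 6-4 hydrogen-bond well `eps_hb [2 (r0/r)^6 − 3 (r0/r)^4] cos²θ` acting
  only between complementary partners (donor probe ↔ acceptor-flagged atom
  and vice versa), where θ is measured against the atom's idealized
  lone-pair/N-H axis — the outward unit vector away from the mean bonded-
  neighbour position (isotropic when the atom has no neighbours).

The published force field behind the original descriptors is proprietary.
The per-element table shipped here (`mif.ELEMENT_PARAMS`, `mif.HB_WELL`) is
a small, editable surrogate of the same functional shape; well depths were
set once so that each probe's cutoff (−0.75, −0.5, −2.6, −4.2 kcal/mol for
TIP, DRY, O, N1) bites in the intended region: hydrogen-bond wells reach
−4…−6 kcal/mol, hydrophobic wells −0.6…−1. The downstream method consumes
the field only through node filtering and node-energy products, which this
surrogate preserves. Every pair term is clamped symmetrically at
±5 kcal/mol: without the negative-side clamp, the 1/r² electrostatics and
the hydrogen-bond well diverge inside atomic cores and the deepest "wells"
of a field would all sit inside atoms.

The TIP (shape) probe has no published functional form. The surrogate: the
molecular solid is where the TIP steric LJ field exceeds +0.5 kcal/mol;
shell voxels are solid voxels exposed through a face or edge; each scores
−1 times a convexity weight, the fraction of its 26-neighbourhood outside
the solid min-max rescaled over the shell. Convex protrusions — ring edges,
terminal substituents — score most negative, which is the role steric
hotspots play in the correlograms. The surrogate is isolated behind
`ProbeSpec` and `tip_field` so it can be swapped.

Grids are axis-aligned bounding boxes, 0.5 Å spacing and 5 Å margin by
default. Because an axis-aligned grid is not rotation-invariant, the
descriptor pipeline first puts each molecule into a canonical inertial
frame (principal axes of the coordinates; each axis oriented so the third
moment is positive, falling back to the farthest atom; right-handedness
enforced last). Descriptors are then invariant under any rigid motion of
the input to float precision — the defining alignment-independence
property, asserted at 1e-6 in the tests.

## Node filtering and correlograms

Node selection keeps grid points below the probe cutoff, then greedily
adds the candidate maximizing `(1−w)·|E|/|E|max + w·d_min/d_max`
(w = 0.5), starting from the global minimum — an energy/spread trade-off in
the spirit of the AMANDA discretization, capped at 100 nodes per probe.

MACC2 encoding stores, per probe pair and per 0.4 Å distance bin, the
maximum signed node-energy product (two favourable nodes give a positive
value); self-pairs are excluded in auto blocks; bin b covers
[b·0.4, (b+1)·0.4) Å and the default range is 24 Å (60 bins × 10 blocks).
The 0.4 Å width reproduces the reported interpretation intervals (6.4–6.8,
6.8–7.2, 7.6–8.0, 10.4–10.8 Å are consecutive bins). The published
CLACC procedure is not restated anywhere accessible; the implementation
starts from MACC2 and, among node pairs within 90% of each compound's bin
maximum, iteratively re-chooses each compound's pair to minimize the
variable's coefficient of variation across compounds (≤ 10 sweeps). CLACC
values never exceed the MACC2 value for the same compound and bin. MACC2
is the default encoder.

Every nonzero variable records its provenance (contributing node pair,
distance, energies) for hotspot interpretation, and the descriptor matrix
keeps a mask of dropped all-zero columns so train/test matrices stay
conformable.

## PLS, cross-validation and FFD

The regressor is PLS1 (NIPALS). `PLSQsar` delegates the single fit to
scikit-learn's `PLSRegression` and re-expresses coefficients and intercept
on the raw-variable scale; an internal NIPALS path, verified to agree with
scikit-learn to 1e-15, powers the cross-validation loops and FFD row
models, where fit count matters. Centering-only is the default (the GRIND
convention — variables share an energy-product scale); unit-variance
scaling is a flag. For data produced by the synthetic generator the
analyses in this package set `scale=True`: the surrogate fields span a
wider energy range across probes (hydrogen-bond products ~25 kcal²/mol²
versus hydrophobic products ~1), and centering-only PLS measurably assigns
the small-scale blocks zero weight.

Q² = 1 − PRESS/SS_tot with leave-one-out or seeded leave-many-out groups
(default group size 5, the leave-five-out convention); SDEP = √(PRESS/n).
Latent-variable choice maximizes Q² (ties to fewer LVs) and warns when
R² − Q² exceeds 0.3, the usual overfitting flag.

FFD variable selection, per cycle: append ⌈0.2p⌉ dummy (placebo)
variables; build a two-level inclusion design from a Sylvester Hadamard
matrix (randomized column assignment and sign flips, plus the
complementary foldover — between ~p and ~2p distinct orthogonal rows
doubled); score each row's included-variable PLS model by leave-one-out
SDEP; estimate each variable's effect as mean SDEP over excluded rows
minus mean SDEP over included rows; remove a variable when its effect is
more negative than the mean absolute dummy effect. An orthogonal design is
essential here: with random balanced columns the large effects of genuinely
informative variables leak, at n~2p rows, into every other column's
estimate and both retention and noise removal degrade to chance — this was
measured, not assumed, during development.

## Validation metrics

MCC, sensitivity (TPR) and specificity (TNR) follow the standard confusion
forms; metrics with vanishing denominators are reported as undefined
(`None`), never as 0. External predictivity uses Roy's
r_m² = r²·(1 − √(max(r² − r₀², 0))) with r₀² the coefficient of
determination of the through-origin regression of observed on predicted
(slope Σop/Σp²); 0.5 is the conventional bar. The applicability domain is
the standardization approach: s_ki = |x_ki − μ_i|/σ_i against the training
distribution; a compound is inside if max s ≤ 3, an outright outlier if
min s > 3, and otherwise decided by S_k = mean(s) + 1.28·sd(s) ≤ 3
(1.28 = the 90th-percentile normal quantile). Constant training columns
are dropped with a warning.

## Pharmacophore models and screening

A model is an ordered feature list (hydrophobic, acceptor, donor; per-
feature radii kept for reporting) plus a symmetric distance matrix and one
global tolerance (1.5 Å). Matching is pure distance geometry: backtracking
over kind-preserving injective assignments with pairwise pruning
(|d_mol − d_model| ≤ tolerance), deterministic order, first admissible
assignment returned, fit score 1 − RMS(deviations)/tolerance. Feature
direction vectors, exclusion volumes and the original scoring function are
not reproduced (a schema flag is reserved for exclusion volumes); models
communicate exactly what their distance matrices say. Ten models derived
from a ryanodine template ship as packaged JSON; their matrices are
printed values and one or two bend the triangle inequality slightly, which
the loader tolerates with a warning. Screening stops at the first matching
conformation per compound, so it is invariant to conformer order.

Feature perception: pre-labelled atom flags take precedence (the synthetic
compounds are flagged); otherwise donors are O/N bearing hydrogen,
acceptors are oxygens and under-substituted nitrogens, and hydrophobic
points are ring-system centroids plus centroids of heteroatom-free
aliphatic carbon clusters of at least two atoms.

## The synthetic generator

The generator emulates the statistical structure of the study dataset, not
its chemistry. Defaults: 40 compounds; class weights 0.30/0.15/0.075/0.475
(mirroring a 12/6/3/19 composition); IC₅₀ range 0.0029–20,000 µM; activity
threshold 160 µM; observation noise 0.3 pIC₅₀ units; motif fraction 0.5;
15–60 atoms per compound.

Geometry. Compounds of a class share a scaffold template (a compact
random-walk skeleton attached to a six-carbon ring with a flagged
hydrophobic centre) plus 0.12 Å positional jitter — congeneric series
share scaffolds, and this keeps irrelevant correlogram variation low-rank.
Motif-bearing compounds place two acceptor and two donor atoms at the
five-feature template geometry (acceptors 2.62/4.79 Å and donors
5.56/7.68 Å from the hydrophobic centre, embedded from the printed distance
matrix to 0.004 Å) with 0.05 Å jitter, plus a second ring 6.6 Å away —
actives in this family are ring-rich. Non-motif compounds carry the
anti-motif: an acceptor pair ~9.5 Å apart and a donor pair ~2.6 Å apart
hung a few Å from the core, the arrangements the model should penalize.
Feature partial charges are drawn per compound from uniform ranges
(acceptors −0.62…−0.28 e, donors +0.14…+0.36 e), so hydrogen-bond well
depths — and with them the correlogram products — vary continuously across
a series the way substituent effects do; motif ring compactness varies
similarly (radius 1.25–1.55 Å). One seed stream per dataset is split into
named substreams (geometry, charges, labels, noise) so changing one does
not shift the others.

Activities. Noiseless pIC₅₀ is a sparse linear function of the dataset's
own correlogram variables: one variable per informative block — DRY-DRY,
DRY-O, DRY-N1, DRY-TIP contribute positively; short-range O-O and N1-N1
negatively — chosen as the column that best tracks the block's planted
continuous driver (feature charges, ring compactness) among columns
populated in ≥ 35% of compounds at node separations ≥ 2 Å (sub-2 Å bins
are grid-discretization artifacts). Contributions are equal on the
standardized scale and affinely mapped into the configured potency range;
Gaussian noise is added; IC₅₀ is back-transformed. The coefficient map,
intercept and noiseless values are stored in `SyntheticTruth`. An explicit
`true_beta` overrides the auto-selection.

What passing tests do and do not show. The generator reproduces the
*structure* the analysis assumes — scaffold-clustered geometry, planted
distance motifs, activities linear in correlogram variables with known
sparse support — so green tests demonstrate that the pipeline recovers
signals of that structure at the study's dimensions (n = 40, ~500
variables). They do not show anything about real conformer quality,
protonation, tautomers, charge assignment, or whether real inhibitor
activities are linear in GRIND variables.

## Problem sizes and known limitations

- Test-suite problem sizes: the full-pipeline regime property regenerates
  8 datasets of 40 compounds (fields at the default 0.5 Å spacing); the
  planted-truth FFD, six-variable sign-recovery and screening-MCC
  properties run 25 seeds each at matrix level or without field
  computation. The package's regime statistics (Q² ≈ 0.7–0.8 after two FFD
  cycles, screening MCC ≈ 0.6–0.9) are reproduced by
  `scripts/acceptance.py`.
- Per-variable identifiability has a hard limit at these dimensions: with
  ~500 variables and 40 compounds the chance-correlation mass of
  uninformative columns exceeds the informative correlation mass, so no
  LV-2 model — and therefore no FFD effect estimate — can single out every
  planted column when near-duplicates (adjacent distance bins populated by
  grid quantization) exist. The pipeline property therefore asserts the
  cross-validation regime plus sign-correctness of the retained planted
  variables, and literal all-variable sign recovery is asserted where it
  is identifiable (6 informative among 120).
- Electrostatics use a distance-dependent dielectric (1/r² decay), no
  solvent model, no polarization; hydrogen-bond directionality is a cos²
  factor around a single idealized axis.
- The TIP probe and CLACC encoder are documented surrogates for
  unpublished algorithms.
- Pharmacophore matching ignores exclusion volumes and feature directions;
  scores are not comparable to any proprietary fit function.
- Degenerate inputs: empty node sets encode to all-zero descriptors;
  constant y is rejected; constant descriptor columns are dropped from the
  applicability domain with a warning; undefined metrics surface as
  `None`.
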