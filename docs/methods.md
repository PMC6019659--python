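# Methods

This note records the models behind `ssforge`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Candidate scoring model

**Descriptor.** A candidate pair is described by 44 scalars: the 36
cross-residue distances over {C, O, N, Cα, Cβ, Sγ} × {C, O, N, Cα, Cβ, Sγ}
(intra-residue distances are nearly constant across proteins and are
excluded), the three dihedral angles between corresponding planes C/Cα/Cβ,
Cα/Cβ/N and C/Cα/N of the two residues (normals oriented by the stated atom
order, angle mapped to [0°, 180°]), and the five bridge torsions
χ1 = N–Cα–Cβ–Sγ, χ2 = Cα–Cβ–Sγ–Sγ′, χ3 = Cβ–Sγ–Sγ′–Cβ′ and their primed
mirrors on the second residue. All torsions follow the IUPAC sign
convention; the implementation was cross-checked against an independent
dihedral routine and against the chemical-component ideal cysteine, so
generated helices are right-handed and placed Cβ atoms are L-configured
(improper torsion C–N–Cα–Cβ = −122.6°).

**Virtual mutation.** Non-cysteine positions are mutated in silico: Cβ is
taken from the experimental structure when present (glycine gets a virtual
Cβ from ideal tetrahedral geometry), and Sγ is placed at Cβ–Sγ = 1.81 Å,
Cα–Cβ–Sγ = 114.0° over a χ1 rotamer grid of {−60°, +60°, 180°}. Among the
9 rotamer combinations the one minimizing |d(Sγ–Sγ) − 2.05 Å| is scored —
preferring near-ideal bond lengths over raw minimum distance, since an
Sγ–Sγ contact well under bond length is as unbuildable as one well over it.
All ideal-geometry constants live in one table (`constants.py`) and come
from standard stereochemistry dictionaries.

**Library.** Native disulfides are detected as CYS–CYS pairs with
Sγ–Sγ ≤ 2.3 Å (covalent bond ≈ 2.05 Å plus coordinate error; closest
partner wins when a cysteine has several neighbours within the cutoff;
SSBOND header records are cross-checked and disagreements logged, never
trusted over geometry). Each observation contributes its 44 descriptors to
per-feature histograms — distances in 0.25 Å bins over [0, 15] Å, angles in
10° bins over (−180°, 180°] — and an 8-atom coordinate template. Counts are
Laplace-smoothed (add-one per bin) *inside* the contiguous range of occupied
bins only, so sampling holes never zero out a score while values outside the
range any native disulfide occupies are hard zeros; the filter semantics
(P_Geom = 0 disqualifies) therefore remain meaningful. Densities are
evaluated piecewise-linearly between bin centers: this keeps the score
continuous in every descriptor, so candidates sitting exactly on a bin
boundary are numerically stable under coordinate round-off.

A local-environment profile (secondary-structure class from φ/ψ regions ×
burial class from the Cα-neighbour count within 10 Å, threshold 10) is
mined alongside and stored in the library as descriptive metadata; it does
not enter P_Geom.

**Scores.**

* P_Geom: geometric mean over the 44 features of
  density(observed)/density(mode). Equal to 1 exactly when every feature
  sits in its modal bin; 0 iff any feature is out of support.
* P_RMSD = exp(−RMSD²/2σ²), σ = 0.5 Å by default — at σ the score is
  exp(−½) ≈ 0.61, roughly the point where a template match stops being
  convincing. RMSD comes from proper-rotation Kabsch superposition of the
  8-atom frame against every template, trying both residue orderings
  (a disulfide is symmetric).
* ΔS = −2.1 − (3/2)·R·ln n cal·mol⁻¹·K⁻¹ for the loop of n residues the
  bond closes (n = ordinal sequence separation + 1; ordinal positions, not
  author numbering, so numbering gaps do not distort loop lengths).
  P_ΔS = min(1, |ΔS|/25): a linear saturating map whose cap only sets the
  classifier feature scale — any monotone map preserves the ranking.
  Pairs with separation < 4 are gated to P_ΔS = 0 (sequence-local bridges
  tend to distort the surrounding turn rather than rigidify the fold), as
  are inter-chain pairs, which close no covalent loop. Inter-chain
  enumeration is off by default and available behind a flag.

**Ranking.** All intra-chain pairs are enumerated and scored; records with
P_Geom = 0 or P_ΔS = 0 are removed; survivors are sorted by P_Geom
descending, ties broken by ascending template RMSD and then residue order,
making the output fully deterministic.

**Classifier.** An RBF-kernel SVM over (P_Geom, P_RMSD, P_ΔS). Features are
min-max scaled with constants frozen into the model; hyperparameters are
selected by stratified 5-fold grid search (C ∈ {0.1, 1, 10, 100},
gamma ∈ {0.01, 0.1, 1, 10}) with a seeded fold assignment. Negatives for
corpus training are random non-disulfide pairs from the same structures at
1:1 balance. The fitted machine is frozen to plain arrays (support vectors,
dual coefficients, intercept, kernel width) and prediction evaluates the
RBF decision function from those arrays directly, so JSON round-trips are
bit-identical. Permutation-null checks use nested cross-validation (the
hyperparameter search runs inside each outer training split); a plain
best-over-grid CV score is upward-biased under the null and would sit a few
points above chance. Margins are reported raw; no probability calibration.

## Quasi-harmonic ensemble entropy

Frames are centred at the mass-weighted centroid and least-squares fitted to
the ensemble mean (two passes of mean refinement — further passes change the
result below the estimator's statistical noise). Eigenvalues λᵢ of the
mass-weighted covariance matrix define mode frequencies ωᵢ = √(k_B T/λᵢ);
each contributes the quantum harmonic-oscillator entropy
s = k_B[x/(eˣ−1) − ln(1−e^{−x})], x = ħω/k_B T, summed per mole in
cal·mol⁻¹·K⁻¹. Modes with λ < 1e−8 Å²·amu are numerical null space
(including the six rigid-body directions removed by superposition) and are
discarded; at most 3N − 6 modes contribute. Schlitter's upper-bound formula
(k_B/2)·ln(1 + e²/x²) is available behind a flag for comparison.
B-factors are (8π²/3)·⟨Δr²⟩ per atom from the fitted frames.

## Synthetic generators and what they show

* `make_helix` builds poly-alanine α-helices (φ = −57°, ψ = −47°, ω = 180°)
  from ideal internal coordinates, emitted as PDB text through the package
  writer so parsers are exercised, never bypassed.
* `make_cystine_bundle` plants one cystine with *exactly* specified bridge
  torsions and Sγ–Sγ distance between two helices: the second helix is
  rigidly placed by walking across the bridge with internal coordinates and
  recovering the backbone frame from a canonical cysteine. The two helices
  share one chain with a chain break, keeping the planted pair intra-chain
  for the loop-closure gate. `make_cystine_corpus` samples such bundles with
  Sγ–Sγ ~ N(2.05 Å, 0.02 Å), χ3 from the ±97° mode mixture (4° jitter),
  χ2/χ2′ around −80°, and χ1 rotamers with gauche⁻ dominant (70/15/15) —
  the canonical native cystine statistics.
* `make_gaussian_ensemble` draws frames with a prescribed mass-weighted
  covariance spectrum placed orthogonal to the rigid-body subspace of a
  fixed base structure, so the analysis superposition leaves the planted
  spectrum intact and the entropy target is available in closed form.
* `make_separable_training_set` gives well-separated positive/negative
  score-triple clouds for classifier sanity checks.

These fixtures establish that the pipeline recovers planted parameters,
retrieves planted designs, and respects its contracts. They do **not**
establish performance on real proteins: real native-disulfide statistics
are broader and multi-modal beyond χ3, real candidate sites involve clashes
and strain the pipeline does not model (no repacking, no clash or ΔΔG
scoring), and homology-model inputs add coordinate error that the scores
inherit. Problem sizes in the tests and the acceptance script (50-structure
corpus, 30-residue bundle, 10,000-frame / 5-atom ensembles, n = 100
training sets, 20 permutations) were chosen as the smallest at which the
recovery targets are statistically unambiguous.

## Numerical choices and limitations

* Dihedrals are undefined for collinear triples → explicit degenerate-
  geometry error; superposition requires ≥ 3 points and always returns a
  proper rotation (mirror inputs are fitted, not reflected).
* Altloc conformers resolve to highest occupancy, ties by altloc letter;
  model 1 is used for prediction, all models for ensembles.
* Candidate pairs whose residues lack a backbone atom (chain-terminal O,
  truncated residues) are skipped and counted, not fatal.
* Library and model files are versioned JSON; loading a different schema
  version fails loudly rather than guessing.
* The loop-closure ΔS and the quasi-harmonic ensemble entropy are distinct
  estimators with different inputs; the package never conflates them —
  one gates candidates, the other analyses ensembles.
* No symmetry-mate expansion, no structure repair beyond virtual Cβ, no MD
  engine: ensembles must be supplied.
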