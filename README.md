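# ssforge

Disulfide-bond engineering oriented at crystal quality.

Engineered disulfide bridges lock flexible proteins into a single
conformation, lowering conformational entropy — one of the key obstacles to
growing well-diffracting crystals. `ssforge` scores every residue pair of a
protein structure for its suitability to host an engineered S–S bond, using
statistics mined from native disulfides in solved structures, and provides
the quasi-harmonic ensemble-entropy analysis used to validate such designs
against simulation trajectories.

## The method

For a candidate pair (i, j), cysteine side chains are virtually built from
ideal stereochemistry (Cβ from the backbone; Sγ over a χ1 rotamer grid of
−60°/+60°/180°, keeping the combination whose Sγ–Sγ distance is closest to
the 2.05 Å covalent bond). Three scores are computed:

* **P_Geom** — geometric probability. A 44-dimensional descriptor (the 36
  cross-residue distances over the atoms C, O, N, Cα, Cβ, Sγ; the three
  inter-plane dihedrals C/Cα/Cβ, Cα/Cβ/N, C/Cα/N; the five bridge torsions
  χ1, χ2, χ3, χ2′, χ1′) is evaluated against Laplace-smoothed empirical
  densities mined from native disulfides, and the per-feature factors
  (density normalized by that feature's modal density) are combined by
  geometric mean. Any descriptor outside the range native disulfides occupy
  gives P_Geom = 0.
* **P_RMSD** — closeness to the nearest native template: the 8-atom frame
  (N, Cα, Cβ, Sγ of both residues) is superposed (Kabsch) on every mined
  template, both residue orderings, and the minimum RMSD is mapped through
  exp(−RMSD²/2σ²) with σ = 0.5 Å.
* **P_ΔS** — loop-closure entropy admissibility. Closing a loop of n
  residues costs ΔS = −2.1 − (3/2)·R·ln n cal·mol⁻¹·K⁻¹ (R = 1.987).
  Pairs closer than 4 positions in sequence, or on different chains, are
  inadmissible (P_ΔS = 0); otherwise P_ΔS = min(1, |ΔS|/25).

Candidates with P_Geom = 0 or P_ΔS = 0 are removed; the rest are ranked by
P_Geom descending. An RBF-kernel SVM trained on (P_Geom, P_RMSD, P_ΔS) of
native versus random pairs attaches a positive/negative call with a signed
margin.

For validation of designs against conformational ensembles (multi-model PDB
or simulation snapshots), the `entropy` module computes the quasi-harmonic
entropy: eigenvalues λᵢ of the mass-weighted covariance matrix (after
rigid-body removal) define modes ωᵢ = √(k_B T/λᵢ) whose quantum
harmonic-oscillator entropies are summed, plus per-atom B-factors
(8π²/3)·⟨Δr²⟩ and terminal-distance fluctuation series.

## Worked example

Everything below runs from synthetic fixtures — no downloads:

```python
from ssforge import fixtures as fx, build_library, rank_candidates
from ssforge.structure_io import parse_structure, write_structure

# mine a native-disulfide library from a 50-structure synthetic corpus
corpus, _ = fx.make_cystine_corpus(50, seed=1)
library = build_library(corpus)
print(f"library: {library.n_observations} native disulfides, "
      f"{len(library.templates)} templates")

# rank every residue pair of a two-helix bundle with one ideal planted pair
structure, key_a, key_b = fx.make_two_helix_bundle(seed=1)
structure = parse_structure(write_structure(structure))
records = rank_candidates(structure, library)
print(f"planted pair: {key_a[0]}{key_a[1]} - {key_b[0]}{key_b[1]}")
for rec in records[:3]:
    s = rec.scores
    print(f"  {rec.pair.res_a[0]}{rec.pair.res_a[1]:>3} - "
          f"{rec.pair.res_b[0]}{rec.pair.res_b[1]:>3}   "
          f"P_Geom={s.p_geom:.3f}  P_RMSD={s.p_rmsd:.3f}  "
          f"dS={s.delta_s:+.2f} cal/mol/K")
```

prints

```
library: 50 native disulfides, 50 templates
planted pair: A8 - A23
  A  8 - A 23   P_Geom=0.704  P_RMSD=0.998  dS=-10.36 cal/mol/K
```

Of the 435 possible pairs in the bundle, only the planted cross-helix pair
survives the P_Geom/P_ΔS filter, with near-modal geometry (P_Geom = 0.70),
an almost exact match to the nearest native template (P_RMSD = 0.998), and a
loop-closure entropy gain of −10.4 cal·mol⁻¹·K⁻¹ for the 16-residue loop it
closes.

The same pipeline is available from the shell:

```sh
ssforge fixtures --kind two_helix_bundle --seed 1 --out bundle.pdb
ssforge build-library --pdb-dir corpus/ --out lib.json
ssforge predict --structure bundle.pdb --library lib.json --out candidates.tsv
ssforge entropy --ensemble traj.pdb --temperature 300
```

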