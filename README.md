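# chromofold

Population Hi-C measures how often two genomic regions touch, averaged
over millions of cells — but many of those contacts are by-stander
collisions of a polymer crowded into a nucleus, and the map says nothing
about the 3D arrangement inside any single cell. `chromofold` addresses
both problems for a locus of interest (hundreds of kb at 5 kb
resolution), and then uses the resulting single-cell models to ask how
eQTLs relate spatially to the genes they regulate. It is aimed at
computational biologists working at the interface of 3D genome
organization and regulatory genetics.

The pipeline:

1. **Polymer null model.** Chromatin is a self-avoiding bead chain
   (30 nm beads, one per 5 kb bin) grown inside a confinement sphere set
   by a bead volume fraction (default 0.1). Sequential importance
   sampling with Rosenbluth weighting and checkpoint resampling samples
   the uniform distribution over feasible chains; the ensemble contact
   frequency at the 80 nm cross-linking threshold,
   `P0(i,j) = Pr[d(i,j) < 80 nm]`, is the contact probability expected
   from random collision alone.
2. **Nonrandom interaction calling.** Observed counts are normalized to
   probabilities `q(i,j)` by anchoring the adjacent diagonal, then each
   pair is scored by a run-level, depth-matched bootstrap of the null
   ensemble; Benjamini–Hochberg adjusted p < 0.05 defines the nonrandom
   set — contacts beyond what confinement explains.
3. **Constraint-based folding.** Nonrandom interactions become spatial
   constraints with per-cell activation probabilities calibrated so the
   folded population reproduces the observed frequencies; guided
   sequential growth then reconstructs an ensemble of single-cell 3D
   conformations. Simulated maps from the ensemble are compared with the
   input (Pearson over the informative upper triangle), against a
   1D-distance decay benchmark.
4. **eQTL geometry and heterogeneity.** On the folded ensemble: eGene
   (promoter bead) to eQTL (variant bead) median distances classify pairs
   as physical contacts (< 80 nm); sets of ≥ 3 regions whose pairwise
   medians all fall within 80 ± 5 nm are many-body units; |NES| (the
   GTEx normalized effect size, the slope of expression on genotype) is
   compared between contact groups by rank-sum test; k-means on pairwise
   distance vectors splits the pooled cells into structural
   subpopulations ordered by compactness.

## Worked example

Everything runs on synthetic study data — no downloads. The config below
builds a structured 100-bead locus (two compact domains plus long-range
loops at ~90% per-cell penetrance), draws Poisson Hi-C counts at depth
1e5, and runs the full pipeline:

```yaml
# config.yaml
outdir: out
seed: 1
fixture: {n_beads: 100, depth: 1.0e5}
n_null: 2000
n_fold: 500
B: 400
K: 2
```

```sh
chromofold run --config config.yaml
```

On this locus the run prints the following into `out/manifest.json` and
the per-stage reports:

* `call-nonrandom: nonrandom_fraction = 0.182` — 18% of the 4851 tested
  pairs exceed the polymer null at FDR 0.05; the remaining 82% of Hi-C
  contacts at this locus are explainable as confined-polymer collisions.
* `fold: n_constraints = 279` — calibration prunes the ~880 called pairs
  to the subset not already explained by the rest of the constraint
  system acting through polymer physics.
* `comparison.json: model_pearson_r = 0.867` vs
  `baseline_pearson_r = 0.657` — the folded 500-cell ensemble reproduces
  the ground-truth contact map far better than a predictor that only
  knows genomic distance, i.e. the called interactions carry the locus's
  spatial organization (a larger folding population, as used by
  `scripts/acceptance.py`, pushes the model correlation to ~0.9).
* `eqtl_contacts.tsv / nes_test.json` — 10 of 20 synthetic variant–gene
  pairs are classified as physical contacts (ensemble median distance
  < 80 nm); contacting pairs carry larger |NES| (medians 1.45 vs 0.67,
  rank-sum p = 3.2e-4).
* `clusters.json` — the two structural subpopulations separate the two
  planted archetypes perfectly (per-source proportions [1, 0] and
  [0, 1]), reported most-compact-first (mean radius of gyration 91.8 nm,
  then 97.6 nm).

Individual stages are also available as subcommands (`null-model`,
`call-nonrandom`, `fold`, `simulate-hic`, `compare-maps`,
`eqtl-contacts`, `many-body`, `cluster`, `synth`); see `chromofold
COMMAND --help`.

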