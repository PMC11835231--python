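# Methods

This note documents the models, algorithms and numerical choices behind
`chromofold`, in the order the pipeline runs them.

## Polymer model and null ensemble

Chromatin at a locus is a linear bead chain, one bead per Hi-C bin
(default 5 kb). Geometry defaults:

| parameter | default | meaning |
|---|---|---|
| `bead_diameter` | 30 nm | hard-core excluded volume of one 5 kb bead |
| `bond_length` | = diameter | distance between consecutive beads (tangent beads) |
| `volume_fraction` | 0.1 | share of the confinement sphere occupied by bead volume |
| `confinement_radius` | derived | `R = (d/2) (n_beads / volume_fraction)^(1/3)` |
| contact threshold | 80 nm | distance below which a bead pair is cross-linkable |

The confinement radius scales with locus size at fixed occupancy, standing
in for the nuclear volume available to the fiber. All geometry is
config-exposed (`ChainParams`).

Null conformations are sampled by sequential importance sampling: bead 0
uniform in the sphere; each next bead drawn among `n_trial_directions`
(default 20) uniform points on the bond sphere, restricted to placements
respecting the hard core and the confinement; the chain log-weight
accumulates the Rosenbluth correction `log(n_open / n_trials)`, so weighted
averages target the uniform distribution over all feasible self-avoiding
confined chains. Populations grow in lockstep with systematic resampling at
checkpoints (every 25 beads) whenever the Kish effective sample size falls
below half the population or chains have died (a chain dies when no
placement is feasible).

Resampling is unavoidable here — confined-chain Rosenbluth weights have a
heavy left tail from nearly-trapped chains, and without it the effective
sample of a 2000-chain, 100-bead ensemble drops to a few dozen — but it
makes conformations within one population share ancestry. The ensemble is
therefore assembled from many **independent runs** (default 100 chains per
run), and every downstream bootstrap treats the run, not the conformation,
as the exchangeable unit. Run tags travel with the ensemble through the
XYZ format.

## Nonrandom interaction calling

Observed counts are normalized to probabilities by anchoring the adjacent
diagonal: the scale `s` makes the mean of `s * counts` over |i−j| = 1 equal
the null ensemble's mean contact probability there (near 1 in both), then
`q = min(1, s*c)`. Pairs with |i−j| < 2 are excluded from testing; at this
geometry lag-1 contact is certain (bond 30 nm < 80 nm).

Each tested pair's raw p-value is the add-one upper-tail bootstrap
`p = (1 + #{replicate >= q}) / (B + 1)`. A replicate resamples **runs** of
the null ensemble with replacement and averages `R/2` of them — half the
run count, because the observation is compared against a null map that is
itself estimated from `R` runs, so the observed-minus-null difference
carries roughly twice the variance of a mean of `R` runs. Replicates are
additionally *depth-matched*: replicate frequencies are converted to
Poisson counts at the observed adjacent-diagonal depth and normalized
exactly like the observed map, so counting noise enters the null
distribution of the statistic. Benjamini–Hochberg step-up adjustment over
the tested pairs controls the FDR; adjusted p < 0.05 defines the
nonrandom set. `m` in BH is the number of tested pairs.

Measured on held-out null ensembles (same generator, independent seed),
the BH-significant fraction is 0 across seeds; raw p-values remain mildly
anti-conservative at desk scale (the empirical run distribution has only
~20 atoms), which BH absorbs.

## Constraint-based folding

Each nonrandom interaction becomes a spatial constraint with an
**activation probability**: a loop called from population Hi-C is present
in a fraction of cells, not all. From calls, the initial activation is the
excess contact probability `(q − null) / (1 − null)`. During growth, an
active constraint (i, j) weights candidate placements of bead j by the
one-sided flat-bottom likelihood
`exp(−max(0, d − target)² / (2σ²))` with σ = 2 nm — sharp enough that an
active, satisfied pair rarely exceeds the 80 nm target by more than a few
nm. σ = 2 was chosen because the equilibrium satisfaction of softer
potentials (σ ≥ 5 nm) falls below the per-constraint satisfaction the
folding QC demands; it is config-exposed.

Two guidance terms keep the sequential sampler on target:

* a **reachability funnel**: while a constraint (i, j) is pending
  (i placed, j not), candidates further from bead i than
  `target + remaining_contour × 0.7` are downweighted — a confined
  self-avoiding chain never extends straight, hence the 0.7;
* **checkpoint lookahead**: resampling weights at checkpoints (every 5
  beads during folds) include the same funnel score of the current chain
  end.

Both terms enter the sampling weights, i.e. the effective target multiplies
the constraint likelihood by funnel factors. The funnel is exactly 1 on
any trajectory that can still satisfy its pending constraints, so the
sampled distribution agrees with the constraint-conditioned target on the
satisfied set and only reweights how violating chains are represented. (An
"exact" variant that divides the guidance back out of the importance
weights was tried and rejected: funnel-violating chains received unbounded
weight refunds and single lineages took over entire populations.)

Folds also use independent runs (100 chains each) with an internal
population of at least `max(n_requested, 3000)` and 40 trial directions;
the requested ensemble is drawn from the final weighted populations by
systematic resampling, evenly across runs. Runs that go extinct (all
chains jammed) are retried with fresh seeds up to 3 times.

### Calibration of activations

Calls are correlated: pairs elevated as a by-product of a few true loops
would, if activated independently, over-compact the ensemble. Folding from
calls therefore runs 3 calibration rounds: a pilot fold measures, per
constrained pair, the contact frequency among cells where the constraint
was active (`m1`) and passive (`m0`); the mixture model
`achieved = a·m1 + (1−a)·m0` gives the activation that hits the observed
target, `a = (q − m0)/(m1 − m0)`, clipped to [0, 1]. Pairs whose passive
frequency already reaches the target are dropped (activation < 0.02) — the
rest of the constraint system explains them. On the synthetic locus below
this prunes ~800 called pairs to ~150–250 informative constraints and
removes the over-compaction that a one-shot fold exhibits.

## Map comparison

Simulated maps aggregate a (sub)sample of conformations at the 80 nm
threshold. `pearson_map_similarity` correlates strict upper-triangle
entries with |i−j| ≥ 2 by default (diagonal and adjacent entries are ~1 in
any polymer map). Structure-fidelity analyses (model vs truth, baseline vs
truth, archetype distinguishability) use |i−j| ≥ 4: with 30 nm bonds and
an 80 nm threshold, lag-2 pairs are *geometrically forced* to contact
probability exactly 1 (max separation 60 nm) and lag-3 to ≈ 0.93, so those
entries carry no structural information and only inflate correlations.
The 1D-distance benchmark predicts every entry by its genomic-separation
diagonal mean of the observed map.

## eQTL–eGene geometry

Variants map to the bead containing their (1-based) position; genes map to
their TSS bead — the promoter bead — by default (a gene-body alternative
would take any overlapping bead; the TSS choice follows the use of
promoter distances in tissue comparisons). A pair is a physical contact
when the ensemble median distance is strictly below 80 nm; medians use a
seeded subsample (default 5000) of conformations. A set of ≥ 3 regions is
a many-body unit when every pairwise median is ≤ 85 nm — the cross-linking
threshold plus a 5 nm tolerance, inclusive at the upper edge, deliberately
asymmetric to the strict pair rule. |NES| of contacting vs non-contacting
pairs is compared with a two-sided Wilcoxon rank-sum test (exact for
combined n ≤ 20, normal approximation with tie correction otherwise);
Welch's t on |NES| is available as an alternative.

## Heterogeneity

Conformations are embedded as vectors of all n(n−1)/2 pairwise bead
distances — rigid-motion invariant by construction, preserving geometry
gradations that binarized contacts lose (a contact-feature flag exists for
sensitivity checks). Features are standardized over the pooled set and
clustered with k-means (10 seeded restarts, best inertia). K is user-set;
a silhouette scan over K ∈ [2, 8] is reported but never auto-selects.
Summaries report per-source cluster proportions, per-cluster mean radius
of gyration with clusters ordered most-compact-first, and per-cluster
aggregated contact maps.

## Synthetic study data

The fixture generator emulates a structured locus at desk scale:

* **Archetypes** are TAD-like: 2 non-overlapping compact domains
  (24–34 beads) with unstructured gaps, compacted by a dense scaffold grid
  of constraints at ~90% penetrance (jittered per domain), plus 3
  cross-domain loops. Domain/gap contrast at equal genomic lag is what
  distinguishes a structured map from bare distance decay — isolated loop
  pairs alone are a negligible share of map variance and leave the decay
  baseline indistinguishable from a structured model. Archetype layouts
  are rejection-sampled to share ≤ 0.35 bead coverage, so their maps are
  distinguishable. Partial penetrance reflects single-cell variability of
  real chromatin structures.
* **Synthetic Hi-C** draws Poisson counts (optionally negative binomial)
  around `depth · p / Σp` from an ensemble's probability map; default
  depth 1e5 off-diagonal counts.
* **eQTL tables** emit GTEx-dialect variant ids at mid-bead positions with
  |NES| drawn from N(1.2, 0.3) for contact pairs and N(0.6, 0.3) for
  non-contact pairs (signs random; only |NES| matters downstream), plus a
  matching TSS BED.

What passing tests on these fixtures show: the statistical machinery —
FDR control against the polymer null, frequency-calibrated folding,
contact classification, rank-sum power, subpopulation recovery — behaves
correctly on data whose generating process is known. What they do not
show: robustness to real-data artifacts the generator omits (mappability
and GC biases, translocations, unmappable bins, cross-tissue NES
harmonization, genome-wide backgrounds beyond a single locus).

## Problem sizes and numerical choices

Default desk-scale sizes: 100-bead loci (500 kb at 5 kb resolution),
2000-chain null ensembles (20 independent runs), 500-conformation folded
ensembles from ≥ 3000-chain internal populations (8000 for the
reconstruction-fidelity analysis), B = 400 bootstrap replicates. The
paper-scale analogues (10⁶-chain nulls, 5×10⁴–5×10⁵-conformation folds,
~150–800-bead loci) are reachable with the same code and larger budgets;
ensemble sizes are free parameters throughout.

Ties and degenerate inputs: zero-variance maps raise on correlation;
`i == j` distance queries return 0; empty constraint sets fold exactly as
null growth (bead-for-bead identical trajectories under the same seed);
empty clusters are reported with a notice and omitted maps. Bond-length
validation is exact to 1e-6 relative; hard-core checks allow 1e-9 relative
slack so a bond of exactly one diameter never fails by rounding.

## Known limitations

* Desk-scale SMC ensembles have far fewer effective independent
  conformations than their nominal size (ancestry collapse); run-level
  bookkeeping makes this explicit and keeps the bootstrap honest, but
  per-pair frequency estimates carry the corresponding noise.
* Independent per-cell constraint activation cannot represent co-occurring
  loop programs (correlated activation); calibration matches pairwise
  marginals only.
* The one-sided constraint potential cannot pull pairs apart, so an
  over-called contact set can only be corrected by dropping or attenuating
  constraints, not by repulsion.
* A single linear fiber per locus: no lamina/nucleolus compartments, no
  epigenetic-state heteropolymers, no multi-chromosome folding.
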