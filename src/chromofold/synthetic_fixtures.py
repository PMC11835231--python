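"""Desk-scale synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the pipeline can be exercised without any external download:

* archetype ensembles — constraint sets are harvested from the contact
  pairs of a real sampled chain (a "template"), which guarantees the
  planted constraints are jointly satisfiable, then folded into an
  ensemble. Different archetypes use different templates, so their
  contact maps are structurally distinct.
* synthetic Hi-C — Poisson (optionally negative-binomial) counts around
  ``depth * p / sum(p)`` from an ensemble's contact probability map,
  emulating sequencing-depth noise with distance decay and planted
  off-diagonal structure.
* eQTL tables — GTEx-dialect variant-gene pairs whose |NES| is drawn from
  separate distributions for spatially contacting and non-contacting
  pairs, with random signs (only |NES| matters downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constrained_folding import ConstraintSet, fold_ensemble
from .genome_io import (ContactMatrix, EqtlRecord, GeneAnnotation, LocusSpec)
from .null_ensemble import (CONTACT_THRESHOLD_NM, ChainParams,
                            ConformationEnsemble, generate_null_ensemble)

__all__ = [
    "FixtureSpec",
    "NesEffect",
    "make_archetype_ensembles",
    "template_constraints",
    "tad_constraints",
    "synth_hic_from_ensemble",
    "synth_eqtl_table",
]


@dataclass(frozen=True)
class NesEffect:
    """|NES| distributions for contact vs non-contact pairs."""

    contact_mean: float = 1.2
    free_mean: float = 0.6
    sd: float = 0.3

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.contact_mean < self.free_mean:
            raise ValueError(
                "planted effect requires contact mean >= non-contact mean")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic locus fixture."""

    n_beads: int = 100
    n_archetypes: int = 2
    #: domains per archetype; each contributes anchor + scaffold constraints
    n_tads: int = 2
    #: long-range loops between domains per archetype
    n_cross_loops: int = 3
    conformations_per_archetype: int = 500
    #: internal SMC population for the archetype folds; sets the effective
    #: number of independent lineages behind the ground-truth maps
    fold_population: int = 6000
    #: fraction of cells in which a planted domain/loop is present; real
    #: chromatin structures are partially penetrant at the single-cell level
    penetrance: float = 0.9
    depth: float = 1e5
    noise: str = "poisson"  # or "nb"
    nb_dispersion: float = 0.1
    effect: NesEffect = field(default_factory=NesEffect)
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate YAML-parsed strings like "1.0e5"
        for name in ("depth", "penetrance", "nb_dispersion"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if min(self.n_beads, self.n_archetypes, self.n_tads,
               self.conformations_per_archetype) < 1:
            raise ValueError("all fixture counts must be positive")
        if not (0 < self.penetrance <= 1):
            raise ValueError("penetrance must be in (0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be nonnegative")
        if self.noise not in ("poisson", "nb"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def template_constraints(n_beads: int, n_constraints: int, seed: int,
                         min_lag: int = 6,
                         params: ChainParams | None = None) -> ConstraintSet:
    """Harvest a feasible constraint set from a sampled template chain.

    A small null batch is grown; one chain serves as the template and
    ``n_constraints`` of its contact pairs (|i-j| >= min_lag, within the
    cross-linking threshold) are drawn with probability proportional to
    genomic span, favouring the long-range loops that make an archetype's
    map distinguishable from plain distance decay. Because one
    conformation realizes all pairs simultaneously, the set is feasible
    by construction.
    """
    rng = np.random.default_rng(seed)
    batch = generate_null_ensemble(32, n_beads, params=params,
                                   seed=int(rng.integers(2 ** 31)))
    X = batch.coords_array()
    ii, jj = np.triu_indices(n_beads, k=min_lag)
    for attempt in rng.permutation(len(batch)):
        tmpl = X[attempt]
        d = np.linalg.norm(tmpl[ii] - tmpl[jj], axis=-1)
        in_contact = d < CONTACT_THRESHOLD_NM
        if in_contact.sum() >= n_constraints:
            ci, cj = ii[in_contact], jj[in_contact]
            span = (cj - ci).astype(float)
            pick = rng.choice(in_contact.sum(), size=n_constraints,
                              replace=False, p=span / span.sum())
            pairs = sorted((int(ci[p]), int(cj[p])) for p in pick)
            return ConstraintSet(pairs, source=f"template(seed={seed})")
    raise RuntimeError(
        f"no template chain with {n_constraints} contacts at lag >= {min_lag}; "
        "lower min_lag or n_constraints")


def sample_domain_layout(n_beads: int, n_tads: int,
                         rng: np.random.Generator, min_width: int = 24,
                         max_width: int = 34, gap: int = 6) -> list[tuple[int, int]]:
    """Random non-overlapping domain blocks separated by unstructured gaps."""
    if n_beads - 1 < n_tads * (min_width + gap):
        raise ValueError("locus too short for the requested domain count")
    widths = rng.integers(min_width, max_width + 1, size=n_tads)
    free = n_beads - 1 - int(widths.sum()) - gap * (n_tads - 1)
    if free < 0:
        widths = np.full(n_tads, min_width)
        free = n_beads - 1 - int(widths.sum()) - gap * (n_tads - 1)
    cuts = np.sort(rng.integers(0, free + 1, size=n_tads))
    slack = np.diff(np.concatenate([[0], cuts, [free]]))
    blocks = []
    pos = 0
    for t in range(n_tads):
        start = pos + int(slack[t]) + (gap if t > 0 else 0)
        end = start + int(widths[t])
        blocks.append((start, end))
        pos = end
    return blocks


def _layout_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]],
                    n_beads: int) -> float:
    """Jaccard overlap of the bead sets covered by two layouts."""
    ca, cb = np.zeros(n_beads, bool), np.zeros(n_beads, bool)
    for x, y in a:
        ca[x:y + 1] = True
    for x, y in b:
        cb[x:y + 1] = True
    union = (ca | cb).sum()
    return float((ca & cb).sum() / union) if union else 0.0


def tad_constraints(n_beads: int, n_tads: int = 2, seed: int = 0,
                    penetrance: float = 1.0, n_cross_loops: int = 3,
                    blocks: list[tuple[int, int]] | None = None,
                    penetrance_jitter: float = 0.05) -> ConstraintSet:
    """Domain-style constraint set: dense TAD scaffolds plus cross loops.

    The locus holds ``n_tads`` non-overlapping blocks separated by
    unstructured gaps; the contrast between compact domains and free
    fiber at the same genomic lag is what distinguishes the map from
    bare distance decay. Each block is compacted into a blob by a dense
    grid of scaffold constraints (the way a TAD appears as a dense square
    in Hi-C); ``n_cross_loops`` long-range loops connect interior beads of
    different blocks. Nested local constraints are geometrically
    compatible, so the set is feasible by construction.
    """
    rng = np.random.default_rng(seed)
    if blocks is None:
        blocks = sample_domain_layout(n_beads, n_tads, rng)
    pairs: dict[tuple[int, int], float] = {}
    for a, b in blocks:
        pen = float(np.clip(penetrance + rng.uniform(-penetrance_jitter,
                                                     penetrance_jitter),
                            0.05, 1.0))
        step = max(3, (b - a) // 8)
        grid = list(range(a, b + 1, step))
        if grid[-1] != b:
            grid.append(b)
        for xi, x in enumerate(grid):
            for y in grid[xi + 1:]:
                pairs[(x, y)] = pen
    interiors = [np.arange(a + 2, b - 1) for a, b in blocks]
    n_tads = len(blocks)
    if n_tads < 2:
        n_cross_loops = 0
    for _ in range(n_cross_loops):
        t1, t2 = rng.choice(n_tads, size=2, replace=False)
        i = int(rng.choice(interiors[t1]))
        j = int(rng.choice(interiors[t2]))
        lo, hi = min(i, j), max(i, j)
        if lo < hi and (lo, hi) not in pairs:
            pairs[(lo, hi)] = penetrance
    return ConstraintSet(
        [(i, j, CONTACT_THRESHOLD_NM, p) for (i, j), p in sorted(pairs.items())],
        source=f"tads(seed={seed})")


def make_archetype_ensembles(spec: FixtureSpec,
                             params: ChainParams | None = None,
                             locus: LocusSpec | None = None
                             ) -> list[tuple[str, ConformationEnsemble, ConstraintSet]]:
    """Fold one labeled ensemble per archetype under its planted constraints.

    Returns ``[(label, ensemble, constraint_set), ...]``; reproducible from
    ``spec.seed``.
    """
    out = []
    layouts: list[list[tuple[int, int]]] = []
    layout_rng = np.random.default_rng(spec.seed * 1000 + 11)
    for a in range(spec.n_archetypes):
        # archetypes must be structurally distinct: resample the domain
        # layout until it shares little coverage with earlier archetypes
        for _ in range(200):
            blocks = sample_domain_layout(spec.n_beads, spec.n_tads, layout_rng)
            if all(_layout_overlap(blocks, prev, spec.n_beads) <= 0.35
                   for prev in layouts):
                break
        layouts.append(blocks)
        cs = tad_constraints(spec.n_beads, spec.n_tads,
                             seed=spec.seed * 1000 + 17 * a + 3,
                             penetrance=spec.penetrance,
                             n_cross_loops=spec.n_cross_loops,
                             blocks=blocks)
        ens = fold_ensemble(cs, spec.conformations_per_archetype, spec.n_beads,
                            params=params, seed=spec.seed * 1000 + 17 * a + 7,
                            locus=locus, min_population=spec.fold_population)
        out.append((f"archetype{a}", ens, cs))
    return out


def synth_hic_from_ensemble(ensemble: ConformationEnsemble, depth: float,
                            seed: int | None = None,
                            locus: LocusSpec | None = None,
                            threshold: float = CONTACT_THRESHOLD_NM,
                            noise: str = "poisson",
                            nb_dispersion: float = 0.1) -> ContactMatrix:
    """Sample a symmetric count matrix around ``depth * p / sum(p)``.

    ``p`` is the ensemble's contact probability map; the strict upper
    triangle is drawn (Poisson by default, negative binomial with the given
    dispersion if ``noise="nb"``) and mirrored. ``depth`` is the expected
    total off-diagonal count (both triangles).
    """
    from .null_ensemble import contact_frequency_matrix

    if depth < 0:
        raise ValueError("depth must be nonnegative")
    prob = contact_frequency_matrix(ensemble, threshold, locus=locus)
    n = prob.n_beads
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    p = prob.values[iu]
    counts = np.zeros((n, n))
    if depth > 0 and p.sum() > 0:
        lam = (depth / 2.0) * p / p.sum()
        if noise == "poisson":
            c = rng.poisson(lam)
        elif noise == "nb":
            r = 1.0 / nb_dispersion
            c = rng.negative_binomial(r, np.clip(r / (r + lam), 1e-12, 1.0))
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        counts[iu] = c
        counts = counts + counts.T
    return ContactMatrix(prob.locus, counts, kind="counts")


def synth_eqtl_table(locus: LocusSpec,
                     contact_pairs: list[tuple[int, int]],
                     free_pairs: list[tuple[int, int]],
                     effect: NesEffect | None = None,
                     seed: int | None = None,
                     tissue: str = "synthetic-tissue"
                     ) -> tuple[list[EqtlRecord], list[GeneAnnotation]]:
    """Emit GTEx-dialect eQTL records and a matching TSS annotation set.

    Pairs are (gene_bead, eqtl_bead) index tuples; |NES| is drawn from the
    contact or non-contact distribution accordingly, with random sign.
    Variant and TSS positions sit mid-bead, so they round-trip through
    the bead mapping.
    """
    effect = effect or NesEffect()
    rng = np.random.default_rng(seed)
    n = locus.n_beads
    records: list[EqtlRecord] = []
    annotations: list[GeneAnnotation] = []
    bases = np.array(list("ACGT"))

    def mid(bead: int) -> int:  # 1-based mid-bead position
        return locus.start + bead * locus.resolution + locus.resolution // 2 + 1

    gene_count = 0
    for group, pairs in (("contact", contact_pairs), ("free", free_pairs)):
        mean = effect.contact_mean if group == "contact" else effect.free_mean
        for gene_bead, eqtl_bead in pairs:
            if not (0 <= gene_bead < n and 0 <= eqtl_bead < n):
                raise ValueError(f"pair ({gene_bead}, {eqtl_bead}) outside locus")
            gene_id = f"SYNG{gene_count:04d}"
            gene_count += 1
            pos = mid(eqtl_bead)
            ref, alt = rng.choice(bases, size=2, replace=False)
            nes = abs(rng.normal(mean, effect.sd)) * rng.choice([-1.0, 1.0])
            vid = f"{locus.chrom}_{pos}_{ref}_{alt}_b38"
            records.append(EqtlRecord(vid, locus.chrom, pos, str(ref), str(alt),
                                      gene_id, float(nes), tissue))
            annotations.append(GeneAnnotation(gene_id, locus.chrom,
                                              mid(gene_bead), "+"))
    return records, annotations
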