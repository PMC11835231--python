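"""Spatial analysis of eQTL-eGene pairs on conformation ensembles.

Three questions, all answered from ensemble-median Euclidean distances
between the 5 kb beads holding a variant and its target gene's promoter:

* is an eGene-eQTL pair in physical contact (median distance strictly
  below the 80 nm cross-linking threshold)?
* do >= 3 regions form a many-body unit (every pairwise median at most
  the threshold plus a 5 nm tolerance, i.e. <= 85 nm at defaults)?
* do physically contacting pairs carry larger |NES| (normalized effect
  size, the slope of expression on genotype) than non-contacting pairs?

The pair rule is strict (< 80 nm); the many-body rule is inclusive at its
85 nm upper edge — "approximately equal to" the cross-linking threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ensemble_analysis import pairwise_distance_summary
from .genome_io import EqtlRecord, GeneAnnotation, LocusSpec, map_to_bead
from .null_ensemble import CONTACT_THRESHOLD_NM, ConformationEnsemble

__all__ = [
    "PairContactResult",
    "ManyBodyUnit",
    "classify_pairs",
    "detect_many_body",
    "compare_nes_distributions",
    "MANY_BODY_TOLERANCE_NM",
]

#: slack (nm) above the cross-linking threshold admitted by the many-body rule
MANY_BODY_TOLERANCE_NM = 5.0


@dataclass(frozen=True)
class PairContactResult:
    record: EqtlRecord
    gene_bead: int
    eqtl_bead: int
    median_distance: float
    physical_contact: bool

    @property
    def abs_nes(self) -> float:
        return abs(self.record.nes)


@dataclass(frozen=True)
class ManyBodyUnit:
    members: tuple[int, ...]
    labels: tuple[str, ...]
    median_matrix: np.ndarray
    classified: bool
    base_threshold: float
    tolerance: float


def classify_pairs(ensemble: ConformationEnsemble,
                   records: list[EqtlRecord],
                   annotations: list[GeneAnnotation],
                   locus: LocusSpec,
                   threshold: float = CONTACT_THRESHOLD_NM,
                   n_sample: int | None = None,
                   seed: int | None = None) -> tuple[list[PairContactResult], list[EqtlRecord]]:
    """Classify each eGene-eQTL pair as physical contact or not.

    The variant maps to the bead containing its position, the gene to its
    TSS (promoter) bead; the pair is a physical contact when the ensemble
    median distance is strictly below ``threshold``. Records whose variant
    or gene does not map into the locus are skipped and returned separately.
    """
    if ensemble.n_beads != locus.n_beads:
        raise ValueError("ensemble and locus bead counts differ")
    tss_by_gene = {a.gene_id: a for a in annotations}
    results: list[PairContactResult] = []
    skipped: list[EqtlRecord] = []
    for rec in records:
        ann = tss_by_gene.get(rec.gene_id)
        try:
            if ann is None:
                raise ValueError(f"no TSS annotation for gene {rec.gene_id}")
            eqtl_bead = map_to_bead(rec.pos, locus)
            gene_bead = map_to_bead(ann.tss, locus)
        except ValueError:
            skipped.append(rec)
            continue
        summary = pairwise_distance_summary(ensemble, gene_bead, eqtl_bead,
                                            n_sample=n_sample, seed=seed)
        med = summary["median"]
        results.append(PairContactResult(rec, gene_bead, eqtl_bead, med,
                                         bool(med < threshold)))
    if not results:
        raise ValueError("no eGene-eQTL pair maps into the locus")
    return results, skipped


def detect_many_body(ensemble: ConformationEnsemble,
                     members,
                     base_threshold: float = CONTACT_THRESHOLD_NM,
                     tolerance: float = MANY_BODY_TOLERANCE_NM,
                     labels=None,
                     n_sample: int | None = None,
                     seed: int | None = None) -> ManyBodyUnit:
    """Test whether >= 3 beads form a many-body interaction unit.

    The unit is classified when every pairwise ensemble-median distance is
    <= base_threshold + tolerance (85 nm at defaults, inclusive).
    """
    members = [int(m) for m in members]
    if len(members) < 3:
        raise ValueError("a many-body unit needs at least 3 members")
    if len(set(members)) != len(members):
        raise ValueError("duplicate members")
    labels = tuple(labels) if labels is not None \
        else tuple(f"bead{m}" for m in members)
    if len(labels) != len(members):
        raise ValueError("labels and members length mismatch")
    k = len(members)
    med = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            s = pairwise_distance_summary(ensemble, members[a], members[b],
                                          n_sample=n_sample, seed=seed)
            med[a, b] = med[b, a] = s["median"]
    off = med[np.triu_indices(k, 1)]
    classified = bool((off <= base_threshold + tolerance).all())
    return ManyBodyUnit(tuple(members), labels, med, classified,
                        base_threshold, tolerance)


def compare_nes_distributions(results: list[PairContactResult],
                              method: str = "ranksum") -> dict:
    """Compare |NES| between contact and non-contact pair groups.

    Two-sided Wilcoxon rank-sum (Mann-Whitney U), exact when the combined
    sample is small (n <= 20), normal approximation with tie correction
    otherwise. ``method="welch"`` switches to Welch's t on |NES|.
    """
    contact = np.array([r.abs_nes for r in results if r.physical_contact])
    free = np.array([r.abs_nes for r in results if not r.physical_contact])
    if contact.size == 0 or free.size == 0:
        raise ValueError(
            f"both groups must be non-empty (contact n={contact.size}, "
            f"non-contact n={free.size})")
    if method == "ranksum":
        mode = "exact" if contact.size + free.size <= 20 else "asymptotic"
        res = stats.mannwhitneyu(contact, free, alternative="two-sided",
                                 method=mode)
        stat_name = "U"
    elif method == "welch":
        res = stats.ttest_ind(contact, free, equal_var=False)
        stat_name = "t"
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "statistic": float(res.statistic),
        "statistic_name": stat_name,
        "p_value": float(res.pvalue),
        "n_contact": int(contact.size),
        "n_free": int(free.size),
        "median_contact": float(np.median(contact)),
        "median_free": float(np.median(free)),
        "method": method,
    }
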