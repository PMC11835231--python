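"""End-to-end pipeline orchestration with provenance and per-stage seeding.

A single config drives the stages null-model -> call-nonrandom -> fold ->
simulate/compare -> eqtl-contacts -> many-body -> cluster; every artifact
is recorded in a manifest together with the stage parameters and seed, and
a stage whose outputs already exist with a matching parameter hash is
skipped on re-runs.

One global seed expands into per-stage seeds by hashing the stage name
(CRC-32 of the name XOR the global seed, folded below 2^31), so any stage
can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .constrained_folding import ConstraintSet, fold_from_calls
from .ensemble_analysis import (distance_decay_baseline, pearson_map_similarity,
                                simulate_hic)
from .eqtl_spatial import (classify_pairs, compare_nes_distributions,
                           detect_many_body)
from .genome_io import (map_to_bead, parse_locus, read_contact_matrix,
                        read_ensemble_xyz, read_eqtl_table, read_tss_bed,
                        write_contact_matrix, write_ensemble_xyz,
                        write_eqtl_table, write_tss_bed)
from .heterogeneity import cluster_conformations, summarize_clusters
from .nonrandom_calling import (call_nonrandom, observed_probability,
                                significant_fraction)
from .null_ensemble import (CONTACT_THRESHOLD_NM, ChainParams,
                            contact_frequency_matrix, generate_null_ensemble)
from .synthetic_fixtures import (FixtureSpec, make_archetype_ensembles,
                                 synth_eqtl_table, synth_hic_from_ensemble)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

#: comparison mask for structure-similarity analyses; lags below 4 are
#: geometrically forced into contact by the bead geometry (30 nm bonds vs
#: the 80 nm threshold) and carry no information
STRUCTURE_MIN_LAG = 4


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2 ** 31)


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of one pipeline run."""

    outdir: str
    seed: int = 0
    locus: str | None = None            # e.g. "chr2:230805000-231690000"
    resolution: int = 5000
    hic: str | None = None              # contact-count file (triplet/dense)
    eqtl: str | None = None             # GTEx-style pair table
    tss: str | None = None              # TSS BED
    fixture: dict | None = None         # FixtureSpec fields, if synthetic
    threshold: float = CONTACT_THRESHOLD_NM
    alpha: float = 0.05
    B: int = 400
    n_null: int = 2000
    n_fold: int = 500
    K: int | None = None                # cluster count; None skips clustering
    triad: list[int] | None = None      # bead indices for many-body check
    chain: dict = field(default_factory=dict)  # ChainParams overrides
    fold_population: int | None = None  # internal SMC population for folding
    calibration_rounds: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def __post_init__(self) -> None:
        # tolerate YAML-parsed strings like "1.0e5"
        self.threshold = float(self.threshold)
        self.alpha = float(self.alpha)

    def validate(self) -> None:
        if self.hic is None and self.fixture is None:
            raise ValueError("config must provide either a Hi-C path or a "
                             "fixture spec")
        if self.hic is not None and self.locus is None:
            raise ValueError("a locus string is required with real Hi-C input")


def _params_hash(params: dict) -> str:
    return hashlib.sha1(
        json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:12]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.stages: dict[str, dict] = {}
        if path.exists():
            self.stages = json.loads(path.read_text()).get("stages", {})

    def fresh(self, stage: str, params: dict, outputs: list[Path]) -> bool:
        """True if the stage can be skipped (outputs exist, params match)."""
        rec = self.stages.get(stage)
        return (rec is not None and rec["params_hash"] == _params_hash(params)
                and all(Path(o).exists() for o in outputs))

    def record(self, stage: str, params: dict, outputs: list[Path],
               seed: int | None = None, **extra: Any) -> None:
        self.stages[stage] = {
            "params": {k: v for k, v in params.items()},
            "params_hash": _params_hash(params),
            "seed": seed,
            "outputs": [str(o) for o in outputs],
            **extra,
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(
            {"version": __version__, "stages": self.stages},
            indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    chain_params = ChainParams(**config.chain) if config.chain else None

    # ---- inputs: real files or synthetic fixture ----------------------
    fixture_truth = None
    if config.hic is not None:
        locus = parse_locus(config.locus, config.resolution)
        counts = read_contact_matrix(config.hic, locus)
        eqtl_records = read_eqtl_table(config.eqtl) if config.eqtl else []
        annotations = read_tss_bed(config.tss) if config.tss else []
    else:
        stage = "fixture"
        fspec = FixtureSpec(**{**(config.fixture or {}),
                               "seed": stage_seed(config.seed, stage)})
        locus = parse_locus(config.locus, config.resolution) if config.locus \
            else None
        arch = make_archetype_ensembles(fspec, params=chain_params, locus=locus)
        locus = arch[0][1].locus or _synthetic_locus(fspec.n_beads,
                                                     config.resolution)
        for label, ens, _cs in arch:
            ens.locus = locus
        counts = synth_hic_from_ensemble(
            arch[0][1], fspec.depth, seed=stage_seed(config.seed, "hic"),
            locus=locus)
        fixture_truth = arch
        write_contact_matrix(counts, out / "hic.tsv")
        for label, ens, _cs in arch:
            write_ensemble_xyz(ens, out / f"{label}.xyz")
        # eQTL fixture: contact pairs at planted constraints, far free pairs
        rng = np.random.default_rng(stage_seed(config.seed, "eqtl-fixture"))
        planted = [(i, j) for i, j, _, _ in arch[0][2].pairs if j - i >= 8]
        contact_pairs = [planted[k] for k in
                         rng.choice(len(planted), size=min(10, len(planted)),
                                    replace=False)]
        free_pairs = _far_pairs(fspec.n_beads, 10,
                                {(i, j) for i, j, _, _ in arch[0][2].pairs},
                                rng)
        eqtl_records, annotations = synth_eqtl_table(
            locus, contact_pairs, free_pairs, effect=fspec.effect,
            seed=stage_seed(config.seed, "eqtl-table"))
        write_eqtl_table(eqtl_records, out / "eqtl.tsv")
        write_tss_bed(annotations, out / "tss.bed")
        manifest.record(stage, {"fixture": asdict(fspec)},
                        [out / "hic.tsv", out / "eqtl.tsv", out / "tss.bed"],
                        seed=fspec.seed)

    n_beads = locus.n_beads

    # ---- null model ---------------------------------------------------
    stage = "null-model"
    null_path = out / "null.xyz"
    params = {"n": config.n_null, "n_beads": n_beads,
              "chain": config.chain, "seed": stage_seed(config.seed, stage)}
    if manifest.fresh(stage, params, [null_path]):
        null = read_ensemble_xyz(null_path)
        null.locus = locus
    else:
        null = generate_null_ensemble(config.n_null, n_beads,
                                      params=chain_params,
                                      seed=params["seed"], locus=locus)
        write_ensemble_xyz(null, null_path)
        manifest.record(stage, params, [null_path], seed=params["seed"])

    # ---- nonrandom calling -------------------------------------------
    stage = "call-nonrandom"
    calls_path = out / "calls.tsv"
    params = {"alpha": config.alpha, "B": config.B,
              "threshold": config.threshold,
              "seed": stage_seed(config.seed, stage)}
    calls = call_nonrandom(counts, null, alpha=config.alpha, B=config.B,
                           threshold=config.threshold, seed=params["seed"])
    _write_calls(calls, calls_path)
    manifest.record(stage, params, [calls_path], seed=params["seed"],
                    nonrandom_fraction=significant_fraction(calls))

    # ---- constrained folding ------------------------------------------
    stage = "fold"
    folded_path = out / "folded.xyz"
    params = {"n_fold": config.n_fold, "threshold": config.threshold,
              "seed": stage_seed(config.seed, stage)}
    fold_kw = {}
    if config.fold_population:
        fold_kw = {"final_population": config.fold_population,
                   "calibration_population": config.fold_population}
    folded, cal = fold_from_calls(calls, config.n_fold, n_beads,
                                  params=chain_params, seed=params["seed"],
                                  locus=locus, target=config.threshold,
                                  calibration_rounds=config.calibration_rounds,
                                  **fold_kw)
    write_ensemble_xyz(folded, folded_path)
    manifest.record(stage, params, [folded_path], seed=params["seed"],
                    n_constraints=len(cal))

    # ---- simulated map and comparison ---------------------------------
    stage = "simulate-hic"
    sim = simulate_hic(folded, threshold=config.threshold)
    sim_path = out / "simulated.tsv"
    write_contact_matrix(sim, sim_path)
    if fixture_truth:
        reference = contact_frequency_matrix(fixture_truth[0][1],
                                             config.threshold, locus=locus)
    else:
        null_map = contact_frequency_matrix(null, config.threshold,
                                            locus=locus)
        reference = observed_probability(counts, null_map)
    cmp_model = pearson_map_similarity(sim, reference,
                                       min_lag=STRUCTURE_MIN_LAG)
    cmp_base = pearson_map_similarity(distance_decay_baseline(counts),
                                      reference, min_lag=STRUCTURE_MIN_LAG)
    report = {"model_pearson_r": cmp_model.pearson_r,
              "baseline_pearson_r": cmp_base.pearson_r,
              "n_entries": cmp_model.n_entries}
    (out / "comparison.json").write_text(json.dumps(report, indent=2))
    manifest.record(stage, {"threshold": config.threshold},
                    [sim_path, out / "comparison.json"], **report)

    # ---- eQTL spatial analysis ----------------------------------------
    if eqtl_records and annotations:
        stage = "eqtl-contacts"
        seed = stage_seed(config.seed, stage)
        results, skipped = classify_pairs(folded, eqtl_records, annotations,
                                          locus, threshold=config.threshold,
                                          n_sample=5000, seed=seed)
        rows = ["\t".join(["variant_id", "gene_id", "gene_bead", "eqtl_bead",
                           "median_distance_nm", "physical_contact",
                           "abs_nes"])]
        for r in results:
            rows.append("\t".join(map(str, [
                r.record.variant_id, r.record.gene_id, r.gene_bead,
                r.eqtl_bead, f"{r.median_distance:.2f}",
                int(r.physical_contact), f"{r.abs_nes:.4g}"])))
        (out / "eqtl_contacts.tsv").write_text("\n".join(rows) + "\n")
        nes = None
        if any(r.physical_contact for r in results) and \
                any(not r.physical_contact for r in results):
            nes = compare_nes_distributions(results)
            (out / "nes_test.json").write_text(json.dumps(nes, indent=2))
        manifest.record(stage, {"threshold": config.threshold},
                        [out / "eqtl_contacts.tsv"], seed=seed,
                        n_contacts=sum(r.physical_contact for r in results),
                        n_pairs=len(results), n_skipped=len(skipped),
                        nes_p=None if nes is None else nes["p_value"])

        if config.triad:
            stage = "many-body"
            unit = detect_many_body(folded, config.triad,
                                    base_threshold=config.threshold,
                                    n_sample=5000,
                                    seed=stage_seed(config.seed, stage))
            (out / "many_body.json").write_text(json.dumps({
                "members": list(unit.members),
                "median_matrix_nm": unit.median_matrix.tolist(),
                "classified": unit.classified}, indent=2))
            manifest.record(stage, {"triad": config.triad},
                            [out / "many_body.json"],
                            classified=unit.classified)

    # ---- heterogeneity -------------------------------------------------
    if config.K:
        stage = "cluster"
        seed = stage_seed(config.seed, stage)
        sources = ([(label, ens) for label, ens, _ in fixture_truth]
                   if fixture_truth else [("folded", folded)])
        model = cluster_conformations(sources, K=config.K, seed=seed)
        summary = summarize_clusters(model, sources,
                                     threshold=config.threshold)
        (out / "clusters.json").write_text(json.dumps({
            "K": config.K,
            "proportions": {k: v.tolist()
                            for k, v in summary.proportions.items()},
            "mean_rg_nm": summary.mean_rg.tolist(),
            "notices": summary.notices}, indent=2))
        manifest.record(stage, {"K": config.K}, [out / "clusters.json"],
                        seed=seed)

    manifest.save()
    return json.loads(manifest.path.read_text())


def _synthetic_locus(n_beads: int, resolution: int):
    from .genome_io import LocusSpec
    return LocusSpec("chrN", 0, n_beads * resolution, resolution)


def _far_pairs(n_beads: int, n: int, forbidden: set, rng) -> list[tuple[int, int]]:
    """Random long-range pairs away from any planted constraint."""
    near = set()
    for i, j in forbidden:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                near.add((i + di, j + dj))
    out = []
    tries = 0
    while len(out) < n and tries < 10000:
        tries += 1
        i = int(rng.integers(0, n_beads - 30))
        j = i + int(rng.integers(25, min(70, n_beads - i)))
        if j < n_beads and (i, j) not in near and (i, j) not in out:
            out.append((i, j))
    return out


def _write_calls(calls, path: Path) -> None:
    rows = ["\t".join(["i", "j", "observed_p", "null_p", "p_raw", "p_adj",
                       "significant"])]
    for c in calls:
        rows.append("\t".join(map(str, [
            c.i, c.j, f"{c.observed_p:.6g}", f"{c.null_p:.6g}",
            f"{c.p_raw:.6g}", f"{c.p_adj:.6g}", int(c.significant)])))
    Path(path).write_text("\n".join(rows) + "\n")


def read_calls(path: str | Path):
    """Read a calls TSV written by the pipeline back into InteractionCall."""
    from .nonrandom_calling import InteractionCall

    calls = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("i\t"):
            raise ValueError(f"unrecognized calls file {path}")
        for line in fh:
            f = line.split()
            calls.append(InteractionCall(int(f[0]), int(f[1]), float(f[2]),
                                         float(f[3]), float(f[4]), float(f[5]),
                                         bool(int(f[6]))))
    return calls
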