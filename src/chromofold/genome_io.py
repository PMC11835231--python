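"""Readers, writers and coordinate conventions shared across the pipeline.

Conventions
-----------
* Locus strings (``chr2:230805000-231690000``) are 0-based half-open, matching
  Hi-C bin-boundary arithmetic; printed locus spans are exact multiples of the
  bin resolution.
* GTEx-style variant positions (``chr16_86531581_A_T_b38``) are 1-based.
* Genes are represented by their TSS bead (promoter bead) by default; the TSS
  of a BED interval is ``start + 1`` on the + strand and ``end`` on the -
  strand (both 1-based).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "LocusSpec",
    "ContactMatrix",
    "EqtlRecord",
    "GeneAnnotation",
    "parse_locus",
    "format_locus",
    "parse_variant_id",
    "map_to_bead",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_eqtl_table",
    "read_tss_bed",
    "write_ensemble_xyz",
    "read_ensemble_xyz",
]

_LOCUS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class LocusSpec:
    """A genomic window binned into beads at a fixed resolution.

    ``start``/``end`` are 0-based half-open base-pair coordinates; each bead
    covers ``resolution`` bp (5 kb by default, the working resolution of the
    whole pipeline).
    """

    chrom: str
    start: int
    end: int
    resolution: int = 5000

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"locus end ({self.end}) must exceed start ({self.start})")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        span = self.end - self.start
        if span % self.resolution:
            raise ValueError(
                f"locus span {span} bp is not divisible by resolution "
                f"{self.resolution} (remainder {span % self.resolution})"
            )
        if span // self.resolution < 2:
            raise ValueError("locus must span at least 2 beads")

    @property
    def n_beads(self) -> int:
        return (self.end - self.start) // self.resolution

    def bead_starts(self) -> np.ndarray:
        return self.start + self.resolution * np.arange(self.n_beads)


def parse_locus(text: str, resolution: int = 5000) -> LocusSpec:
    """Parse a ``chrom:start-end`` string into a :class:`LocusSpec`."""
    m = _LOCUS_RE.match(text.strip().replace(",", "").replace(" ", ""))
    if m is None:
        raise ValueError(f"malformed locus string: {text!r} (expected chrom:start-end)")
    return LocusSpec(m["chrom"], int(m["start"]), int(m["end"]), resolution)


def format_locus(locus: LocusSpec) -> str:
    return f"{locus.chrom}:{locus.start}-{locus.end}"


def parse_variant_id(text: str) -> tuple[str, int, str, str, str]:
    """Split a GTEx b38-dialect variant id into (chrom, pos, ref, alt, build).

    Position is 1-based, per GTEx convention.
    """
    fields = text.strip().split("_")
    if len(fields) != 5:
        raise ValueError(
            f"variant id {text!r} has {len(fields)} underscore fields, expected 5"
        )
    chrom, pos_s, ref, alt, build = fields
    try:
        pos = int(pos_s)
    except ValueError:
        raise ValueError(f"variant id {text!r}: position {pos_s!r} is not an integer")
    if pos < 1:
        raise ValueError(f"variant id {text!r}: position must be >= 1")
    return chrom, pos, ref, alt, build


def map_to_bead(pos: int, locus: LocusSpec) -> int:
    """Map a 1-based base-pair position to its bead index within ``locus``."""
    zero_based = pos - 1
    if not (locus.start <= zero_based < locus.end):
        raise ValueError(
            f"position {pos} (1-based) falls outside locus "
            f"{format_locus(locus)}"
        )
    return (zero_based - locus.start) // locus.resolution


@dataclass
class ContactMatrix:
    """Symmetric per-pair contact counts or probabilities for a locus."""

    locus: LocusSpec
    values: np.ndarray
    kind: Literal["counts", "probability"] = "counts"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = self.locus.n_beads
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match locus ({n} beads)")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("contact matrix entries must be nonnegative")
        if self.kind == "probability":
            if (v > 1 + 1e-9).any():
                raise ValueError("probability matrix entries must be <= 1")
            np.fill_diagonal(v, 1.0)
        elif self.kind == "counts":
            if not np.allclose(v, np.round(v)):
                raise ValueError("count matrix entries must be integers")
        else:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        # store symmetrized to be robust to float asymmetry on read paths
        self.values = (v + v.T) / 2.0

    @property
    def n_beads(self) -> int:
        return self.locus.n_beads


def read_contact_matrix(path: str | Path, locus: LocusSpec,
                        kind: Literal["counts", "probability"] = "counts") -> ContactMatrix:
    """Read a contact matrix from triplet or dense text.

    Triplet lines are ``bin1_start TAB bin2_start TAB count`` with bin starts
    on the locus resolution grid; a line per unordered pair is mirrored.
    A dense file (auto-detected by having ``n_beads`` columns) is read as a
    whitespace-separated square matrix.
    """
    path = Path(path)
    n = locus.n_beads
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
    values = np.zeros((n, n), dtype=float)
    if rows and len(rows[0]) == n and n != 3:
        if len(rows) != n:
            raise ValueError(f"dense matrix in {path} has {len(rows)} rows, expected {n}")
        values = np.array([[float(x) for x in r] for r in rows])
    else:
        for r in rows:
            if len(r) != 3:
                raise ValueError(f"triplet line with {len(r)} fields in {path}")
            b1, b2, c = int(r[0]), int(r[1]), float(r[2])
            if c < 0:
                raise ValueError(f"negative count {c} in {path}")
            idx = []
            for b in (b1, b2):
                off = b - locus.start
                if off % locus.resolution or not (0 <= off < locus.end - locus.start):
                    raise ValueError(
                        f"bin start {b} off-grid or outside locus {format_locus(locus)}"
                    )
                idx.append(off // locus.resolution)
            i, j = idx
            values[i, j] = c
            values[j, i] = c
    if kind == "probability":
        np.fill_diagonal(values, 1.0)
    return ContactMatrix(locus, values, kind)


def write_contact_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the upper triangle (including diagonal) as tab-separated triplets."""
    locus = matrix.locus
    starts = locus.bead_starts()
    with open(path, "w") as fh:
        for i in range(matrix.n_beads):
            for j in range(i, matrix.n_beads):
                v = matrix.values[i, j]
                if v == 0:
                    continue
                if matrix.kind == "counts":
                    fh.write(f"{starts[i]}\t{starts[j]}\t{int(round(v))}\n")
                else:
                    fh.write(f"{starts[i]}\t{starts[j]}\t{v:.10g}\n")


@dataclass(frozen=True)
class EqtlRecord:
    """One significant variant-gene association in the GTEx dialect."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    gene_id: str
    nes: float  # signed slope of the expression-on-genotype regression
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("variant position must be >= 1")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 1-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError("TSS must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def read_eqtl_table(path: str | Path) -> list[EqtlRecord]:
    """Read a GTEx-style significant variant-gene pair table (TSV).

    Requires at least ``variant_id``, ``gene_id`` and ``slope`` columns; an
    optional ``tissue`` column is carried through. NES is the slope column.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene_id", "slope"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"eQTL table {path} missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        chrom, pos, ref, alt, _build = parse_variant_id(row.variant_id)
        tissue = str(getattr(row, "tissue", ""))
        records.append(
            EqtlRecord(row.variant_id, chrom, pos, ref, alt,
                       str(row.gene_id), float(row.slope), tissue)
        )
    return records


def write_eqtl_table(records: Iterable[EqtlRecord], path: str | Path) -> None:
    rows = [
        {"variant_id": r.variant_id, "gene_id": r.gene_id,
         "slope": r.nes, "tissue": r.tissue}
        for r in records
    ]
    pd.DataFrame(rows, columns=["variant_id", "gene_id", "slope", "tissue"]).to_csv(
        path, sep="\t", index=False
    )


def read_tss_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read gene TSS annotations from BED (name field = gene id).

    TSS = start + 1 for + strand genes, = end for - strand genes (1-based).
    """
    annotations = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"BED line with fewer than 4 fields: {line!r}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) >= 6 else "+"
            tss = start + 1 if strand == "+" else end
            annotations.append(GeneAnnotation(name, chrom, tss, strand))
    return annotations


def write_tss_bed(annotations: Iterable[GeneAnnotation], path: str | Path,
                  width: int = 1) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            if a.strand == "+":
                start, end = a.tss - 1, a.tss - 1 + width
            else:
                start, end = a.tss - width, a.tss
            fh.write(f"{a.chrom}\t{start}\t{end}\t{a.gene_id}\t0\t{a.strand}\n")


def write_ensemble_xyz(ensemble, path: str | Path) -> None:
    """Write an ensemble as multi-model plain text.

    Per conformation: a ``#model <k> weight <w>`` header, then one
    ``x y z`` line per bead in nm (3 decimals).
    """
    conformations = ensemble.conformations
    if not conformations:
        raise ValueError("refusing to write an empty ensemble")
    run_ids = getattr(ensemble, "run_ids", None)
    n_beads = len(conformations[0].coords)
    with open(path, "w") as fh:
        for k, conf in enumerate(conformations):
            if len(conf.coords) != n_beads:
                raise ValueError("all conformations must share a bead count")
            header = f"#model {k} weight {conf.log_weight:.10g}"
            if run_ids is not None:
                header += f" run {int(run_ids[k])}"
            fh.write(header + "\n")
            for x, y, z in np.asarray(conf.coords):
                fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")


def read_ensemble_xyz(path: str | Path):
    """Read an ensemble written by :func:`write_ensemble_xyz`."""
    from .null_ensemble import Conformation, ConformationEnsemble

    conformations = []
    run_ids: list[int] = []
    coords: list[list[float]] = []
    log_weight = 0.0
    started = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#model"):
                f = line.split()
                if len(f) not in (4, 6) or f[2] != "weight" or \
                        (len(f) == 6 and f[4] != "run"):
                    raise ValueError(f"malformed model header: {line!r}")
                if started:
                    conformations.append(
                        Conformation(np.array(coords), log_weight, validate=False)
                    )
                coords = []
                log_weight = float(f[3])
                if len(f) == 6:
                    run_ids.append(int(f[5]))
                started = True
            else:
                f = line.split()
                if len(f) != 3:
                    raise ValueError(f"malformed coordinate line: {line!r}")
                coords.append([float(x) for x in f])
    if started:
        conformations.append(Conformation(np.array(coords), log_weight, validate=False))
    if not conformations:
        raise ValueError(f"no conformations found in {path}")
    n_beads = len(conformations[0].coords)
    for c in conformations:
        if len(c.coords) != n_beads:
            raise ValueError("inconsistent bead counts across models")
    ids = np.array(run_ids) if len(run_ids) == len(conformations) else None
    return ConformationEnsemble(conformations, run_ids=ids)
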