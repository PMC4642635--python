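"""Readers and writers for the plain-text interchange formats.

Formats: phased haplotype TSV (two rows per individual, id column first),
phased VCF (diploid "|"-separated genotypes), pedigree TSV (id, sire, dam;
unknown coded 0/NA), genotype matrix TSV ({0,1,2} dosages), interval-weight
files, and square or long relationship-matrix TSV. Matrix output defaults
to 17 significant digits so that exact identities survive a file round
trip.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, ParseError
from .genomes import Genome
from .pedigree import Pedigree
from .relatedness import RelationshipMatrix

__all__ = [
    "read_haplotype_table",
    "write_haplotype_table",
    "read_phased_vcf",
    "read_pedigree",
    "write_pedigree",
    "read_genotype_matrix",
    "read_weights",
    "write_matrix",
    "write_matrix_long",
    "read_matrix",
    "genomes_to_haplotype_rows",
]


def read_haplotype_table(path) -> list[tuple[str, list[str], list[str]]]:
    """Phased haplotype TSV: two consecutive rows per individual.

    First column is the individual id, remaining columns are allele symbols
    (one per marker). A header line whose first field is ``id`` is skipped.
    Returns ``(individual, alleles_hap1, alleles_hap2)`` triples.
    """
    rows: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if lineno == 1 and parts[0].lower() == "id":
                continue
            if len(parts) < 2:
                raise ParseError("haplotype row needs id + alleles", str(path), lineno)
            if any(a == "" or a in (".", "NA") for a in parts[1:]):
                raise ParseError(
                    f"missing allele in haplotype row for {parts[0]!r}; "
                    "phased input must be complete", str(path), lineno,
                )
            rows.append((parts[0], parts[1:]))
    if len(rows) % 2:
        raise ParseError(
            f"odd number of haplotype rows ({len(rows)}); expected two per individual",
            str(path),
        )
    out = []
    for (id1, h1), (id2, h2) in zip(rows[0::2], rows[1::2]):
        if id1 != id2:
            raise ParseError(
                f"consecutive haplotype rows have different ids: {id1!r} vs {id2!r}",
                str(path),
            )
        if len(h1) != len(h2):
            raise ParseError(f"ragged haplotypes for individual {id1!r}", str(path))
        out.append((id1, h1, h2))
    return out


def write_haplotype_table(path, phased: Sequence[tuple[str, Sequence[str], Sequence[str]]]):
    with open(path, "w") as fh:
        if phased:
            p = len(phased[0][1])
            fh.write("id\t" + "\t".join(f"m{k}" for k in range(p)) + "\n")
        for ind, h1, h2 in phased:
            fh.write(ind + "\t" + "\t".join(map(str, h1)) + "\n")
            fh.write(ind + "\t" + "\t".join(map(str, h2)) + "\n")


def genomes_to_haplotype_rows(
    genomes: Sequence[Genome], apfa
) -> list[tuple[str, list[str], list[str]]]:
    """Convert genomes back to allele rows using the model's edge alleles."""
    allele = {e.id: e.allele for e in apfa.edges}
    return [
        (g.id, [allele[s] for s in g.hap1], [allele[s] for s in g.hap2])
        for g in genomes
    ]


def read_phased_vcf(path) -> list[tuple[str, list[str], list[str]]]:
    """Phased diploid VCF to allele-index haplotype triples.

    Uses the allele indices (0 = REF, 1.. = ALT) as symbols. Every genotype
    must be phased ("|") and complete; one contig is treated as one
    interval sequence in record order.
    """
    from cyvcf2 import VCF  # deferred: optional at import time

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    h1: list[list[str]] = [[] for _ in samples]
    h2: list[list[str]] = [[] for _ in samples]
    for var in vcf:
        for i, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise ParseError(
                    f"missing genotype for sample {samples[i]!r} at "
                    f"{var.CHROM}:{var.POS}; phased input must be complete",
                    str(path),
                )
            if not phased:
                raise ParseError(
                    f"unphased genotype for sample {samples[i]!r} at "
                    f"{var.CHROM}:{var.POS}", str(path),
                )
            h1[i].append(str(a))
            h2[i].append(str(b))
    return [(s, h1[i], h2[i]) for i, s in enumerate(samples)]


def read_pedigree(path) -> Pedigree:
    """Pedigree TSV ``id<TAB>sire<TAB>dam``; unknown parents 0/NA/empty."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if lineno == 1 and parts[0].lower() in ("id", "individual"):
                continue
            if len(parts) != 3:
                raise ParseError(
                    f"expected 3 columns (id, sire, dam), got {len(parts)}",
                    str(path), lineno,
                )
            records.append(tuple(parts))
    return Pedigree.from_records(records)


def write_pedigree(path, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\n")
        for ind, sire, dam in ped.records:
            fh.write(f"{ind}\t{sire or '0'}\t{dam or '0'}\n")


def read_genotype_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Genotype TSV: rows = individuals (id first), values in {0,1,2}."""
    ids, rows = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if lineno == 1 and parts[0].lower() == "id":
                continue
            try:
                rows.append([int(v) for v in parts[1:]])
            except ValueError:
                raise ParseError("non-integer genotype value", str(path), lineno)
            ids.append(parts[0])
    if not rows:
        raise ParseError("empty genotype matrix", str(path))
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"ragged genotype rows (widths {sorted(widths)})", str(path))
    return np.array(rows, dtype=np.int64), ids


def read_weights(path, p: int | None = None) -> np.ndarray:
    """Interval weights: whitespace/newline-separated non-negative reals."""
    with open(path) as fh:
        tokens = fh.read().split()
    try:
        w = np.array([float(t) for t in tokens])
    except ValueError:
        raise ParseError("non-numeric weight", str(path))
    if p is not None and w.size != p:
        raise DimensionError(f"expected {p} weights, found {w.size}")
    return w


def _fmt(digits: int):
    return lambda v: f"{v:.{digits}g}"


def write_matrix(path, matrix: RelationshipMatrix, digits: int = 17) -> None:
    """Square TSV: id header row and column, full precision by default."""
    fmt = _fmt(digits)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(matrix.ids) + "\n")
        for i, ind in enumerate(matrix.ids):
            fh.write(ind + "\t" + "\t".join(fmt(v) for v in matrix.values[i]) + "\n")


def write_matrix_long(path, matrix: RelationshipMatrix, digits: int = 17) -> None:
    """Long format: ``id1<TAB>id2<TAB>value`` for i ≤ j."""
    fmt = _fmt(digits)
    with open(path, "w") as fh:
        fh.write("id1\tid2\tvalue\n")
        for i, a in enumerate(matrix.ids):
            for j in range(i, matrix.n):
                fh.write(f"{a}\t{matrix.ids[j]}\t{fmt(matrix.values[i, j])}\n")


def read_matrix(path, kind: str = "") -> RelationshipMatrix:
    """Read a square matrix TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ParseError("matrix row and column ids differ", str(path))
    return RelationshipMatrix(df.to_numpy(dtype=float), ids, kind=kind)
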