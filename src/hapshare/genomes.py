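"""Diploid genomes as segment collections and the haplomarker design matrix.

A genome is an unordered pair of haplotypes, each a length-``p`` sequence of
segment ids (one per interval). After recombination a haplotype need not be
a connected path in the APFA — offspring gametes cross between paths — so
genomes store per-interval segment ids rather than paths. The derived
multiplicity map ``x_is ∈ {0, 1, 2}`` (segment appearing on both haplotypes
counts twice) sums to ``2p``, with exactly two units of multiplicity mass
per interval.

Stacking multiplicity rows over individuals gives the N×|E| haplomarker
design matrix ``X``, the basis of the relatedness measures.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .apfa import Apfa
from .errors import DimensionError, ModelError, UntraceableHaplotypeError
from .multiset import SegmentMultiset

__all__ = [
    "Genome",
    "HaplomarkerMatrix",
    "genome_from_paths",
    "design_matrix",
    "haplotypes_to_genomes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Genome:
    """A diploid genome: two haplotypes of segment ids, one per interval."""

    id: str
    hap1: tuple[str, ...]
    hap2: tuple[str, ...]

    def __post_init__(self):
        if len(self.hap1) != len(self.hap2):
            raise DimensionError(
                f"genome {self.id!r}: haplotypes have lengths "
                f"{len(self.hap1)} and {len(self.hap2)}"
            )
        object.__setattr__(self, "hap1", tuple(self.hap1))
        object.__setattr__(self, "hap2", tuple(self.hap2))

    @property
    def p(self) -> int:
        return len(self.hap1)

    @cached_property
    def multiset(self) -> SegmentMultiset:
        """Multiplicity map; cardinality is ``2p``."""
        out = SegmentMultiset()
        for seg in self.hap1 + self.hap2:
            dict.__setitem__(out, seg, out.get(seg, 0) + 1)
        return out

    @property
    def homozygosity(self) -> float:
        """Fraction of intervals carrying the same segment twice (``f_i``)."""
        return sum(a == b for a, b in zip(self.hap1, self.hap2)) / self.p


def genome_from_paths(
    individual_id: str,
    hap1: Sequence[str],
    hap2: Sequence[str],
    apfa: Apfa,
) -> Genome:
    """Build a genome from two haplotypes, validating against the model.

    Each segment id must exist in ``apfa`` at the interval where it is used;
    the haplotypes need not be connected paths.
    """
    if len(hap1) != apfa.p or len(hap2) != apfa.p:
        raise DimensionError(
            f"genome {individual_id!r}: haplotype lengths ({len(hap1)}, {len(hap2)}) "
            f"do not match p={apfa.p}"
        )
    for hap_no, hap in ((1, hap1), (2, hap2)):
        for level, seg in enumerate(hap):
            if not apfa.has_edge(seg):
                raise ModelError(
                    f"genome {individual_id!r}, haplotype {hap_no}: unknown segment "
                    f"{seg!r} at interval {level}"
                )
            if apfa.edge(seg).level != level:
                raise ModelError(
                    f"genome {individual_id!r}, haplotype {hap_no}: segment {seg!r} "
                    f"belongs to interval {apfa.edge(seg).level}, used at {level}"
                )
    return Genome(individual_id, tuple(hap1), tuple(hap2))


class HaplomarkerMatrix:
    """Integer N×|E| multiplicity matrix with labelled rows and columns.

    ``values[i, s] = x_is ∈ {0, 1, 2}``; rows sum to ``2p`` and each
    per-interval column block sums to 2 in every row. Column order is the
    model's canonical segment order.
    """

    def __init__(
        self,
        values: np.ndarray,
        ids: Sequence[str],
        segment_ids: Sequence[str],
        levels: Sequence[int],
    ):
        self.values = np.asarray(values, dtype=np.int64)
        self.ids = list(ids)
        self.segment_ids = list(segment_ids)
        self.levels = np.asarray(levels, dtype=np.int64)
        if self.values.shape != (len(self.ids), len(self.segment_ids)):
            raise DimensionError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} individuals × {len(self.segment_ids)} segments"
            )
        if len(self.levels) != len(self.segment_ids):
            raise DimensionError("one level per segment column is required")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return int(self.levels.max()) + 1 if self.levels.size else 0


def design_matrix(genomes: Sequence[Genome], apfa: Apfa) -> HaplomarkerMatrix:
    """Haplomarker design matrix for a set of genomes on one model."""
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DimensionError(f"duplicate individual id(s): {dupes}")
    segment_ids = apfa.segment_ids
    col = {s: j for j, s in enumerate(segment_ids)}
    X = np.zeros((len(genomes), len(segment_ids)), dtype=np.int64)
    for i, g in enumerate(genomes):
        if g.p != apfa.p:
            raise DimensionError(f"genome {g.id!r} has p={g.p}, model has p={apfa.p}")
        for seg, mult in g.multiset.items():
            try:
                X[i, col[seg]] = mult
            except KeyError:
                raise ModelError(
                    f"genome {g.id!r} uses segment {seg!r} absent from the model"
                ) from None
    levels = [apfa.edge(s).level for s in segment_ids]
    return HaplomarkerMatrix(X, ids, segment_ids, levels)


def _trace(
    alleles: Sequence[str], apfa: Apfa, individual: str, hap_no: int
) -> tuple[str, ...]:
    """Walk root-to-sink choosing, at each level, the edge emitting the allele.

    When two outgoing edges of a vertex emit the same allele (possible in a
    multigraph) the higher-probability edge wins, ties broken by edge id; a
    warning is logged.
    """
    if len(alleles) != apfa.p:
        raise DimensionError(
            f"individual {individual!r}: {len(alleles)} alleles, model has p={apfa.p}"
        )
    path: list[str] = []
    vertex = apfa.root
    for level, allele in enumerate(alleles):
        matches = [e for e in apfa.out_edges(vertex) if e.allele == str(allele)]
        if not matches:
            raise UntraceableHaplotypeError(individual, hap_no, level, str(allele))
        if len(matches) > 1:
            matches.sort(key=lambda e: (-e.prob, e.id))
            logger.warning(
                "ambiguous allele %r at interval %d for individual %r: "
                "chose edge %s", allele, level, individual, matches[0].id,
            )
        path.append(matches[0].id)
        vertex = matches[0].target
    return tuple(path)


def haplotypes_to_genomes(
    phased: Sequence[tuple[str, Sequence[str], Sequence[str]]],
    apfa: Apfa,
) -> list[Genome]:
    """Map phased allele sequences onto APFA segments.

    ``phased`` holds one ``(individual_id, alleles_hap1, alleles_hap2)``
    triple per individual; alleles must be complete (no missing values —
    impute upstream). Deterministic.
    """
    genomes = []
    for individual, h1, h2 in phased:
        genomes.append(
            Genome(individual, _trace(h1, apfa, individual, 1), _trace(h2, apfa, individual, 2))
        )
    return genomes
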