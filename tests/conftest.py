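"""Shared fixtures: small APFA constructors, random genomes, brute oracles."""

from __future__ import annotations

import numpy as np
import pytest

from hapshare.apfa import Apfa, Edge
from hapshare.genomes import Genome
from hapshare.multiset import cardinality, multiset_intersect, multiset_product


def chain_multigraph_apfa(p: int, n_alleles: int) -> Apfa:
    """One vertex per level, ``n_alleles`` parallel edges per interval."""
    vertices = {f"V{k}": k for k in range(p + 1)}
    edges = [
        Edge(f"L{k}E{a}", k, f"V{k}", f"V{k + 1}", str(a), 1.0 / n_alleles)
        for k in range(p)
        for a in range(n_alleles)
    ]
    return Apfa(p, vertices, tuple(edges))


def seg(level: int, allele: int) -> str:
    return f"L{level}E{allele}"


def random_genome(apfa: Apfa, rng: np.random.Generator, ind_id: str) -> Genome:
    """Arbitrary genome: independent uniform segment per interval per haplotype."""
    by_level: dict[int, list[str]] = {}
    for e in apfa.edges:
        by_level.setdefault(e.level, []).append(e.id)
    hap1 = tuple(by_level[k][rng.integers(len(by_level[k]))] for k in range(apfa.p))
    hap2 = tuple(by_level[k][rng.integers(len(by_level[k]))] for k in range(apfa.p))
    return Genome(ind_id, hap1, hap2)


# -- independent brute-force oracles (multiset definitions, no matrices) ----

def oracle_b(g1: Genome, g2: Genome) -> float:
    return cardinality(multiset_intersect(g1.multiset, g2.multiset)) / (2 * g1.p)


def oracle_c(g1: Genome, g2: Genome) -> float:
    return cardinality(multiset_product(g1.multiset, g2.multiset)) / (2 * g1.p)


def oracle_ibs_coancestry(g1: Genome, g2: Genome) -> float:
    """Mean of the 4p allele-pair identity indicators (IBS coancestry)."""
    hits = 0
    for k in range(g1.p):
        for a in (g1.hap1[k], g1.hap2[k]):
            for b in (g2.hap1[k], g2.hap2[k]):
                hits += a == b
    return hits / (4 * g1.p)


@pytest.fixture
def rng():
    return np.random.default_rng(90210)


@pytest.fixture
def small_apfa():
    return chain_multigraph_apfa(p=6, n_alleles=3)


@pytest.fixture
def worked_trio():
    """A mother/father/offspring trio matching the worked-example values.

    Parents are fully heterozygous 20-interval genomes with product measure
    0.75 between them; the offspring's haplotypes coincide at 9 of the 20
    intervals, giving homozygosity 0.45 and self-product 1.45.
    """
    p = 20
    apfa = chain_multigraph_apfa(p, n_alleles=4)
    mother = Genome("mother",
                    tuple(seg(k, 0) for k in range(p)),
                    tuple(seg(k, 1) for k in range(p)))
    father = Genome("father",
                    tuple(seg(k, 0) for k in range(p)),
                    tuple(seg(k, 1) if k < 10 else seg(k, 2) for k in range(p)))
    offspring = Genome("offspring",
                       tuple(seg(k, 0) for k in range(p)),
                       tuple(seg(k, 0) if k < 9 else seg(k, 1) for k in range(p)))
    return apfa, mother, father, offspring
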