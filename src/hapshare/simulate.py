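"""Meiosis and pedigree gene-drop simulation on segment sequences.

During meiosis a diploid genome ``G = [H¹ + H²]`` is partitioned into two
complementary gametes of ``p`` segments each; an offspring receives one
gamete from each parent, the four combinations being equiprobable. The key
structural fact is that the expectations of the offspring relatedness
measures depend only on the parental measures, not on how segregation
partitioned the genomes:

    E(c_ik) = (c_ii + c_ij)/2        E(c_kk) = 1 + c_ij/2
    E(f_k)  = c_ij/2                 E(c_kh) = (c_ih + c_jh)/2
    E(b_ik) = E(b_jk) = 1/2 + c_ij/4

:func:`exact_expectation` verifies these identities by exhaustively
averaging over the four gamete combinations for *any* supplied partition —
the invariance makes the choice of crossover model immaterial to the
expectations. The simulator itself uses the simplest partition process
satisfying the gamete axioms: a uniformly chosen starting haplotype with
independent Bernoulli crossovers at each interval boundary. No expression
is known for the four-individual intersect expectation ``E(b_kh)``; it is
only estimated by Monte Carlo here.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apfa import Apfa, validate_apfa
from .errors import DimensionError, ModelError
from .genomes import Genome, design_matrix
from .multiset import cardinality
from .pedigree import Pedigree, numerator_matrix, pedigree_distance
from .relatedness import intersect_measure, product_measure, vanraden_g

__all__ = [
    "SimConfig",
    "GametePair",
    "make_gametes",
    "mate",
    "exact_expectation",
    "expected_offspring_moments",
    "simulate_pedigree",
    "monte_carlo_expectations",
    "sample_path",
    "genotypes_from_genomes",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``crossover_rate`` is the probability of a crossover at each of the
    ``p − 1`` interval boundaries (default 0.05 — a light, map-free rate;
    the verified expectation identities are invariant to it). ``seed`` is
    mandatory for all stochastic operations.
    """

    crossover_rate: float = 0.05
    seed: int = 0
    replicates: int = 1

    def __post_init__(self):
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise DimensionError(
                f"crossover rate must be in [0, 1], got {self.crossover_rate}"
            )
        if self.replicates < 0:
            raise DimensionError("replicate count must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class GametePair:
    """Two complementary gametes from one meiosis.

    At every interval the two gametes carry the parent's two segments
    between them, so ``hap1 + hap2`` equals the parent genome as a
    multiset.
    """

    hap1: tuple[str, ...]
    hap2: tuple[str, ...]
    crossovers: tuple[int, ...] = ()


def make_gametes(
    genome: Genome, config: SimConfig, rng: np.random.Generator
) -> GametePair:
    """Partition a genome into two complementary gametes.

    The first gamete starts on a uniformly chosen parental haplotype and
    switches source at each boundary independently with probability
    ``config.crossover_rate``; the second is the complement. With rate 0
    the parental haplotypes pass intact; with rate 1 they alternate every
    interval.
    """
    p = genome.p
    source = int(rng.integers(2))
    switches = rng.random(p - 1) < config.crossover_rate if p > 1 else np.array([])
    h1, h2 = [], []
    crossovers = []
    parental = (genome.hap1, genome.hap2)
    for k in range(p):
        if k > 0 and switches[k - 1]:
            source = 1 - source
            crossovers.append(k)
        h1.append(parental[source][k])
        h2.append(parental[1 - source][k])
    return GametePair(tuple(h1), tuple(h2), tuple(crossovers))


def mate(
    gi: Genome,
    gj: Genome,
    config: SimConfig,
    rng: np.random.Generator,
    child_id: str = "offspring",
) -> Genome:
    """One offspring: a uniformly chosen gamete from each parent."""
    if gi.p != gj.p:
        raise DimensionError(
            f"parents have different interval counts: {gi.p} and {gj.p}"
        )
    pair_i = make_gametes(gi, config, rng)
    pair_j = make_gametes(gj, config, rng)
    hi = (pair_i.hap1, pair_i.hap2)[int(rng.integers(2))]
    hj = (pair_j.hap1, pair_j.hap2)[int(rng.integers(2))]
    return Genome(child_id, hi, hj)


def _pair_measures(a: Genome, b: Genome) -> tuple[int, int]:
    """(Σ min, Σ product) integer numerators between two genomes."""
    ma, mb = a.multiset, b.multiset
    return cardinality(ma & mb), cardinality(ma * mb)


def exact_expectation(
    gi: Genome,
    gj: Genome,
    partition_i: GametePair,
    partition_j: GametePair,
    others: Sequence[Genome] = (),
) -> dict:
    """Average offspring measures over the four equiprobable gamete combos.

    For the fixed partitions ``G_i = [H_i¹ + H_i²]`` and ``G_j = [H_j¹ +
    H_j²]``, forms the four possible offspring and returns the exact
    averages of ``c_ik``, ``c_jk``, ``c_kk``, ``f_k``, ``b_ik``, ``b_jk``
    and, for each supplied genome ``h``, ``c_kh``. These equal the closed
    forms of :func:`expected_offspring_moments` for *any* valid partition.
    """
    p = gi.p
    if gj.p != p:
        raise DimensionError("parent genomes must have the same interval count")
    for name, part, parent in (("i", partition_i, gi), ("j", partition_j, gj)):
        if len(part.hap1) != p or len(part.hap2) != p:
            raise DimensionError(f"partition of parent {name} has wrong length")
        recombined = {}
        for seg in part.hap1 + part.hap2:
            recombined[seg] = recombined.get(seg, 0) + 1
        if recombined != dict(parent.multiset):
            raise DimensionError(
                f"partition of parent {name} is not complementary: "
                "the two gametes must jointly carry the parent's 2p segments"
            )

    combos = [
        Genome("k", hi, hj)
        for hi in (partition_i.hap1, partition_i.hap2)
        for hj in (partition_j.hap1, partition_j.hap2)
    ]
    # integer accumulation; divide once
    sum_c_ik = sum(_pair_measures(gi, k)[1] for k in combos)
    sum_c_jk = sum(_pair_measures(gj, k)[1] for k in combos)
    sum_b_ik = sum(_pair_measures(gi, k)[0] for k in combos)
    sum_b_jk = sum(_pair_measures(gj, k)[0] for k in combos)
    sum_c_kk = sum(_pair_measures(k, k)[1] for k in combos)
    sum_f_k = sum(sum(a == b for a, b in zip(k.hap1, k.hap2)) for k in combos)
    out = {
        "E_c_ik": sum_c_ik / (8 * p),
        "E_c_jk": sum_c_jk / (8 * p),
        "E_c_kk": sum_c_kk / (8 * p),
        "E_f_k": sum_f_k / (4 * p),
        "E_b_ik": sum_b_ik / (8 * p),
        "E_b_jk": sum_b_jk / (8 * p),
    }
    if others:
        out["E_c_kh"] = {
            h.id: sum(_pair_measures(h, k)[1] for k in combos) / (8 * p) for h in others
        }
    return out


def expected_offspring_moments(
    c_ii: float, c_jj: float, c_ij: float, c_ih: dict | None = None,
    c_jh: dict | None = None,
) -> dict:
    """Closed-form offspring expectations given parental product measures."""
    out = {
        "E_c_ik": (c_ii + c_ij) / 2.0,
        "E_c_jk": (c_jj + c_ij) / 2.0,
        "E_c_kk": 1.0 + c_ij / 2.0,
        "E_f_k": c_ij / 2.0,
        "E_b_ik": 0.5 + c_ij / 4.0,
        "E_b_jk": 0.5 + c_ij / 4.0,
    }
    if c_ih is not None and c_jh is not None:
        out["E_c_kh"] = {h: (c_ih[h] + c_jh[h]) / 2.0 for h in c_ih}
    return out


def sample_path(apfa: Apfa, rng: np.random.Generator) -> tuple[str, ...]:
    """One root-to-sink path sampled edge-by-edge by edge probability."""
    path = []
    vertex = apfa.root
    for _level in range(apfa.p):
        outs = apfa.out_edges(vertex)
        probs = np.array([e.prob for e in outs])
        choice = outs[int(rng.choice(len(outs), p=probs / probs.sum()))]
        path.append(choice.id)
        vertex = choice.target
    return tuple(path)


def simulate_pedigree(
    apfa: Apfa,
    ped: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    founder_genomes: dict[str, Genome] | None = None,
) -> list[Genome]:
    """Gene-drop through a pedigree on an APFA segment pool.

    Founders receive two independent probability-weighted root-to-sink
    paths; every other individual is produced by :func:`mate` from its
    parents' genomes in topological order. An individual with exactly one
    recorded parent receives one gamete from that parent and one fresh
    APFA-sampled haplotype for the unknown side. Deterministic given the
    seed.

    ``founder_genomes`` overrides sampling for the named founders — e.g.
    segment-disjoint heterozygous founders make the realized product
    measure coincide with identity-by-descent relatedness, the regime in
    which simulated C converges to the pedigree expectation A.
    """
    diags = validate_apfa(apfa)
    if diags:
        raise ModelError(
            "cannot sample founders from an invalid APFA: " + "; ".join(diags[:3])
        )
    if rng is None:
        rng = config.rng()
    founder_genomes = founder_genomes or {}
    parents = ped.parents
    genomes: dict[str, Genome] = {}
    for ind in ped.topological_order():
        sire, dam = parents[ind]
        if sire is None and dam is None:
            if ind in founder_genomes:
                genomes[ind] = founder_genomes[ind]
            else:
                genomes[ind] = Genome(ind, sample_path(apfa, rng), sample_path(apfa, rng))
        elif sire is not None and dam is not None:
            child = mate(genomes[sire], genomes[dam], config, rng, child_id=ind)
            genomes[ind] = child
        else:
            known = genomes[sire if sire is not None else dam]
            pair = make_gametes(known, config, rng)
            gamete = (pair.hap1, pair.hap2)[int(rng.integers(2))]
            genomes[ind] = Genome(ind, gamete, sample_path(apfa, rng))
    return [genomes[i] for i in ped.ids]


def genotypes_from_genomes(genomes: Sequence[Genome], apfa: Apfa) -> np.ndarray:
    """Marker dosage matrix: per interval, the count of non-"0" alleles."""
    n, p = len(genomes), apfa.p
    allele = {e.id: e.allele for e in apfa.edges}
    M = np.zeros((n, p), dtype=np.int64)
    for i, g in enumerate(genomes):
        for k in range(p):
            M[i, k] = (allele[g.hap1[k]] != "0") + (allele[g.hap2[k]] != "0")
    return M


def monte_carlo_expectations(
    apfa: Apfa,
    ped: Pedigree,
    config: SimConfig,
    founder_genomes: dict[str, Genome] | None = None,
) -> pd.DataFrame:
    """Distribution of relatedness measures by pedigree distance.

    Replicates the gene-drop ``config.replicates`` times and summarizes, per
    pedigree-distance class, the mean and standard deviation of the
    intersect measure b, the product measure c, the pedigree expectation a,
    and vanRaden's g (from simulated marker dosages; monomorphic markers
    dropped, NaN when fewer than two polymorphic markers remain). Pairs at
    infinite distance (no pedigree path) are grouped under distance ``inf``.
    """
    ids = ped.ids
    n = len(ids)
    A = numerator_matrix(ped)
    D = pedigree_distance(ped).to_numpy()
    iu = np.triu_indices(n, k=1)
    dist = D[iu]

    rng = config.rng()
    b_all, c_all, g_all = [], [], []
    for _rep in range(config.replicates):
        genomes = simulate_pedigree(apfa, ped, config, rng, founder_genomes)
        X = design_matrix(genomes, apfa)
        b_all.append(intersect_measure(X).values[iu])
        c_all.append(product_measure(X).values[iu])
        M = genotypes_from_genomes(genomes, apfa)
        polymorphic = ~(M == M[0]).all(axis=0)
        if polymorphic.sum() >= 2:
            g_all.append(
                vanraden_g(M[:, polymorphic], ids=ids).values[iu]
            )
        else:
            g_all.append(np.full(iu[0].size, np.nan))

    rows = []
    if config.replicates:
        b_mat = np.vstack(b_all)
        c_mat = np.vstack(c_all)
        g_mat = np.vstack(g_all)
        a_vec = A.values[iu]
        for d in sorted(set(dist.tolist())):
            sel = dist == d
            reps = config.replicates
            rows.append(
                {
                    "distance": d,
                    "n_pairs": int(sel.sum()) * reps,
                    "b_mean": float(np.mean(b_mat[:, sel])),
                    "b_sd": float(np.std(b_mat[:, sel], ddof=1)) if sel.sum() * reps > 1 else np.nan,
                    "c_mean": float(np.mean(c_mat[:, sel])),
                    "c_sd": float(np.std(c_mat[:, sel], ddof=1)) if sel.sum() * reps > 1 else np.nan,
                    "a_mean": float(np.mean(a_vec[sel])),
                    "a_sd": float(np.std(a_vec[sel], ddof=1)) if sel.sum() > 1 else np.nan,
                    "g_mean": float(np.nanmean(g_mat[:, sel])),
                    "g_sd": float(np.nanstd(g_mat[:, sel], ddof=1)) if sel.sum() * reps > 1 else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "distance", "n_pairs", "b_mean", "b_sd", "c_mean", "c_sd",
            "a_mean", "a_sd", "g_mean", "g_sd",
        ],
    )


def simulation_sidecar(config: SimConfig, apfa: Apfa, ped: Pedigree) -> str:
    """JSON sidecar describing a simulation run (seed, rate, sizes)."""
    return json.dumps(
        {
            "seed": config.seed,
            "crossover_rate": config.crossover_rate,
            "replicates": config.replicates,
            "p": apfa.p,
            "n_segments": len(apfa.edges),
            "n_individuals": len(ped.ids),
            "founders": ped.founders(),
        },
        indent=2,
    )
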