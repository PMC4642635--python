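"""Numerator matrix A, pedigree distance, hybrid R, conditioning, consistency."""

import numpy as np
import pytest

from hapshare.errors import DimensionError, NumericalError, PedigreeError
from hapshare.genomes import Genome
from hapshare.pedigree import (
    ConditioningSpec,
    Pedigree,
    condition_matrix,
    consistency_check,
    hybrid_matrix,
    numerator_matrix,
    pedigree_distance,
)
from hapshare.relatedness import RelationshipMatrix
from hapshare.simulate import SimConfig, simulate_pedigree

from conftest import chain_multigraph_apfa


def random_pedigree(n, n_founders, rng, single_parent_prob=0.0):
    records = [(f"i{k}", None, None) for k in range(n_founders)]
    for k in range(n_founders, n):
        i, j = rng.choice(k, size=2, replace=False)
        sire, dam = f"i{i}", f"i{j}"
        if rng.random() < single_parent_prob:
            dam = None
        records.append((f"i{k}", sire, dam))
    return Pedigree.from_records(
        [(a, b or "0", c or "0") for a, b, c in records]
    )


def gene_drop_oracle(ped: Pedigree, n_drops: int, rng) -> np.ndarray:
    """Monte-Carlo IBD estimate of A by dropping founder alleles. Vectorized.

    Each founder receives two globally unique alleles; every descendant
    inherits one random allele from each parent (a fresh unique allele for
    an unknown parent). Returns (A_hat, SE) stacked as a (2, n, n) array.
    """
    order = ped.topological_order()
    parents = ped.parents
    alleles = {}
    next_allele = [0]

    def fresh():
        a = np.arange(next_allele[0], next_allele[0] + n_drops) * 0 + next_allele[0]
        next_allele[0] += 1
        return np.full(n_drops, a[0], dtype=np.int64)

    for ind in order:
        sire, dam = parents[ind]
        pair = []
        for par in (sire, dam):
            if par is None:
                pair.append(fresh())
            else:
                pa, pb = alleles[par]
                pick = rng.integers(0, 2, n_drops, dtype=np.int64)
                pair.append(np.where(pick == 0, pa, pb))
        alleles[ind] = (pair[0], pair[1])

    ids = ped.ids
    n = len(ids)
    a_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        ai1, ai2 = alleles[ids[i]]
        for j in range(i, n):
            aj1, aj2 = alleles[ids[j]]
            if i == j:
                per_rep = 1.0 + (ai1 == ai2)
            else:
                per_rep = (
                    (ai1 == aj1).astype(float) + (ai1 == aj2) + (ai2 == aj1) + (ai2 == aj2)
                ) / 2.0
            a_hat[i, j] = a_hat[j, i] = per_rep.mean()
            se[i, j] = se[j, i] = per_rep.std(ddof=1) / np.sqrt(n_drops)
    return np.stack([a_hat, se])


class TestNumeratorMatrix:
    def test_trio_textbook_values(self):
        ped = Pedigree.from_records([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])
        A = numerator_matrix(ped)
        assert A.loc("s", "o") == 0.5
        assert A.loc("d", "o") == 0.5
        assert A.loc("o", "o") == 1.0
        assert A.loc("s", "d") == 0.0

    def test_offspring_of_full_sibs_is_inbred(self):
        ped = Pedigree.from_records(
            [("a", "0", "0"), ("b", "0", "0"),
             ("c", "a", "b"), ("d", "a", "b"), ("x", "c", "d")]
        )
        A = numerator_matrix(ped)
        assert A.loc("c", "d") == 0.5
        assert A.loc("x", "x") == 1.25  # inbreeding 0.25

    def test_matches_gene_drop_oracle(self, rng):
        """A equals the 100k-drop IBD estimate within Monte-Carlo error.

        With ~1275 simultaneous entries a per-entry 3·SE band is expected
        to be exceeded a few times by chance, so the 3·SE check is applied
        to 99% of entries with a Bonferroni-style 4.5·SE family-wise cap.
        """
        ped = random_pedigree(50, 10, rng, single_parent_prob=0.1)
        A = numerator_matrix(ped)
        a_hat, se = gene_drop_oracle(ped, n_drops=100_000, rng=rng)
        z = np.abs(A.values - a_hat) / (se + 1e-12)
        assert np.mean(z <= 3.0) >= 0.99
        assert np.max(z) <= 4.5

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree.from_records([("a", "b", "0"), ("b", "a", "0")])

    def test_unknown_parent_reference_rejected(self):
        with pytest.raises(PedigreeError, match="no pedigree record"):
            Pedigree.from_records([("a", "ghost", "0")])


class TestPedigreeDistance:
    @pytest.fixture
    def family(self):
        # grandparents -> two full sibs -> cousins -> second cousins
        return Pedigree.from_records([
            ("gp1", "0", "0"), ("gp2", "0", "0"),
            ("p1", "gp1", "gp2"), ("p2", "gp1", "gp2"),
            ("m1", "0", "0"), ("m2", "0", "0"),
            ("c1", "p1", "m1"), ("c2", "p2", "m2"),
            ("n1", "0", "0"), ("n2", "0", "0"),
            ("s1", "c1", "n1"), ("s2", "c2", "n2"),
            ("island", "0", "0"),
        ])

    def test_parent_offspring_and_sib_cousin_distances(self, family):
        d = pedigree_distance(family, [("gp1", "p1"), ("p1", "p2"), ("c1", "c2"), ("s1", "s2")])
        assert d == [1.0, 2.0, 4.0, 6.0]

    def test_half_sibs_at_distance_two(self):
        ped = Pedigree.from_records(
            [("f", "0", "0"), ("m1", "0", "0"), ("m2", "0", "0"),
             ("h1", "f", "m1"), ("h2", "f", "m2")]
        )
        assert pedigree_distance(ped, [("h1", "h2")]) == [2.0]

    def test_unreachable_pair_is_infinite(self, family):
        assert pedigree_distance(family, [("gp1", "island")]) == [float("inf")]
        D = pedigree_distance(family)
        assert np.isinf(D.loc["island", "gp1"])

    def test_unknown_id_rejected(self, family):
        with pytest.raises(PedigreeError, match="unknown individual"):
            pedigree_distance(family, [("gp1", "nobody")])


class TestHybridMatrix:
    @pytest.fixture
    def ped(self, rng):
        return random_pedigree(20, 5, rng)

    def test_empty_genotyped_set_reduces_to_a(self, ped):
        A = numerator_matrix(ped)
        R = hybrid_matrix(ped, [], A)
        assert np.array_equal(R.values, A.values)

    def test_full_genotyped_set_returns_realized(self, ped, rng):
        n = len(ped.ids)
        M = rng.random((n, n))
        C = RelationshipMatrix((M + M.T) / 2, ped.ids, "C")
        R = hybrid_matrix(ped, ped.ids, C)
        assert np.allclose(R.values, C.values)

    def test_trio_hand_recursion(self):
        ped = Pedigree.from_records([("p1", "0", "0"), ("p2", "0", "0"), ("o", "p1", "p2")])
        C = RelationshipMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), ["p1", "p2"], "C")
        R = hybrid_matrix(ped, ["p1", "p2"], C)
        assert R.loc("o", "o") == pytest.approx(1.2)
        assert R.loc("p1", "o") == pytest.approx(0.7)
        assert R.loc("p2", "o") == pytest.approx(0.7)

    def test_idempotent_when_realized_is_a_itself(self, ped):
        A = numerator_matrix(ped)
        S = ped.ids[:7]
        R = hybrid_matrix(ped, S, A.restrict(S))
        assert np.allclose(R.values, A.values, atol=1e-12)

    def test_genotyped_not_in_pedigree_rejected(self, ped):
        A = numerator_matrix(ped)
        with pytest.raises(PedigreeError, match="not in pedigree"):
            hybrid_matrix(ped, ["stranger"], A)


def random_spd(n, rng):
    M = rng.random((n, n)) - 0.5
    return M @ M.T + n * np.eye(n)


class TestConditionMatrix:
    def test_identity_replacement_is_noop(self, rng):
        A = RelationshipMatrix(random_spd(6, rng), [f"i{k}" for k in range(6)])
        spec = ConditioningSpec(tuple(A.ids[:3]), A.values[:3, :3])
        out = condition_matrix(A, spec)
        assert np.allclose(out.values, A.values, atol=1e-10)

    def test_marginal_replaced_and_conditional_preserved(self, rng):
        n, k = 8, 3
        ids = [f"i{j}" for j in range(n)]
        A = RelationshipMatrix(random_spd(n, rng), ids)
        star = random_spd(k, rng)
        out = condition_matrix(A, ConditioningSpec(tuple(ids[:k]), star))
        V, W = A.values, out.values
        assert np.max(np.abs(W[:k, :k] - star)) <= 1e-8
        cond_before = V[k:, k:] - V[k:, :k] @ np.linalg.solve(V[:k, :k], V[:k, k:])
        cond_after = W[k:, k:] - W[k:, :k] @ np.linalg.solve(W[:k, :k], W[:k, k:])
        assert np.max(np.abs(cond_after - cond_before)) <= 1e-8

    def test_agrees_with_precision_increment_formula(self, rng):
        """Ã equals (A⁻¹ + blockdiag(E, 0))⁻¹ with E = (A*₁₁)⁻¹ − (A₁₁)⁻¹."""
        n, k = 7, 4
        ids = [f"i{j}" for j in range(n)]
        A = RelationshipMatrix(random_spd(n, rng), ids)
        star = random_spd(k, rng)
        out = condition_matrix(A, ConditioningSpec(tuple(ids[:k]), star))
        E = np.linalg.inv(star) - np.linalg.inv(A.values[:k, :k])
        prec = np.linalg.inv(A.values)
        prec[:k, :k] += E
        assert np.allclose(out.values, np.linalg.inv(prec), atol=1e-8)

    def test_precision_differs_only_in_group_one_block(self, rng):
        n, k = 6, 2
        ids = [f"i{j}" for j in range(n)]
        A = RelationshipMatrix(random_spd(n, rng), ids)
        star = random_spd(k, rng)
        out = condition_matrix(A, ConditioningSpec(tuple(ids[:k]), star))
        dprec = np.linalg.inv(out.values) - np.linalg.inv(A.values)
        dprec[:k, :k] = 0.0
        assert np.max(np.abs(dprec)) < 1e-8

    def test_singular_group_one_block_rejected(self, rng):
        V = random_spd(5, rng)
        V[0] = V[1]
        V[:, 0] = V[:, 1]
        A = RelationshipMatrix(V, [f"i{j}" for j in range(5)])
        with pytest.raises(NumericalError):
            condition_matrix(A, ConditioningSpec(("i0", "i1"), np.eye(2)))


class TestConsistencyCheck:
    def test_self_consistency_gives_zero_deviation(self, rng):
        ped = random_pedigree(15, 5, rng)
        A = numerator_matrix(ped)
        stats = consistency_check(A, A, group1_size=5, replicates=3, seed=11)
        assert (stats["msd"] < 1e-16).all()

    def test_seeded_determinism(self, rng):
        ped = random_pedigree(15, 5, rng)
        A = numerator_matrix(ped)
        X = RelationshipMatrix(A.values + 0.01 * np.eye(A.n), A.ids)
        s1 = consistency_check(A, X, 4, 5, seed=3)
        s2 = consistency_check(A, X, 4, 5, seed=3)
        assert s1.equals(s2)

    def test_gene_drop_realized_matrix_is_consistent_with_a(self, rng):
        """(A|C₁₁)₂₂ tracks C₂₂ when C is realized IBD from segment-disjoint founders."""
        n, n_founders, p = 30, 8, 120
        ped = random_pedigree(n, n_founders, rng)
        apfa = chain_multigraph_apfa(p, 2 * n_founders)
        founders = {
            f"i{k}": Genome(
                f"i{k}",
                tuple(f"L{j}E{2 * k}" for j in range(p)),
                tuple(f"L{j}E{2 * k + 1}" for j in range(p)),
            )
            for k in range(n_founders)
        }
        from hapshare.genomes import design_matrix
        from hapshare.relatedness import product_measure

        config = SimConfig(crossover_rate=0.1, seed=5, replicates=1)
        genomes = simulate_pedigree(apfa, ped, config, founder_genomes=founders)
        C = product_measure(design_matrix(genomes, apfa))
        A = numerator_matrix(ped)
        stats = consistency_check(A, C, group1_size=12, replicates=10, seed=7)
        assert np.abs(stats["slope_no_intercept"].mean() - 1.0) < 0.05

    def test_group_size_bounds(self, rng):
        ped = random_pedigree(10, 4, rng)
        A = numerator_matrix(ped)
        with pytest.raises(DimensionError):
            consistency_check(A, A, group1_size=10, replicates=1, seed=0)
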