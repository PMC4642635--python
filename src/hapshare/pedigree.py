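"""Pedigree-based expected relatedness and hybrid expected/realized matrices.

The numerator relationship matrix ``A`` holds the pedigree expectation of
relatedness under the classical assumptions (non-inbred, mutually unrelated
founders): ``a_ij = 2θ_ij`` off the diagonal and ``1 + θ_i`` on it, where θ
is the identity-by-descent coefficient of coancestry. It is computed by the
recursive tabular method over a topological ordering in which parents
precede offspring.

When a subset ``S`` of individuals has realized (genomic) relatedness
available, the same recursion seeded with those values yields a hybrid
matrix ``R``: realized within ``S``, pedigree-propagated elsewhere. A
complementary route conditions the whole covariance matrix on a replacement
of the ``S`` block, preserving the conditional covariance of the rest; that
operator is also the basis of the consistency check between pedigree and
genomic measures.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DimensionError, NumericalError, PedigreeError
from .relatedness import RelationshipMatrix, compare_matrices

__all__ = [
    "Pedigree",
    "ConditioningSpec",
    "numerator_matrix",
    "pedigree_distance",
    "hybrid_matrix",
    "condition_matrix",
    "consistency_check",
]

UNKNOWN = {None, "", "0", "NA", "na", ".", 0}


@dataclass(frozen=True)
class Pedigree:
    """Individuals with optional sire/dam references; acyclic by invariant.

    ``records`` is a tuple of ``(id, sire, dam)`` with ``None`` for unknown
    parents. Every named parent must itself be a record.
    """

    records: tuple[tuple[str, str | None, str | None], ...]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[object, object, object]]
    ) -> "Pedigree":
        """Normalize raw records; unknown parents may be coded 0, NA or empty."""
        cleaned = []
        for ind, sire, dam in records:
            def norm(x):
                return None if x in UNKNOWN else str(x)
            cleaned.append((str(ind), norm(sire), norm(dam)))
        ped = cls(tuple(cleaned))
        ped._check()
        return ped

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        return {ind: (s, d) for ind, s, d in self.records}

    def _check(self) -> None:
        ids = self.ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual id(s): {dupes}")
        known = set(ids)
        for ind, sire, dam in self.records:
            for parent in (sire, dam):
                if parent is not None and parent not in known:
                    raise PedigreeError(
                        f"parent {parent!r} of {ind!r} has no pedigree record"
                    )
        self.topological_order()

    def topological_order(self) -> list[str]:
        """Kahn sort with ties broken by input order; parents precede offspring."""
        order_index = {ind: i for i, (ind, _, _) in enumerate(self.records)}
        children: dict[str, list[str]] = {i: [] for i in order_index}
        indeg = {i: 0 for i in order_index}
        for ind, sire, dam in self.records:
            for parent in (sire, dam):
                if parent is not None:
                    children[parent].append(ind)
                    indeg[ind] += 1
        ready = sorted((i for i, d in indeg.items() if d == 0), key=order_index.get)
        out: list[str] = []
        while ready:
            node = ready.pop(0)
            out.append(node)
            newly = []
            for child in children[node]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    newly.append(child)
            ready = sorted(set(ready) | set(newly), key=order_index.get)
        if len(out) != len(order_index):
            cycle = sorted(set(order_index) - set(out), key=order_index.get)
            raise PedigreeError(
                f"pedigree contains a cycle involving: {', '.join(cycle)}"
            )
        return out

    def founders(self) -> list[str]:
        return [ind for ind, s, d in self.records if s is None and d is None]


def numerator_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix A by the tabular method.

    In topological order, for individual ``k`` with parents ``i, j``:
    ``a_kk = 1 + a_ij / 2`` and ``a_kh = (a_ih + a_jh) / 2`` for earlier
    ``h``; an unknown parent contributes relationship 0. Rows/columns are
    returned in pedigree input order.
    """
    return _tabular(ped, genotyped=frozenset(), realized=None, kind="A")


def _tabular(
    ped: Pedigree,
    genotyped: frozenset[str],
    realized: RelationshipMatrix | None,
    kind: str,
) -> RelationshipMatrix:
    order = ped.topological_order()
    pos = {ind: i for i, ind in enumerate(order)}
    parents = ped.parents
    n = len(order)
    R = np.zeros((n, n))

    if realized is not None:
        sub = realized.restrict(sorted(genotyped, key=pos.get))
        idx = np.array([pos[i] for i in sub.ids])
        R[np.ix_(idx, idx)] = sub.values

    in_s = np.zeros(n, dtype=bool)
    for ind in genotyped:
        in_s[pos[ind]] = True

    def rel(a: str | None, b_idx: int) -> float:
        if a is None:
            return 0.0
        return R[pos[a], b_idx]

    for k_idx, k in enumerate(order):
        sire, dam = parents[k]
        if not in_s[k_idx]:
            if sire is not None and dam is not None:
                r_ij = R[pos[sire], pos[dam]]
            else:
                r_ij = 0.0
            R[k_idx, k_idx] = 1.0 + r_ij / 2.0
        for h_idx in range(k_idx):
            if in_s[k_idx] and in_s[h_idx]:
                continue
            val = (rel(sire, h_idx) + rel(dam, h_idx)) / 2.0
            R[k_idx, h_idx] = R[h_idx, k_idx] = val

    # back to input order
    input_ids = ped.ids
    perm = np.array([pos[i] for i in input_ids])
    return RelationshipMatrix(R[np.ix_(perm, perm)], input_ids, kind=kind)


def hybrid_matrix(
    ped: Pedigree, genotyped: Iterable[str], realized: RelationshipMatrix
) -> RelationshipMatrix:
    """Hybrid expected/realized relationship matrix R.

    Entries within the genotyped set ``S`` are fixed to the realized
    genomic values; every other entry is filled by the numerator-matrix
    recursion in topological order, so expectations downstream of ``S`` are
    adjusted by the realized information. With ``S`` empty this is exactly
    ``A``; with ``S`` covering everyone it is exactly the realized matrix.
    """
    S = frozenset(str(i) for i in genotyped)
    missing = S - set(ped.ids)
    if missing:
        raise PedigreeError(f"genotyped id(s) not in pedigree: {sorted(missing)}")
    if S and realized is None:
        raise DimensionError("realized matrix required when genotyped set is non-empty")
    if S:
        absent = S - set(realized.ids)
        if absent:
            raise DimensionError(
                f"genotyped id(s) missing from the realized matrix: {sorted(absent)}"
            )
    return _tabular(ped, S, realized if S else None, kind="R")


def pedigree_distance(
    ped: Pedigree, pairs: Sequence[tuple[str, str]] | None = None
):
    """Shortest-path distance in the undirected parent-child graph.

    Parent-offspring pairs are at distance 1, full and half sibs at 2,
    first cousins at 4, second cousins at 6. Returns a DataFrame (ids ×
    ids, ``inf`` where unreachable) or, if ``pairs`` is given, a list of
    distances for those pairs.
    """
    graph = nx.Graph()
    graph.add_nodes_from(ped.ids)
    for ind, sire, dam in ped.records:
        for parent in (sire, dam):
            if parent is not None:
                graph.add_edge(parent, ind)
    if pairs is not None:
        out = []
        for a, b in pairs:
            if a not in graph or b not in graph:
                missing = a if a not in graph else b
                raise PedigreeError(f"unknown individual id {missing!r}")
            try:
                out.append(float(nx.shortest_path_length(graph, a, b)))
            except nx.NetworkXNoPath:
                out.append(float("inf"))
        return out
    ids = ped.ids
    n = len(ids)
    D = np.full((n, n), np.inf)
    pos = {v: i for i, v in enumerate(ids)}
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        for tgt, d in lengths.items():
            D[pos[src], pos[tgt]] = float(d)
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass(frozen=True)
class ConditioningSpec:
    """Replacement of the marginal covariance of a subgroup.

    ``group1`` lists the ids whose marginal block is replaced by
    ``a11_star`` (symmetric, same order as ``group1``).
    """

    group1: tuple[str, ...]
    a11_star: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a11_star, dtype=float)
        if a.shape != (len(self.group1), len(self.group1)):
            raise DimensionError(
                f"replacement block shape {a.shape} does not match "
                f"{len(self.group1)} group-one ids"
            )
        if np.max(np.abs(a - a.T), initial=0.0) > 1e-8:
            raise DimensionError("replacement block must be symmetric")
        object.__setattr__(self, "a11_star", a)


def condition_matrix(A: RelationshipMatrix, spec: ConditioningSpec) -> RelationshipMatrix:
    """Condition a covariance matrix on a new group-one marginal block.

    Produces ``Ã = A | A*₁₁`` with ``Ã₁₁ = A*₁₁`` while the conditional
    covariance of group two given group one is unchanged — equivalently,
    the precision matrix receives the increment ``E = (A*₁₁)⁻¹ − (A₁₁)⁻¹``
    in its group-one block only. Computed via Cholesky solves of ``A₁₁``
    (never explicit inverses):

    ``Ã₁₂ = A*₁₁ A₁₁⁻¹ A₁₂``,
    ``Ã₂₂ = A₂₂ − A₂₁ A₁₁⁻¹ A₁₂ + (A₁₁⁻¹A₁₂)ᵀ A*₁₁ (A₁₁⁻¹A₁₂)``.
    """
    missing = set(spec.group1) - set(A.ids)
    if missing:
        raise DimensionError(f"group-one id(s) not in matrix: {sorted(missing)}")
    pos = {v: i for i, v in enumerate(A.ids)}
    idx1 = np.array([pos[g] for g in spec.group1], dtype=int)
    idx2 = np.array([i for i in range(A.n) if A.ids[i] not in set(spec.group1)], dtype=int)

    V = A.values
    A11 = V[np.ix_(idx1, idx1)]
    A12 = V[np.ix_(idx1, idx2)]
    A22 = V[np.ix_(idx2, idx2)]
    try:
        cf = scipy.linalg.cho_factor(A11)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"group-one block is not positive definite: {exc}") from None
    Z = scipy.linalg.cho_solve(cf, A12)  # A11^{-1} A12
    S = spec.a11_star
    T12 = S @ Z
    T22 = A22 - A12.T @ Z + Z.T @ S @ Z

    out = np.empty_like(V)
    out[np.ix_(idx1, idx1)] = S
    out[np.ix_(idx1, idx2)] = T12
    out[np.ix_(idx2, idx1)] = T12.T
    out[np.ix_(idx2, idx2)] = (T22 + T22.T) / 2.0
    try:
        scipy.linalg.cholesky(out)
    except scipy.linalg.LinAlgError:
        raise NumericalError("conditioned matrix is not positive definite")
    return RelationshipMatrix(out, A.ids, kind="conditioned")


def consistency_check(
    A: RelationshipMatrix,
    X: RelationshipMatrix,
    group1_size: int,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Consistency of a realized measure X with the pedigree expectation A.

    Per replicate: sample group one uniformly without replacement, form
    ``A | X₁₁`` and compare the group-two off-diagonals of the conditioned
    matrix with those of ``X₂₂``. If X is consistent with A up to founder
    assumptions, the two should agree closely. Seeded and reproducible.
    """
    if A.ids != X.ids:
        raise DimensionError("matrices must share the same ids in the same order")
    if not 1 <= group1_size < A.n:
        raise DimensionError(
            f"group1_size must be in 1..{A.n - 1}, got {group1_size}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    ids = np.array(A.ids)
    for rep in range(replicates):
        g1 = list(ids[np.sort(rng.choice(A.n, size=group1_size, replace=False))])
        g2 = [i for i in A.ids if i not in set(g1)]
        x11 = X.restrict(g1).values
        cond = condition_matrix(A, ConditioningSpec(tuple(g1), x11))
        stats = compare_matrices(X.restrict(g2), cond.restrict(g2))
        stats["replicate"] = rep
        rows.append(stats)
    return pd.DataFrame(rows)
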