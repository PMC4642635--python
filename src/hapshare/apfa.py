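"""Acyclic probabilistic finite automata (APFA) defining a genome segmentation.

An APFA is a leveled directed multigraph modelling the joint distribution of
``p`` markers at the haplotype level. Vertices sit at levels ``0..p`` with a
single root (level 0) and a single sink (level ``p``); each edge joins a
level-``k`` vertex to a level-``k+1`` vertex, carries a marker allele symbol
and a transition probability, and outgoing probabilities from every non-sink
vertex sum to one. A haplotype is a root-to-sink path and its probability is
the product of the probabilities of its edges.

The edges ARE the segments of the genome segmentation: two haplotypes that
traverse the same edge in an interval share the same DNA in that interval.
Because every edge belongs to exactly one level, segment sets of distinct
intervals are disjoint by construction.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace

from .errors import DimensionError, InvalidPathError, ModelError, ParseError

__all__ = [
    "Edge",
    "Apfa",
    "validate_apfa",
    "haplotype_probability",
    "build_trie_apfa",
    "read_apfa",
    "write_apfa",
    "read_beagle_dag",
    "enumerate_paths",
]

#: tolerance on the sum of outgoing-edge probabilities per vertex
PROB_TOL = 1e-9


@dataclass(frozen=True)
class Edge:
    """One chromosomal segment: an edge of the APFA.

    ``level`` is the 0-based interval index the segment occupies (the level
    of its source vertex); ``allele`` is the marker allele the edge emits.
    """

    id: str
    level: int
    source: str
    target: str
    allele: str
    prob: float


@dataclass(frozen=True)
class Apfa:
    """A leveled APFA over ``p`` intervals.

    ``vertex_levels`` maps vertex id to its level in ``{0..p}``; ``edges``
    are stored in canonical order (level, then edge id). Construction does
    not validate — call :func:`validate_apfa` (or ``.validate()``).
    """

    p: int
    vertex_levels: dict[str, int]
    edges: tuple[Edge, ...]

    # caches, keyed by object identity
    _by_id: dict[str, Edge] = field(default_factory=dict, repr=False, compare=False)
    _out: dict[str, list[Edge]] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "edges", tuple(sorted(self.edges, key=lambda e: (e.level, e.id)))
        )
        seen: dict[str, Edge] = {}
        out: dict[str, list[Edge]] = {v: [] for v in self.vertex_levels}
        for e in self.edges:
            if e.id in seen:
                raise ModelError(f"duplicate edge id {e.id!r}")
            seen[e.id] = e
            out.setdefault(e.source, []).append(e)
        object.__setattr__(self, "_by_id", seen)
        object.__setattr__(self, "_out", out)

    # -- accessors ---------------------------------------------------------
    @property
    def root(self) -> str:
        roots = [v for v, lev in self.vertex_levels.items() if lev == 0]
        if len(roots) != 1:
            raise ModelError(f"expected a single root, found {len(roots)}")
        return roots[0]

    @property
    def sink(self) -> str:
        sinks = [v for v, lev in self.vertex_levels.items() if lev == self.p]
        if len(sinks) != 1:
            raise ModelError(f"expected a single sink, found {len(sinks)}")
        return sinks[0]

    @property
    def segment_ids(self) -> tuple[str, ...]:
        """Canonical segment (edge) ordering: by level, then id."""
        return tuple(e.id for e in self.edges)

    def edge(self, edge_id: str) -> Edge:
        try:
            return self._by_id[edge_id]
        except KeyError:
            raise ModelError(f"unknown segment id {edge_id!r}") from None

    def has_edge(self, edge_id: str) -> bool:
        return edge_id in self._by_id

    def out_edges(self, vertex: str) -> list[Edge]:
        return self._out.get(vertex, [])

    def validate(self) -> list[str]:
        return validate_apfa(self)

    def canonical(self) -> "Apfa":
        """Relabel vertices and edges deterministically.

        Vertices become ``V{level}N{ordinal}`` and edges ``L{level}E{ordinal}``,
        ordinals assigned by a breadth-first traversal from the root with
        edges ordered by (source ordinal, allele, target). Two models that
        differ only in labels canonicalize to equal objects, which is the
        notion of equality used for file round-trips.
        """
        order: dict[str, str] = {self.root: "V0N0"}
        counters = [0] * (self.p + 1)
        edge_names: dict[str, str] = {}
        ecount = [0] * self.p
        frontier = [self.root]
        for level in range(self.p):
            nxt: list[str] = []
            for v in frontier:
                outs = sorted(self.out_edges(v), key=lambda e: (e.allele, e.target, e.id))
                for e in outs:
                    if e.target not in order:
                        counters[level + 1] += 1
                        order[e.target] = f"V{level + 1}N{counters[level + 1] - 1}"
                        nxt.append(e.target)
                    edge_names[e.id] = f"L{level}E{ecount[level]}"
                    ecount[level] += 1
            frontier = nxt
        new_edges = tuple(
            replace(
                e,
                id=edge_names[e.id],
                source=order[e.source],
                target=order[e.target],
            )
            for e in self.edges
            if e.id in edge_names
        )
        new_vertices = {order[v]: lev for v, lev in self.vertex_levels.items() if v in order}
        return Apfa(self.p, new_vertices, new_edges)


def validate_apfa(apfa: Apfa) -> list[str]:
    """Check the structural invariants; return diagnostics (empty iff valid).

    Checks: single root and sink, edge leveling (level-``k`` source to
    level-``k+1`` target, edge level equals source level), probabilities in
    ``[0, 1]`` summing to one per non-sink vertex within ``1e-9``, and every
    vertex lying on some root-to-sink path.
    """
    diags: list[str] = []
    if apfa.p < 1:
        diags.append(f"interval count p={apfa.p} must be >= 1")
        return diags
    for bad in (v for v, lev in apfa.vertex_levels.items() if not 0 <= lev <= apfa.p):
        diags.append(f"vertex {bad!r} has level {apfa.vertex_levels[bad]} outside 0..{apfa.p}")
    n_root = sum(1 for lev in apfa.vertex_levels.values() if lev == 0)
    n_sink = sum(1 for lev in apfa.vertex_levels.values() if lev == apfa.p)
    if n_root != 1:
        diags.append(f"expected exactly one root at level 0, found {n_root}")
    if n_sink != 1:
        diags.append(f"expected exactly one sink at level {apfa.p}, found {n_sink}")

    for e in apfa.edges:
        if e.source not in apfa.vertex_levels or e.target not in apfa.vertex_levels:
            diags.append(f"edge {e.id!r} references an unknown vertex")
            continue
        src_lev = apfa.vertex_levels[e.source]
        tgt_lev = apfa.vertex_levels[e.target]
        if tgt_lev != src_lev + 1:
            diags.append(
                f"edge {e.id!r} skips levels: {e.source!r}@{src_lev} -> {e.target!r}@{tgt_lev}"
            )
        if e.level != src_lev:
            diags.append(f"edge {e.id!r} has level {e.level} but source level {src_lev}")
        if not 0.0 <= e.prob <= 1.0:
            diags.append(f"edge {e.id!r} probability {e.prob} outside [0, 1]")

    for v, lev in apfa.vertex_levels.items():
        if lev == apfa.p:
            continue
        outs = apfa.out_edges(v)
        if not outs:
            diags.append(f"non-sink vertex {v!r} has no outgoing edges")
            continue
        total = math.fsum(e.prob for e in outs)
        if abs(total - 1.0) > PROB_TOL:
            diags.append(f"outgoing probabilities at vertex {v!r} sum to {total!r}, not 1")

    # reachability: forward from root, backward from sink
    fwd = {v for v, lev in apfa.vertex_levels.items() if lev == 0}
    for _ in range(apfa.p):
        fwd |= {e.target for e in apfa.edges if e.source in fwd}
    bwd = {v for v, lev in apfa.vertex_levels.items() if lev == apfa.p}
    for _ in range(apfa.p):
        bwd |= {e.source for e in apfa.edges if e.target in bwd}
    for v in sorted(set(apfa.vertex_levels) - (fwd & bwd)):
        diags.append(f"vertex {v!r} is not on any root-to-sink path")
    return diags


def haplotype_probability(apfa: Apfa, path: Sequence[str]) -> float:
    """Probability of a haplotype: the product of its edge probabilities.

    ``path`` is a sequence of edge ids, one per level ``0..p-1``; consecutive
    edges must share the intermediate vertex, starting at the root and ending
    at the sink.
    """
    if len(path) != apfa.p:
        raise InvalidPathError(f"path has length {len(path)}, expected p={apfa.p}")
    prob = 1.0
    current = apfa.root
    for level, eid in enumerate(path):
        e = apfa.edge(eid)
        if e.level != level:
            raise InvalidPathError(f"edge {eid!r} has level {e.level}, expected {level}")
        if e.source != current:
            raise InvalidPathError(
                f"path disconnected at level {level}: edge {eid!r} starts at "
                f"{e.source!r}, not {current!r}"
            )
        prob *= e.prob
        current = e.target
    if current != apfa.sink:
        raise InvalidPathError(f"path ends at {current!r}, not at the sink")
    return prob


def enumerate_paths(apfa: Apfa) -> list[tuple[tuple[str, ...], float]]:
    """All root-to-sink paths with their probabilities (small models only)."""
    out: list[tuple[tuple[str, ...], float]] = []

    def walk(vertex: str, level: int, acc: tuple[str, ...], prob: float) -> None:
        if level == apfa.p:
            out.append((acc, prob))
            return
        for e in apfa.out_edges(vertex):
            walk(e.target, level + 1, acc + (e.id,), prob * e.prob)

    walk(apfa.root, 0, (), 1.0)
    return out


def build_trie_apfa(haplotypes: Sequence[Sequence[str]]) -> Apfa:
    """Build a prefix-tree APFA from observed haplotypes.

    One vertex per distinct prefix, all length-``p`` prefixes merged into a
    single sink; the probability of an edge is the fraction of haplotypes
    through its source vertex that take it, so each input haplotype has
    positive probability under the model. A minimal stand-in for full
    haplotype-cluster model selection.
    """
    if not haplotypes:
        raise DimensionError("cannot build an APFA from an empty haplotype list")
    p = len(haplotypes[0])
    if p == 0:
        raise DimensionError("haplotypes must be non-empty")
    for i, h in enumerate(haplotypes):
        if len(h) != p:
            raise DimensionError(f"haplotype {i} has length {len(h)}, expected {p}")

    # prefix -> vertex id; counts per (prefix, allele)
    root, sink = "V0N0", f"V{p}N0"
    vertex_levels = {root: 0, sink: p}
    vertex_of: dict[tuple[str, ...], str] = {(): root}
    counters = [0] * (p + 1)
    edge_counts: dict[tuple[str, str, str, int], int] = {}  # (src, tgt, allele, lev)
    through: dict[str, int] = {}

    for h in haplotypes:
        prefix: tuple[str, ...] = ()
        for level in range(p):
            src = vertex_of[prefix]
            through[src] = through.get(src, 0) + 1
            prefix = prefix + (str(h[level]),)
            if level == p - 1:
                tgt = sink
            elif prefix in vertex_of:
                tgt = vertex_of[prefix]
            else:
                counters[level + 1] += 1
                tgt = f"V{level + 1}N{counters[level + 1] - 1}"
                vertex_of[prefix] = tgt
                vertex_levels[tgt] = level + 1
            key = (src, tgt, str(h[level]), level)
            edge_counts[key] = edge_counts.get(key, 0) + 1

    edges: list[Edge] = []
    ordinal = [0] * p
    for (src, tgt, allele, level), count in sorted(
        edge_counts.items(), key=lambda kv: (kv[0][3], kv[0][0], kv[0][2], kv[0][1])
    ):
        edges.append(
            Edge(
                id=f"L{level}E{ordinal[level]}",
                level=level,
                source=src,
                target=tgt,
                allele=allele,
                prob=count / through[src],
            )
        )
        ordinal[level] += 1
    return Apfa(p, vertex_levels, tuple(edges))


# -- native TSV format -----------------------------------------------------

_HEADER = ["level", "source", "target", "allele", "prob"]


def write_apfa(apfa: Apfa, path) -> None:
    """Write the native tab-separated edge list (header + one edge per row)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for e in apfa.edges:
            fh.write(f"{e.level}\t{e.source}\t{e.target}\t{e.allele}\t{e.prob!r}\n")


def read_apfa(path) -> Apfa:
    """Read the native APFA TSV written by :func:`write_apfa`.

    Edge ids are regenerated deterministically as ``L{level}E{ordinal}``;
    duplicate rows (same source, target, allele at a level) are collapsed by
    summing their probabilities. Raises :class:`ParseError` with the line
    number on malformed rows.
    """
    rows: dict[tuple[int, str, str, str], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if [c.strip() for c in header.rstrip("\n").split("\t")] != _HEADER:
            raise ParseError(
                f"expected header {'	'.join(_HEADER)!r}", path=str(path), line=1
            )
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ParseError(
                    f"expected 5 tab-separated columns, got {len(parts)}",
                    path=str(path), line=lineno,
                )
            lev_s, src, tgt, allele, prob_s = parts
            try:
                level = int(lev_s)
            except ValueError:
                raise ParseError(f"non-integer level {lev_s!r}", path=str(path), line=lineno)
            try:
                prob = float(prob_s)
            except ValueError:
                raise ParseError(
                    f"non-numeric probability {prob_s!r}", path=str(path), line=lineno
                )
            key = (level, src, tgt, allele)
            rows[key] = rows.get(key, 0.0) + prob
    if not rows:
        raise ParseError("file contains no edges", path=str(path))
    return _assemble(rows, str(path))


def _assemble(rows: dict[tuple[int, str, str, str], float], path: str) -> Apfa:
    levels = sorted({lev for lev, *_ in rows})
    p = max(levels) + 1
    if levels != list(range(p)):
        missing = sorted(set(range(p)) - set(levels))
        raise ParseError(f"level gap: no edges at level(s) {missing}", path=path)
    vertex_levels: dict[str, int] = {}
    for (lev, src, tgt, _), _prob in rows.items():
        for v, vl in ((src, lev), (tgt, lev + 1)):
            if vertex_levels.setdefault(v, vl) != vl:
                raise ParseError(
                    f"vertex {v!r} appears at levels {vertex_levels[v]} and {vl}", path=path
                )
    edges: list[Edge] = []
    ordinal = [0] * p
    for (lev, src, tgt, allele), prob in sorted(rows.items()):
        edges.append(Edge(f"L{lev}E{ordinal[lev]}", lev, src, tgt, allele, prob))
        ordinal[lev] += 1
    return Apfa(p, vertex_levels, tuple(edges))


def read_beagle_dag(path) -> Apfa:
    """Read a Beagle-3-style DAG file into an APFA.

    Whitespace-delimited rows ``level parent child allele count`` with ``#``
    comment lines; counts are normalized to probabilities per parent node.
    Duplicate edges (same level, parent, child, allele) have their counts
    summed. The result must pass :func:`validate_apfa`.
    """
    counts: dict[tuple[int, str, str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 5:
                raise ParseError(
                    f"expected 5 whitespace-delimited fields, got {len(parts)}",
                    path=str(path), line=lineno,
                )
            lev_s, parent, child, allele, count_s = parts
            try:
                level = int(lev_s)
                count = float(count_s)
            except ValueError:
                raise ParseError(
                    f"non-numeric level or count in {stripped!r}", path=str(path), line=lineno
                )
            if count < 0:
                raise ParseError(f"negative count {count}", path=str(path), line=lineno)
            key = (level, parent, child, allele)
            counts[key] = counts.get(key, 0.0) + count
    if not counts:
        raise ParseError("DAG file contains no data rows (empty model)", path=str(path))

    totals: dict[tuple[int, str], float] = {}
    for (lev, parent, _c, _a), count in counts.items():
        totals[(lev, parent)] = totals.get((lev, parent), 0.0) + count
    for (lev, parent), total in totals.items():
        if total <= 0:
            raise ParseError(
                f"zero total count at node {parent!r} (level {lev}); cannot normalize",
                path=str(path),
            )
    probs = {key: c / totals[(key[0], key[1])] for key, c in counts.items()}
    apfa = _assemble(probs, str(path))
    diags = validate_apfa(apfa)
    if diags:
        raise ModelError(
            "Beagle DAG does not form a valid APFA: " + "; ".join(diags[:5])
        )
    return apfa


def random_apfa(p: int, n_haplotypes: int, n_alleles: int, rng) -> Apfa:
    """Random branching APFA: a trie over random allele sequences.

    Convenience generator for simulations and tests; ``rng`` is a
    ``numpy.random.Generator``.
    """
    haps = [
        [str(a) for a in rng.integers(0, n_alleles, size=p)] for _ in range(n_haplotypes)
    ]
    return build_trie_apfa(haps)
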