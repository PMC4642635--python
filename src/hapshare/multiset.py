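"""Multiset algebra over genome segments.

A diploid genome is treated as a multiset of segments: at each of the ``p``
genomic intervals it carries two segments (one per haplotype), so its total
cardinality is ``2p`` and every multiplicity lies in ``{0, 1, 2}``. The
relatedness measures are built from three element-wise operators on
multiplicity maps:

* intersection ``A ∩ B`` — element-wise minimum,
* sum ``A + B`` — element-wise addition,
* product ``A × B`` — element-wise multiplication,

together with the cardinality ``|A|`` (sum of multiplicities). These satisfy
``|A + B| = |A| + |B|``, distributivity ``A × [B + C] = [A × B] + [A × C]``
and the translation identity ``A + [B ∩ C] = [A + B] ∩ [A + C]``.

Multiplicities are kept as exact integers so that identities among the
derived measures hold exactly before any division.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

__all__ = [
    "SegmentMultiset",
    "multiset_intersect",
    "multiset_sum",
    "multiset_product",
    "cardinality",
]


class SegmentMultiset(dict):
    """Multiplicity map from segment id to a non-negative integer count.

    A thin ``dict`` subclass; zero-multiplicity entries are dropped on
    construction so that equality is support-based. Operators ``&``, ``+``
    and ``*`` implement intersection, sum and product.
    """

    def __init__(self, items: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__()
        pairs = items.items() if isinstance(items, Mapping) else items
        for key, mult in pairs:
            if mult < 0:
                raise ValueError(f"negative multiplicity {mult} for segment {key!r}")
            if mult:
                self[key] = self.get(key, 0) + mult

    def cardinality(self) -> int:
        return sum(self.values())

    def intersect(self, other: Mapping[str, int]) -> "SegmentMultiset":
        out = SegmentMultiset()
        for key, mult in self.items():
            m = min(mult, other.get(key, 0))
            if m:
                dict.__setitem__(out, key, m)
        return out

    def sum(self, other: Mapping[str, int]) -> "SegmentMultiset":
        out = SegmentMultiset(self)
        for key, mult in other.items():
            if mult:
                dict.__setitem__(out, key, out.get(key, 0) + mult)
        return out

    def product(self, other: Mapping[str, int]) -> "SegmentMultiset":
        out = SegmentMultiset()
        for key, mult in self.items():
            m = mult * other.get(key, 0)
            if m:
                dict.__setitem__(out, key, m)
        return out

    __and__ = intersect
    __mul__ = product

    def __add__(self, other: Mapping[str, int]) -> "SegmentMultiset":
        return self.sum(other)


def multiset_intersect(a: Mapping[str, int], b: Mapping[str, int]) -> SegmentMultiset:
    """Element-wise minimum of multiplicities."""
    return SegmentMultiset(a).intersect(b)


def multiset_sum(a: Mapping[str, int], b: Mapping[str, int]) -> SegmentMultiset:
    """Element-wise addition; ``|a + b| == |a| + |b|``."""
    return SegmentMultiset(a).sum(b)


def multiset_product(a: Mapping[str, int], b: Mapping[str, int]) -> SegmentMultiset:
    """Element-wise product; the empty multiset is an annihilator."""
    return SegmentMultiset(a).product(b)


def cardinality(a: Mapping[str, int]) -> int:
    """Total number of elements counted with multiplicity."""
    return sum(a.values())
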