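"""Canonical bipartitions of a taxon bitset.

A bipartition is the unordered split of a tree's leafset induced by deleting
one edge. Equality and hashing go through a canonical orientation: ``side_a``
is the side containing the lowest-index taxon *of the bipartition's own
leafset* (not of the global set), so that restrictions of the same split to a
common subset canonicalize identically.
"""

from __future__ import annotations

from dataclasses import dataclass

from .taxa import TaxonIndex


@dataclass(frozen=True, slots=True)
class Bipartition:
    side_a: int
    side_b: int

    @staticmethod
    def of(m1: int, m2: int) -> "Bipartition":
        """Canonical bipartition from two disjoint nonempty bitmasks."""
        if m1 & m2:
            raise ValueError("bipartition sides must be disjoint")
        if not m1 or not m2:
            raise ValueError("bipartition sides must be nonempty")
        leafset = m1 | m2
        low = leafset & -leafset  # lowest set bit of the leafset
        return Bipartition(m1, m2) if m1 & low else Bipartition(m2, m1)

    @property
    def leafset(self) -> int:
        return self.side_a | self.side_b

    @property
    def nontrivial(self) -> bool:
        return self.side_a.bit_count() >= 2 and self.side_b.bit_count() >= 2

    def restrict(self, subset: int) -> "Bipartition | None":
        """Restriction to ``subset``; None when either side empties out."""
        a = self.side_a & subset
        b = self.side_b & subset
        if not a or not b:
            return None
        return Bipartition.of(a, b)

    def compatible_with(self, other: "Bipartition") -> bool:
        """Four-point compatibility test; both must be on the same leafset."""
        if self.leafset != other.leafset:
            raise ValueError("compatibility is defined on a common leafset")
        return (
            not self.side_a & other.side_a
            or not self.side_a & other.side_b
            or not self.side_b & other.side_a
            or not self.side_b & other.side_b
        )

    def to_string(self, index: TaxonIndex) -> str:
        a = ",".join(index.labels_of(self.side_a))
        b = ",".join(index.labels_of(self.side_b))
        return f"{a}|{b}"

    @staticmethod
    def from_string(text: str, index: TaxonIndex) -> "Bipartition":
        """Parse ``a,b|c,d``-style text against an index."""
        try:
            left, right = text.strip().split("|")
        except ValueError:
            raise ValueError(f"expected 'x,y|z,w' bipartition syntax, got {text!r}") from None
        m1 = index.mask_of(lab.strip() for lab in left.split(",") if lab.strip())
        m2 = index.mask_of(lab.strip() for lab in right.split(",") if lab.strip())
        return Bipartition.of(m1, m2)
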