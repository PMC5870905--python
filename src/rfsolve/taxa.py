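"""Taxon label <-> bit position bookkeeping.

All set algebra in this package runs on Python integers used as fixed-width
bit vectors; a :class:`TaxonIndex` pins down which bit is which taxon. The
ordering is lexicographic over labels, so the mapping is reproducible from
the label set alone.
"""

from __future__ import annotations

from collections.abc import Iterable


class TaxonIndex:
    """Stable bijection between taxon labels and bit positions 0..n-1."""

    __slots__ = ("labels", "position")

    def __init__(self, labels: Iterable[str]):
        ordered = tuple(sorted(set(labels)))
        if not ordered:
            raise ValueError("a TaxonIndex needs at least one taxon label")
        self.labels: tuple[str, ...] = ordered
        self.position: dict[str, int] = {lab: i for i, lab in enumerate(ordered)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.position

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonIndex) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonIndex({len(self)} taxa)"

    @property
    def full_mask(self) -> int:
        """Bitmask with every taxon set."""
        return (1 << len(self.labels)) - 1

    def bit(self, label: str) -> int:
        """Single-bit mask for one label."""
        try:
            return 1 << self.position[label]
        except KeyError:
            raise KeyError(f"unknown taxon label: {label!r}") from None

    def mask_of(self, labels: Iterable[str]) -> int:
        """Bitmask of a collection of labels."""
        mask = 0
        for lab in labels:
            mask |= self.bit(lab)
        return mask

    def labels_of(self, mask: int) -> tuple[str, ...]:
        """Labels of the taxa set in ``mask``, in index order."""
        out = []
        i = 0
        while mask:
            if mask & 1:
                out.append(self.labels[i])
            mask >>= 1
            i += 1
        return tuple(out)
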