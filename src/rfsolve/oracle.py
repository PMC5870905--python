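"""Brute-force exhaustive search over all unrooted binary topologies.

This is the transparency layer: every optimum the dynamic program reports on
a small instance can be replayed against a complete enumeration of the
(2n-5)!! unrooted binary trees. Enumeration is by stepwise leaf insertion —
taxon i is attached to every edge of every (i-1)-taxon topology — which
yields each topology exactly once, in a deterministic order.
"""

from __future__ import annotations

from collections.abc import Iterator, Sequence

from .bipartition import Bipartition
from .taxa import TaxonIndex
from .tree import Tree, adjacency_to_tree, build_taxon_index, edges_of, tree_bipartitions

__all__ = [
    "enumerate_binary_trees",
    "exact_rfs_search",
    "exact_constrained_search",
    "DEFAULT_MAX_TAXA",
]

DEFAULT_MAX_TAXA = 9


def _enumerate_adjacencies(n: int) -> Iterator[dict[int, list[int]]]:
    """Adjacencies over leaf ids 0..n-1 (internal ids >= n), one per topology."""
    center = n
    base = {center: [0, 1, 2], 0: [center], 1: [center], 2: [center]}

    def extend(adj: dict[int, list[int]], next_leaf: int, next_internal: int):
        if next_leaf == n:
            yield adj
            return
        for u, v in edges_of(adj):
            new = {k: list(vs) for k, vs in adj.items()}
            mid = next_internal
            new[u] = [mid if x == v else x for x in new[u]]
            new[v] = [mid if x == u else x for x in new[v]]
            new[mid] = [u, v, next_leaf]
            new[next_leaf] = [mid]
            yield from extend(new, next_leaf + 1, next_internal + 1)

    yield from extend(base, 3, n + 1)


def _bipartition_masks(adj: dict[int, list[int]], n: int, nontrivial: bool = True) -> frozenset[Bipartition]:
    """Canonical bipartitions of an enumerated adjacency; leaf id == bit index."""
    full = (1 << n) - 1
    below: dict[tuple[int, int], int] = {}

    def mask_below(u: int, parent: int) -> int:
        if u < n:
            return 1 << u
        key = (u, parent)
        if key in below:
            return below[key]
        m = 0
        for v in adj[u]:
            if v != parent:
                m |= mask_below(v, u)
        below[key] = m
        return m

    bips = set()
    for u, v in edges_of(adj):
        m = mask_below(u, v)
        if m == 0 or m == full:
            continue
        bip = Bipartition.of(m, full ^ m)
        if nontrivial and not bip.nontrivial:
            continue
        bips.add(bip)
    return frozenset(bips)


def enumerate_binary_trees(index: TaxonIndex, max_taxa: int = DEFAULT_MAX_TAXA) -> Iterator[Tree]:
    """All (2n-5)!! unrooted binary topologies on the index's taxa."""
    n = len(index)
    if not 3 <= n <= max_taxa:
        raise ValueError(f"enumeration supports 3..{max_taxa} taxa, got {n}")
    labels = {i: index.labels[i] for i in range(n)}
    for adj in _enumerate_adjacencies(n):
        yield adjacency_to_tree(adj, labels, rooted=False)


def _source_profiles(
    sources: Sequence[Tree], index: TaxonIndex
) -> list[tuple[int, frozenset[Bipartition], int]]:
    """(leafset mask, nontrivial bipartition set, max(l-3, 0)) per source."""
    out = []
    for t in sources:
        mask = index.mask_of(t.leaf_labels())
        bips = frozenset(tree_bipartitions(t, index, nontrivial_only=True))
        out.append((mask, bips, max(mask.bit_count() - 3, 0)))
    return out


def _score_masks(
    tree_bips: frozenset[Bipartition],
    profiles: list[tuple[int, frozenset[Bipartition], int]],
) -> int:
    score = 0
    for s_mask, src_bips, base in profiles:
        restricted = {r for b in tree_bips if (r := b.restrict(s_mask)) is not None and r.nontrivial}
        score += base + len(src_bips) - 2 * len(restricted & src_bips)
    return score


def exact_rfs_search(
    sources: Sequence[Tree],
    index: TaxonIndex | None = None,
    max_taxa: int = DEFAULT_MAX_TAXA,
) -> tuple[Tree, int, int]:
    """Global unconstrained optimum by exhaustive scoring.

    Returns (first optimal tree in enumeration order, best score, number of
    co-optimal topologies).
    """
    if index is None:
        index = build_taxon_index(sources)
    n = len(index)
    if not 3 <= n <= max_taxa:
        raise ValueError(f"exhaustive search supports 3..{max_taxa} taxa, got {n}")
    profiles = _source_profiles(sources, index)
    labels = {i: index.labels[i] for i in range(n)}
    best_adj = None
    best = None
    n_opt = 0
    for adj in _enumerate_adjacencies(n):
        score = _score_masks(_bipartition_masks(adj, n), profiles)
        if best is None or score < best:
            best = score
            best_adj = adj
            n_opt = 1
        elif score == best:
            n_opt += 1
    return adjacency_to_tree(best_adj, labels, rooted=False), best, n_opt


def exact_constrained_search(
    sources: Sequence[Tree],
    x: Iterable,
    index: TaxonIndex | None = None,
    max_taxa: int = DEFAULT_MAX_TAXA,
) -> tuple[Tree | None, int | None]:
    """Best enumerated tree whose nontrivial bipartitions all lie in ``x``;
    (None, None) if no enumerated tree qualifies."""
    if index is None:
        index = build_taxon_index(sources)
    n = len(index)
    if not 3 <= n <= max_taxa:
        raise ValueError(f"exhaustive search supports 3..{max_taxa} taxa, got {n}")
    allowed = frozenset(x)
    profiles = _source_profiles(sources, index)
    labels = {i: index.labels[i] for i in range(n)}
    best_adj = None
    best = None
    for adj in _enumerate_adjacencies(n):
        bips = _bipartition_masks(adj, n)
        if not bips <= allowed:
            continue
        score = _score_masks(bips, profiles)
        if best is None or score < best:
            best = score
            best_adj = adj
    if best_adj is None:
        return None, None
    return adjacency_to_tree(best_adj, labels, rooted=False), best
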