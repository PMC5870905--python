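"""Exact dynamic program for the constrained Robinson-Foulds supertree.

Minimizing the summed RF distance from a binary supertree T to the source
trees is equivalent to maximizing the *bipartition support*: the number of
(source tree, nontrivial bipartition) pairs [U',V'] that reappear in the
restriction T|L(t). Each supporting bipartition can be charged to exactly
one node of any rooted version of T — the node whose two child clades
(A1, A2) satisfy, for some orientation of the bipartition,

    A1 ∩ S' = U'   and   A2 ∩ S' != ∅        (S' = L(t)).

Because that charge depends only on the child-clade pair, the best support
achievable over clade A decomposes over the split of A:

    BPS(A) = max { BPS(A1) + BPS(A2) + support(A1, A2) }

over disjoint allowed clades A1, A2 with A1 ∪ A2 = A, with BPS({s}) = 0.
Processing allowed clades in order of cardinality and backtracking from the
full taxon set gives the exact optimum over all binary trees whose
bipartitions are drawn from the allowed set, in O(|X|^2 n k) time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

from .bipartition import Bipartition
from .constraints import ConstraintSet
from .errors import InfeasibleConstraintsError
from .taxa import TaxonIndex
from .tree import Node, Tree, _suppress_root_junction, tree_bipartitions

__all__ = [
    "assigned_to_pair",
    "SupportTable",
    "DPTable",
    "run_dp",
    "backtrack_tree",
    "bps_to_rfs",
    "solve_constrained_rfs",
]


def assigned_to_pair(bip: Bipartition, a1: int, a2: int) -> bool:
    """Is a source bipartition charged to a node with child clades (a1, a2)?

    ``bip`` lives on its source's leafset S'. True iff for some labeling
    (P, Q) of its sides, a1 ∩ S' = P and a2 ∩ S' != ∅ (or with a1 and a2
    swapped). Both orientations holding still counts once.
    """
    if a1 & a2:
        raise ValueError("clades must be disjoint")
    s = bip.leafset
    x1 = a1 & s
    x2 = a2 & s
    return ((x1 == bip.side_a or x1 == bip.side_b) and x2 != 0) or (
        (x2 == bip.side_a or x2 == bip.side_b) and x1 != 0
    )


class SupportTable:
    """Memoized support(A1, A2) counts over the source trees.

    Caches, per source, the leafset mask and the side masks of each
    nontrivial bipartition, so one support evaluation is a handful of bitwise
    operations per source bipartition.
    """

    def __init__(self, sources: Sequence[Tree], index: TaxonIndex):
        self.index = index
        self._per_source: list[tuple[int, list[tuple[int, int]]]] = []
        total = 0
        for t in sources:
            s_mask = index.mask_of(t.leaf_labels())
            sides = [
                (b.side_a, b.side_b)
                for b in sorted(
                    tree_bipartitions(t, index, nontrivial_only=True),
                    key=lambda b: (b.side_a, b.side_b),
                )
            ]
            total += len(sides)
            self._per_source.append((s_mask, sides))
        self.total_source_bipartitions = total
        self._memo: dict[tuple[int, int], int] = {}
        self.evaluations = 0  # distinct pairs computed; exposed for logging

    def support(self, a1: int, a2: int) -> int:
        """Number of source bipartitions mapped to a tripartition (a1, a2, *)."""
        if a1 & a2:
            raise ValueError("clades must be disjoint")
        key = (a1, a2) if a1 <= a2 else (a2, a1)
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        count = 0
        for s_mask, sides in self._per_source:
            x1 = a1 & s_mask
            x2 = a2 & s_mask
            if not x1 or not x2:
                continue  # both orientations need the other clade to touch S'
            for p, q in sides:
                if ((x1 == p or x1 == q) and x2) or ((x2 == p or x2 == q) and x1):
                    count += 1
        self._memo[key] = count
        self.evaluations += 1
        return count


@dataclass
class DPTable:
    """Best bipartition support per allowed clade, with backtracking splits."""

    bps: dict[int, int]
    back: dict[int, tuple[int, int]]
    total: int
    clades_evaluated: int = 0
    support_table: SupportTable | None = field(default=None, repr=False)


def run_dp(constraints: ConstraintSet, sources: Sequence[Tree]) -> DPTable:
    """Fill BPS(A) for every allowed clade in cardinality order.

    A clade with no admissible split into two allowed clades is left out of
    the table (a -inf sentinel): it cannot appear in any constrained binary
    tree, so it must not feed a parent's maximization. The full taxon set is
    guaranteed an entry whenever the constraint set honors its invariant.
    """
    index = constraints.index
    table = SupportTable(sources, index)
    clade_set = set(constraints.clades)
    bps: dict[int, int] = {}
    back: dict[int, tuple[int, int]] = {}
    evaluated = 0
    # ascending (cardinality, mask) order; singletons seed the recursion
    for a in constraints.clades:
        size = a.bit_count()
        if size == 1:
            bps[a] = 0
            continue
        best: int | None = None
        best_pair: tuple[int, int] | None = None
        evaluated += 1
        for a1 in constraints.clades:
            k1 = a1.bit_count()
            if k1 >= size:
                break  # clades are sorted by cardinality
            if a1 & a != a1:
                continue
            a2 = a ^ a1
            if a2 not in clade_set:
                continue
            # visit unordered pairs once, A1 canonical-smaller
            if (k1, a1) > (size - k1, a2):
                continue
            v1 = bps.get(a1)
            v2 = bps.get(a2)
            if v1 is None or v2 is None:
                continue  # a child clade is itself unreachable
            value = v1 + v2 + table.support(a1, a2)
            if best is None or value > best:
                best = value
                best_pair = (a1, a2)
        if best is not None:
            bps[a] = best
            back[a] = best_pair
    full = index.full_mask
    if full not in bps:
        raise InfeasibleConstraintsError(
            "the allowed bipartitions admit no binary tree on the full taxon set"
        )
    return DPTable(bps=bps, back=back, total=bps[full], clades_evaluated=evaluated, support_table=table)


def backtrack_tree(dp: DPTable, constraints: ConstraintSet, index: TaxonIndex) -> Tree:
    """Recover an optimal tree from the backpointers; returned unrooted."""

    def build(mask: int) -> Node:
        if mask.bit_count() == 1:
            return Node(index.labels_of(mask)[0])
        pair = dp.back.get(mask)
        if pair is None:
            raise InfeasibleConstraintsError(f"dangling backpointer for clade {mask:#x}")
        a1, a2 = pair
        return Node(children=[build(a1), build(a2)])

    tree = Tree(build(index.full_mask), rooted=False)
    _suppress_root_junction(tree)
    return tree


def bps_to_rfs(bps_total: int, sources: Sequence[Tree]) -> int:
    """Convert total bipartition support to the RFS criterion score.

    For a binary supertree T and source t on l_t leaves with m_t nontrivial
    bipartitions, RF(T, t) = max(l_t - 3, 0) + m_t - 2 * (shared), and the
    shared counts sum to the bipartition support, so

        RFS = sum_t [ max(l_t - 3, 0) + m_t ] - 2 * BPS.
    """
    total = 0
    for t in sources:
        l_t = t.n_leaves()
        m_t = len(tree_bipartitions(t, TaxonIndex(t.leaf_labels()), nontrivial_only=True))
        total += max(l_t - 3, 0) + m_t
    score = total - 2 * bps_total
    if score < 0:
        raise InfeasibleConstraintsError(
            f"negative RFS score ({score}) from BPS {bps_total}: support exceeds the attainable bound"
        )
    return score


def solve_constrained_rfs(
    sources: Sequence[Tree], constraints: ConstraintSet
) -> tuple[Tree, int, int]:
    """Exact constrained optimum: (supertree, total BPS, RFS criterion score).

    The returned binary tree draws every bipartition from the allowed set and
    no binary tree within the constraint space has a lower RFS score.
    """
    dp = run_dp(constraints, sources)
    tree = backtrack_tree(dp, constraints, constraints.index)
    return tree, dp.total, bps_to_rfs(dp.total, sources)
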