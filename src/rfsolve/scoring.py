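"""Criterion and accuracy measurements, plus direct (non-DP) bipartition
support used to cross-validate the dynamic program."""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

from .errors import LeafsetError

from .tree import (
    Tree,
    build_taxon_index,
    is_binary,
    restrict_tree,
    rf_distance,
    rf_to_source,
    rooted_clades,
    tree_bipartitions,
)

__all__ = [
    "ScoreReport",
    "rfs_criterion_score",
    "normalized_rf_error",
    "bipartition_support_of_tree",
]


@dataclass
class ScoreReport:
    """RFS criterion score of a supertree against a set of source trees.

    ``upper_bound`` is (2n - 6) * k when every source is binary; for
    polytomous sources it is instead the exact attainable bound
    sum_t (max(|L(t)| - 3, 0) + m_t), and ``bound_kind`` says which.
    """

    rfs_total: int
    per_source: list[int]
    bps_total: int
    upper_bound: int
    bound_kind: str  # "binary-sources" | "attainable"

    def as_dict(self) -> dict:
        return {
            "rfs_total": self.rfs_total,
            "per_source": self.per_source,
            "bps_total": self.bps_total,
            "upper_bound": self.upper_bound,
            "bound_kind": self.bound_kind,
        }


def rfs_criterion_score(supertree: Tree, sources: Sequence[Tree]) -> ScoreReport:
    """Total (and per-source) RF distance from a binary supertree to sources."""
    if not is_binary(supertree):
        raise ValueError("the RFS criterion is defined for binary supertrees")
    per = [rf_to_source(supertree, t) for t in sources]
    n = supertree.n_leaves()
    k = len(sources)
    index = build_taxon_index([supertree, *sources])
    all_binary = all(is_binary(t) for t in sources)
    if all_binary:
        bound = (2 * n - 6) * k
        kind = "binary-sources"
    else:
        bound = sum(
            max(t.n_leaves() - 3, 0)
            + len(tree_bipartitions(t, index, nontrivial_only=True))
            for t in sources
        )
        kind = "attainable"
    return ScoreReport(
        rfs_total=sum(per),
        per_source=per,
        bps_total=bipartition_support_of_tree(supertree, sources),
        upper_bound=bound,
        bound_kind=kind,
    )


def normalized_rf_error(true_tree: Tree, estimated: Tree) -> float:
    """RF distance divided by 2n - 6: the RF error rate in [0, 1]."""
    if true_tree.leaf_labels() != estimated.leaf_labels():
        raise LeafsetError("RF error rate requires identical leafsets")
    if not (is_binary(true_tree) and is_binary(estimated)):
        raise ValueError("RF error rate is defined for binary trees")
    n = true_tree.n_leaves()
    if n < 4:
        return 0.0
    return rf_distance(true_tree, estimated) / (2 * n - 6)


def bipartition_support_of_tree(
    tree: Tree, sources: Sequence[Tree], rooted: bool = False
) -> int:
    """Number of source bipartitions preserved by the supertree.

    Unrooted mode counts source bipartitions [A', B'] for which some
    supertree bipartition [A, B] restricts to them (A' = S' ∩ A and
    B' = S' ∩ B). Rooted mode requires a rooted input tree and counts source
    bipartitions one of whose sides is a clade of T|S'. The two agree for
    every rooting of the same topology.
    """
    index = build_taxon_index([tree, *sources])
    sup_mask = index.mask_of(tree.leaf_labels())
    if rooted and not tree.rooted:
        raise ValueError("rooted-mode support needs a rooted tree")
    count = 0
    if not rooted:
        sup_bips = tree_bipartitions(tree, index, nontrivial_only=True)
        for t in sources:
            s_mask = index.mask_of(t.leaf_labels())
            if s_mask & ~sup_mask:
                raise LeafsetError("source tree has leaves outside the supertree")
            restricted = {r for b in sup_bips if (r := b.restrict(s_mask)) is not None}
            for b in tree_bipartitions(t, index, nontrivial_only=True):
                if b in restricted:
                    count += 1
    else:
        for t in sources:
            s_labels = set(t.leaf_labels())
            if not s_labels <= set(tree.leaf_labels()):
                raise LeafsetError("source tree has leaves outside the supertree")
            clades = rooted_clades(restrict_tree(tree, s_labels), index)
            for b in tree_bipartitions(t, index, nontrivial_only=True):
                if b.side_a in clades or b.side_b in clades:
                    count += 1
    return count
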