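"""Construction of the allowed-bipartition set X and allowed clades C.

The solver can only return trees whose bipartitions are drawn from X, so X
must (a) be informed by the input and (b) contain at least one compatible
subset of n - 3 bipartitions, guaranteeing a fully resolved output. The
builder here works in three steps:

1. an average internode-distance matrix over the sources seeds a
   neighbor-joining reference tree on the full taxon set;
2. every nontrivial source bipartition is *completed* to the full taxon set
   by attaching each absent taxon to the side of its nearest retained leaf
   in a reference tree, and a greedy consensus of the completions (randomly
   refined to binary) becomes the *backbone*;
3. X = completions against the backbone, plus the backbone's own
   bipartitions, plus the bipartitions of any user-supplied candidate
   supertrees ("enhanced" mode — the optimum is then at least as good as
   every candidate).

The backbone is binary on the full set, so its n - 3 bipartitions are the
compatible subset required by the invariant.
"""

from __future__ import annotations

import random
from collections import Counter, deque
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .bipartition import Bipartition
from .errors import LeafsetError
from .taxa import TaxonIndex
from .tree import (
    Node,
    Tree,
    _suppress_root_junction,
    tree_bipartitions,
    tree_to_adjacency,
)

__all__ = [
    "DistanceMatrix",
    "ConstraintSet",
    "average_internode_matrix",
    "nj_supertree",
    "complete_bipartition",
    "greedy_consensus_backbone",
    "build_constraint_set",
    "clades_of",
]


@dataclass
class DistanceMatrix:
    """Average internode distances (edge counts) with a co-occurrence mask."""

    values: np.ndarray
    present: np.ndarray

    @property
    def complete(self) -> bool:
        n = self.values.shape[0]
        return bool(self.present[~np.eye(n, dtype=bool)].all())


@dataclass
class ConstraintSet:
    """Allowed bipartitions X over S, the derived allowed clades C, and the
    binary backbone witnessing that a fully resolved constrained tree exists."""

    bipartitions: frozenset[Bipartition]
    clades: tuple[int, ...]
    index: TaxonIndex
    provenance: dict[Bipartition, str] = field(default_factory=dict)
    backbone: Tree | None = None

    @staticmethod
    def from_bipartitions(
        bips: Iterable[Bipartition],
        index: TaxonIndex,
        provenance_tag: str = "user",
        backbone: Tree | None = None,
    ) -> "ConstraintSet":
        """Wrap an explicit X (e.g. read from a file or an enumeration)."""
        full = index.full_mask
        frozen = frozenset(bips)
        for b in frozen:
            if b.leafset != full:
                raise LeafsetError("constraint bipartitions must cover the full taxon set")
        return ConstraintSet(
            bipartitions=frozen,
            clades=clades_of(frozen, index),
            index=index,
            provenance={b: provenance_tag for b in frozen},
            backbone=backbone,
        )


def _leaf_path_lengths(tree: Tree) -> dict[str, dict[str, int]]:
    """Edge-count distances between every pair of leaves of one tree."""
    adj, labels = tree_to_adjacency(tree)
    out: dict[str, dict[str, int]] = {}
    for leaf_id, lab in labels.items():
        dist = {leaf_id: 0}
        queue = deque([leaf_id])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        out[lab] = {labels[v]: d for v, d in dist.items() if v in labels and v != leaf_id}
    return out


def average_internode_matrix(sources: Sequence[Tree], index: TaxonIndex) -> DistanceMatrix:
    """Mean over sources, per taxon pair, of the edge count on their path.

    Pairs never co-occurring in a source are masked out, not errors.
    """
    if not sources:
        raise ValueError("at least one source tree is required")
    n = len(index)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for t in sources:
        paths = _leaf_path_lengths(t)
        for lab_i, row in paths.items():
            i = index.position[lab_i]
            for lab_j, d in row.items():
                j = index.position[lab_j]
                if i < j:
                    sums[i, j] += d
                    counts[i, j] += 1
    present = counts > 0
    values = np.zeros((n, n))
    values[present] = sums[present] / counts[present]
    values = values + values.T
    present = present | present.T
    np.fill_diagonal(present, True)
    return DistanceMatrix(values=values, present=present)


def _impute(matrix: DistanceMatrix) -> np.ndarray:
    """Fill missing entries by shortest-path closure over the known ones;
    any still-disconnected pairs get (max finite entry + 2)."""
    if matrix.complete:
        return matrix.values
    n = matrix.values.shape[0]
    graph = np.where(matrix.present, matrix.values, 0.0)
    closed = shortest_path(graph, method="D", directed=False)
    known = matrix.present & ~np.eye(n, dtype=bool)
    out = np.where(known, matrix.values, closed)
    finite = out[np.isfinite(out)]
    fill = (finite.max() if finite.size else 0.0) + 2.0
    out[~np.isfinite(out)] = fill
    np.fill_diagonal(out, 0.0)
    return out


def nj_supertree(matrix: DistanceMatrix, index: TaxonIndex, seed: int = 0) -> Tree:
    """Neighbor joining on the (imputed, if needed) internode matrix.

    Deterministic: the Q-minimizing pair is scanned in cluster-creation
    order, so ties resolve to the lowest-index pair. ``seed`` is accepted
    for interface symmetry; the procedure involves no randomness.
    """
    n = len(index)
    if n < 4:
        raise ValueError("neighbor joining here requires at least 4 taxa")
    d = _impute(matrix).astype(float).copy()
    # clusters: list of (id, subtree Node); distances in a dict keyed by id pair
    nodes: dict[int, Node] = {i: Node(index.labels[i]) for i in range(n)}
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n

    def dget(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(dget(i, j) for j in active if j != i) for i in active}
        best = None
        best_pair = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dget(i, j) - row_sum[i] - row_sum[j]
                if best is None or q < best - 1e-12:
                    best = q
                    best_pair = (i, j)
        i, j = best_pair
        new = next_id
        next_id += 1
        nodes[new] = Node(children=[nodes[i], nodes[j]])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, new), max(k, new))] = 0.5 * (dget(i, k) + dget(j, k) - dget(i, j))
        active = [k for k in active if k not in (i, j)] + [new]
    root = Node(children=[nodes[k] for k in active])
    tree = Tree(root, rooted=False)
    _suppress_root_junction(tree)
    return tree


def complete_bipartition(bip: Bipartition, reference: Tree, index: TaxonIndex) -> Bipartition:
    """Extend a partial-leafset bipartition to the full taxon set.

    Each absent taxon joins the side holding its topologically nearest
    retained leaf in ``reference``; among equally-near leaves the one with
    the lowest taxon index wins.
    """
    full = index.full_mask
    ref_mask = index.mask_of(reference.leaf_labels())
    if ref_mask != full:
        raise LeafsetError("completion reference must be a tree on the full taxon set")
    missing = full & ~bip.leafset
    if not missing:
        return bip
    paths = _leaf_path_lengths(reference)
    retained = index.labels_of(bip.leafset)
    side_a, side_b = bip.side_a, bip.side_b
    for lab in index.labels_of(missing):
        row = paths[lab]
        # nearest retained leaf; ties to lowest taxon index (labels are in
        # index order already, and strict < keeps the first/lowest)
        best_lab = None
        best_d = None
        for r in retained:
            dr = row[r]
            if best_d is None or dr < best_d:
                best_d = dr
                best_lab = r
        if index.bit(best_lab) & bip.side_a:
            side_a |= index.bit(lab)
        else:
            side_b |= index.bit(lab)
    return Bipartition.of(side_a, side_b)


def _build_from_clades(clade_masks: set[int], index: TaxonIndex, rng: random.Random) -> Tree:
    """Rooted hierarchy from nested clades, randomly refined to an unrooted
    binary tree. ``clade_masks`` must be pairwise nested-or-disjoint and
    include all singletons and the full set."""
    full = index.full_mask
    by_size = sorted(clade_masks, key=lambda m: (m.bit_count(), m))
    nodes: dict[int, Node] = {}
    children_of: dict[int, list[int]] = {m: [] for m in clade_masks}
    for m in by_size:
        if m == full:
            continue
        # parent: smallest strict superset
        parent = min(
            (p for p in clade_masks if p != m and (m & p) == m),
            key=lambda p: (p.bit_count(), p),
        )
        children_of[parent].append(m)

    def build(m: int) -> Node:
        if m.bit_count() == 1:
            return Node(index.labels_of(m)[0])
        return Node(children=[build(c) for c in sorted(children_of[m])])

    root = build(full)

    def refine(node: Node, limit: int) -> None:
        for c in node.children:
            refine(c, 2)
        while len(node.children) > limit:
            i, j = sorted(rng.sample(range(len(node.children)), 2))
            merged = Node(children=[node.children[i], node.children[j]])
            node.children = [c for k, c in enumerate(node.children) if k not in (i, j)]
            node.children.append(merged)

    refine(root, 3 if len(index) >= 3 else 2)
    tree = Tree(root, rooted=False)
    _suppress_root_junction(tree)
    return tree


def greedy_consensus_backbone(
    completed_bips: Sequence[Bipartition], index: TaxonIndex, seed: int = 0
) -> Tree:
    """Greedy consensus of full-leafset bipartitions, refined to binary.

    Bipartitions are taken by descending frequency (ties by canonical
    bitset); each is accepted iff compatible with everything accepted so
    far. Remaining polytomies are resolved at random, deterministically per
    seed. An empty multiset yields a seeded random resolution of the star.
    """
    full = index.full_mask
    rng = random.Random(seed)
    counts = Counter(completed_bips)
    accepted: list[Bipartition] = []
    for bip, _freq in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].side_a, kv[0].side_b)):
        if bip.leafset != full:
            raise LeafsetError("backbone input bipartitions must cover the full taxon set")
        if not bip.nontrivial:
            continue
        if all(bip.compatible_with(a) for a in accepted):
            accepted.append(bip)
    low = full & -full  # anchor clades away from the lowest-index taxon
    clades = {full} | {1 << i for i in range(len(index))}
    for bip in accepted:
        clades.add(bip.side_b if bip.side_a & low else bip.side_a)
    return _build_from_clades(clades, index, rng)


def clades_of(x: Iterable[Bipartition], index: TaxonIndex) -> tuple[int, ...]:
    """Both halves of every bipartition, all singletons, and the full set,
    ordered by cardinality then canonical bitset (the DP evaluation order)."""
    masks: set[int] = {index.full_mask}
    masks.update(1 << i for i in range(len(index)))
    for bip in x:
        if bip.leafset != index.full_mask:
            raise LeafsetError("allowed bipartitions must cover the full taxon set")
        masks.add(bip.side_a)
        masks.add(bip.side_b)
    return tuple(sorted(masks, key=lambda m: (m.bit_count(), m)))


def build_constraint_set(
    sources: Sequence[Tree],
    candidates: Sequence[Tree] = (),
    index: TaxonIndex | None = None,
    seed: int = 0,
) -> ConstraintSet:
    """Assemble X (and C) from sources plus optional candidate supertrees."""
    if not sources:
        raise ValueError("at least one source tree is required")
    if index is None:
        from .tree import build_taxon_index

        index = build_taxon_index(sources)
    n = len(index)
    if n < 4:
        raise ValueError("the union of the source leafsets must have at least 4 taxa")
    full = index.full_mask
    for cand in candidates:
        if index.mask_of(cand.leaf_labels()) != full:
            raise LeafsetError("candidate supertrees must be trees on exactly the full taxon set")

    matrix = average_internode_matrix(sources, index)
    reference = nj_supertree(matrix, index, seed)

    source_bips: list[Bipartition] = []
    for t in sources:
        source_bips.extend(
            sorted(tree_bipartitions(t, index, nontrivial_only=True), key=lambda b: (b.side_a, b.side_b))
        )
    first_pass = [complete_bipartition(b, reference, index) for b in source_bips]
    backbone = greedy_consensus_backbone(first_pass, index, seed)

    x: dict[Bipartition, str] = {}
    for b in source_bips:
        comp = complete_bipartition(b, backbone, index)
        x.setdefault(comp, "source-completion")
    for cand in candidates:
        for b in sorted(tree_bipartitions(cand, index, nontrivial_only=True), key=lambda b: (b.side_a, b.side_b)):
            x.setdefault(b, "candidate-tree")
    for b in sorted(tree_bipartitions(backbone, index, nontrivial_only=True), key=lambda b: (b.side_a, b.side_b)):
        x.setdefault(b, "backbone")

    frozen = frozenset(x)
    return ConstraintSet(
        bipartitions=frozen,
        clades=clades_of(frozen, index),
        index=index,
        provenance=x,
        backbone=backbone,
    )
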