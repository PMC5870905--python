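"""Trees, newick I/O, bipartition extraction, restriction, and RF distances.

Unrooted trees are stored as a rooted node structure whose root has degree
>= 3 (after suppressing any degree-2 junction introduced by a rooted newick
string); rooted trees, used only inside the dynamic program and the
rooted-support cross-checks, keep a degree-2 root. Branch lengths and
internal node labels are parsed and discarded: every algorithm here is
purely topological.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Sequence
from pathlib import Path

import dendropy

from .bipartition import Bipartition
from .errors import DuplicateLabelError, LeafsetError, NewickParseError
from .taxa import TaxonIndex

__all__ = [
    "Node",
    "Tree",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "build_taxon_index",
    "tree_bipartitions",
    "restrict_tree",
    "rf_distance",
    "rf_to_source",
    "is_binary",
]


class Node:
    """A tree node; leaves carry a label, internal nodes a child list."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: list["Node"] | None = None):
        self.label = label
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(self.label)
        return Node(self.label, [c.copy() for c in self.children])


class Tree:
    """A labeled tree; ``rooted`` distinguishes a meaningful root."""

    __slots__ = ("root", "rooted")

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    def leaf_labels(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.label)
            else:
                stack.extend(node.children)
        return sorted(out)

    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    def __repr__(self) -> str:
        return f"Tree({write_newick(self)!r}, rooted={self.rooted})"


# ---------------------------------------------------------------------------
# newick I/O


def parse_newick(text: str, index: TaxonIndex | None = None) -> Tree:
    """Parse one newick string into an unrooted :class:`Tree`.

    Multifurcations are preserved. A rooted binary shape ``(A,B);`` is
    unrooted by suppressing the degree-2 junction. If ``index`` is given,
    every leaf label must be known to it.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise DuplicateLabelError(str(exc)) from None
    except dendropy.utility.error.DataParseError as exc:
        raise NewickParseError(
            str(exc),
            getattr(exc, "line_num", None),
            getattr(exc, "col_num", None),
        ) from None
    except Exception as exc:  # dendropy raises a few ad-hoc types for e.g. empty input
        raise NewickParseError(str(exc)) from None

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise NewickParseError("leaf with empty label")
            return Node(dnode.taxon.label)
        return Node(children=[convert(c) for c in dnode.child_nodes()])

    root = convert(dtree.seed_node)
    tree = Tree(root, rooted=False)
    labels = [n.label for n in _leaf_nodes(root)]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise DuplicateLabelError(f"duplicate leaf labels: {', '.join(dup)}")
    if index is not None:
        unknown = [l for l in labels if l not in index]
        if unknown:
            raise LeafsetError(f"labels not in taxon index: {', '.join(sorted(unknown))}")
    _suppress_root_junction(tree)
    return tree


def _leaf_nodes(root: Node) -> list[Node]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            out.append(node)
        else:
            stack.extend(node.children)
    return out


def _suppress_root_junction(tree: Tree) -> None:
    """Collapse a degree-2 root so unrooted trees always have root degree >= 3
    (or are a single leaf / a cherry on two leaves)."""
    while not tree.rooted and not tree.root.is_leaf and len(tree.root.children) == 2:
        c1, c2 = tree.root.children
        if not c1.is_leaf:
            tree.root = Node(children=c1.children + [c2])
        elif not c2.is_leaf:
            tree.root = Node(children=c2.children + [c1])
        else:
            break  # two-leaf tree: nothing to suppress
    # suppress any unary nodes left over elsewhere (defensive; parsers can emit them)
    _suppress_unary(tree.root)


def _suppress_unary(node: Node) -> None:
    i = 0
    while i < len(node.children):
        child = node.children[i]
        if not child.is_leaf and len(child.children) == 1:
            node.children[i] = child.children[0]
            continue
        _suppress_unary(child)
        i += 1


_NEEDS_QUOTE = set("()[]{}:;,'\" \t\n")


def _format_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Deterministic newick: children sorted by their smallest leaf label
    (equivalently, by smallest taxon index under the lexicographic index);
    unrooted trees are first re-hung on the node adjacent to the
    lowest-label leaf, so every rooting of the same unrooted topology writes
    identically. Branch lengths are not emitted."""
    root = tree.root
    if not tree.rooted and not root.is_leaf and root.children:
        adj, labels = tree_to_adjacency(tree)
        low_leaf = min(labels, key=lambda i: labels[i])
        if len(adj) > 2:
            anchor = adj[low_leaf][0]

            def hang(nid: int, parent: int | None) -> Node:
                if nid in labels:
                    return Node(labels[nid])
                return Node(children=[hang(m, nid) for m in adj[nid] if m != parent])

            root = hang(anchor, None)

    def fmt(node: Node) -> tuple[str, str]:
        """(min leaf label, newick text) in one postorder pass."""
        if node.is_leaf:
            return node.label, _format_label(node.label)
        parts = sorted(fmt(c) for c in node.children)
        return parts[0][0], "(" + ",".join(text for _, text in parts) + ")"

    return fmt(root)[1] + ";"


def read_newick_file(path: str | Path, index: TaxonIndex | None = None) -> list[Tree]:
    """Read a newick file, one tree per non-blank line."""
    trees = []
    with io.open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line, index))
    if not trees:
        raise NewickParseError(f"no trees found in {path}")
    return trees


def write_newick_file(trees: Iterable[Tree], path: str | Path) -> None:
    with io.open(path, "w", encoding="utf-8") as fh:
        for tree in trees:
            fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# index construction and bipartitions


def build_taxon_index(trees: Sequence[Tree]) -> TaxonIndex:
    """TaxonIndex over the union of the trees' leafsets, S = U L(t)."""
    if not trees:
        raise ValueError("cannot build a taxon index from an empty tree collection")
    labels: set[str] = set()
    for t in trees:
        labels.update(t.leaf_labels())
    return TaxonIndex(labels)


def _node_masks(tree: Tree, index: TaxonIndex) -> list[tuple[Node, int]]:
    """Postorder (node, leaf-bitmask-below) pairs; root last."""
    out: list[tuple[Node, int]] = []

    def rec(node: Node) -> int:
        if node.is_leaf:
            mask = index.bit(node.label)
        else:
            mask = 0
            for c in node.children:
                mask |= rec(c)
        out.append((node, mask))
        return mask

    rec(tree.root)
    return out


def tree_bipartitions(
    tree: Tree, index: TaxonIndex, nontrivial_only: bool = True
) -> set[Bipartition]:
    """One bipartition per internal edge of the (unrooted view of the) tree."""
    for lab in tree.leaf_labels():
        if lab not in index:
            raise LeafsetError(f"leaf {lab!r} not in taxon index")
    masks = _node_masks(tree, index)
    full = masks[-1][1]
    bips: set[Bipartition] = set()
    for node, mask in masks[:-1]:
        if mask == 0 or mask == full:
            continue
        bip = Bipartition.of(mask, full ^ mask)
        if nontrivial_only and not bip.nontrivial:
            continue
        bips.add(bip)
    return bips


def rooted_clades(tree: Tree, index: TaxonIndex) -> set[int]:
    """All clades (leaf bitmasks below each node, root included) of a rooted tree."""
    return {mask for _, mask in _node_masks(tree, index)}


# ---------------------------------------------------------------------------
# restriction


def restrict_tree(tree: Tree, subset: Iterable[str] | int, index: TaxonIndex | None = None) -> Tree:
    """T|Q: restrict to a leaf subset and suppress degree-2 nodes.

    ``subset`` is a collection of labels, or a bitmask if ``index`` is given.
    Restriction of an unrooted tree is returned unrooted; of a rooted tree,
    rooted (the root is kept, re-hung on its surviving child if necessary).
    """
    if isinstance(subset, int):
        if index is None:
            raise ValueError("a TaxonIndex is required to interpret a bitmask subset")
        keep = set(index.labels_of(subset))
    else:
        keep = set(subset)
    leafset = set(tree.leaf_labels())
    if not keep:
        raise LeafsetError("restriction subset must be nonempty")
    if not keep <= leafset:
        extra = ", ".join(sorted(keep - leafset))
        raise LeafsetError(f"subset contains labels outside the tree: {extra}")

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            return Node(node.label) if node.label in keep else None
        kept = [r for c in node.children if (r := rec(c)) is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]  # suppress degree-2
        return Node(children=kept)

    root = rec(tree.root)
    assert root is not None
    out = Tree(root, tree.rooted)
    if not tree.rooted:
        _suppress_root_junction(out)
    return out


# ---------------------------------------------------------------------------
# RF distances


def rf_distance(t1: Tree, t2: Tree) -> int:
    """|Bip(t1) symdiff Bip(t2)| over nontrivial bipartitions; requires
    identical leafsets."""
    l1, l2 = t1.leaf_labels(), t2.leaf_labels()
    if l1 != l2:
        raise LeafsetError("RF distance requires identical leafsets")
    index = TaxonIndex(l1)
    b1 = tree_bipartitions(t1, index, nontrivial_only=True)
    b2 = tree_bipartitions(t2, index, nontrivial_only=True)
    return len(b1 ^ b2)


def rf_to_source(supertree: Tree, source: Tree) -> int:
    """RF(T, t) for nested leafsets: restrict the supertree to L(t) first."""
    sup_labels = set(supertree.leaf_labels())
    src_labels = set(source.leaf_labels())
    if not src_labels <= sup_labels:
        extra = ", ".join(sorted(src_labels - sup_labels))
        raise LeafsetError(f"source has leaves outside the supertree: {extra}")
    return rf_distance(restrict_tree(supertree, src_labels), source)


def is_binary(tree: Tree) -> bool:
    """Fully resolved: rooted trees have 2 children everywhere; unrooted trees
    have a degree-3 root and 2 children elsewhere. Trees on < 4 leaves are
    vacuously resolved."""
    if tree.n_leaves() <= 3 and not tree.rooted:
        return True

    def ok(node: Node, at_root: bool) -> bool:
        if node.is_leaf:
            return True
        want = 3 if (at_root and not tree.rooted) else 2
        if len(node.children) != want:
            return False
        return all(ok(c, False) for c in node.children)

    return ok(tree.root, True)


# ---------------------------------------------------------------------------
# adjacency view (used by rooting, NNI, enumeration)


def tree_to_adjacency(tree: Tree) -> tuple[dict[int, list[int]], dict[int, str]]:
    """Undirected adjacency over integer node ids, plus leaf id -> label."""
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    counter = [0]

    def rec(node: Node) -> int:
        nid = counter[0]
        counter[0] += 1
        adj[nid] = []
        if node.is_leaf:
            labels[nid] = node.label
        for c in node.children:
            cid = rec(c)
            adj[nid].append(cid)
            adj[cid].append(nid)
        return nid

    rec(tree.root)
    return adj, labels


def adjacency_to_tree(
    adj: dict[int, list[int]], labels: dict[int, str], rooted: bool = False
) -> Tree:
    """Rebuild a Tree from an adjacency; the root is the lowest-id internal
    node (or the single node of a one-leaf tree)."""
    internal = sorted(n for n in adj if n not in labels)
    if not internal:
        nodes = sorted(adj)
        if len(nodes) == 1:
            return Tree(Node(labels[nodes[0]]), rooted)
        # two leaves joined by an edge
        root = Node(children=[Node(labels[n]) for n in nodes])
        return Tree(root, rooted)
    root_id = internal[0]

    def hang(nid: int, parent: int | None) -> Node:
        if nid in labels:
            return Node(labels[nid])
        return Node(children=[hang(m, nid) for m in adj[nid] if m != parent])

    tree = Tree(hang(root_id, None), rooted)
    if not rooted:
        _suppress_root_junction(tree)
    return tree


def edges_of(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    """Deterministically ordered undirected edge list."""
    return sorted({(min(u, v), max(u, v)) for u in adj for v in adj[u]})


def all_rootings(tree: Tree) -> list[Tree]:
    """One rooted tree per edge of an unrooted tree (2n-3 of them when binary)."""
    adj, labels = tree_to_adjacency(tree)

    def hang(nid: int, parent: int) -> Node:
        if nid in labels:
            return Node(labels[nid])
        return Node(children=[hang(m, nid) for m in adj[nid] if m != parent])

    out = []
    for u, v in edges_of(adj):
        root = Node(children=[hang(u, v), hang(v, u)])
        rooted = Tree(root, rooted=True)
        _suppress_unary(rooted.root)
        out.append(rooted)
    return out
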