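"""Seeded generation of model supertrees and scaffold-plus-clades source sets.

The generator emulates the structure of supertree benchmark inputs built
from mixed taxon sampling: one "scaffold" tree covering a random fraction of
the full species set (the scaffold density), plus several "clade-based"
trees each restricted to a clade of the model tree. Topological noise
stands in for gene-tree estimation error: a configurable number of random
NNI moves per source tree, and independent random contraction of internal
edges to create polytomies. All randomness flows from a single integer seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from .errors import RfsolveError
from .tree import Tree, adjacency_to_tree, all_rootings, edges_of, restrict_tree, rooted_clades, tree_to_adjacency
from .taxa import TaxonIndex

__all__ = [
    "SimulationConfig",
    "simulate_model_tree",
    "simulate_sources",
    "random_binary_tree",
    "random_nni",
    "contract_random_edges",
]


@dataclass
class SimulationConfig:
    """Knobs for one synthetic replicate.

    scaffold_density is the fraction of all taxa sampled into the scaffold
    tree; clade_size_range bounds the clade-based trees (default: any
    informative clade, i.e. (3, n - 2), so that taxa whose smallest
    enclosing clade is large can still be sampled); nni_perturbations and
    polytomy_contract_prob set the per-source topological noise.
    """

    n_taxa: int
    scaffold_density: float = 0.75
    n_clade_trees: int = 5
    clade_size_range: tuple[int, int] | None = None
    nni_perturbations: int = 1
    polytomy_contract_prob: float = 0.0
    seed: int = 0
    max_coverage_retries: int = 100

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be at least 4")
        if not 0 < self.scaffold_density <= 1:
            raise ValueError("scaffold_density must be in (0, 1]")
        if self.n_clade_trees < 0 or self.nni_perturbations < 0:
            raise ValueError("counts must be nonnegative")
        if not 0 <= self.polytomy_contract_prob <= 1:
            raise ValueError("polytomy_contract_prob must be in [0, 1]")
        if self.clade_size_range is None:
            lo = 3 if self.n_taxa >= 5 else 2
            self.clade_size_range = (lo, max(lo, self.n_taxa - 2))
        lo, hi = self.clade_size_range
        if not (2 <= lo <= hi <= self.n_taxa):
            raise ValueError(f"infeasible clade_size_range {self.clade_size_range}")


def random_binary_tree(labels: list[str], rng: random.Random) -> Tree:
    """Uniform stepwise insertion: each new leaf attaches to a random edge."""
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    n = len(labels)
    center = n
    adj: dict[int, list[int]] = {center: [0, 1, 2], 0: [center], 1: [center], 2: [center]}
    next_internal = n + 1
    for leaf in range(3, n):
        u, v = rng.choice(edges_of(adj))
        mid = next_internal
        next_internal += 1
        adj[u] = [mid if x == v else x for x in adj[u]]
        adj[v] = [mid if x == u else x for x in adj[v]]
        adj[mid] = [u, v, leaf]
        adj[leaf] = [mid]
    return adjacency_to_tree(adj, {i: labels[i] for i in range(n)}, rooted=False)


def simulate_model_tree(n_taxa: int, seed: int = 0) -> Tree:
    """Random binary model tree on labels t0001..tNNNN, deterministic per seed."""
    if n_taxa < 4:
        raise ValueError("n_taxa must be at least 4")
    labels = [f"t{i:04d}" for i in range(1, n_taxa + 1)]
    return random_binary_tree(labels, random.Random(seed))


def random_nni(tree: Tree, rng: random.Random) -> Tree:
    """One random NNI move: swap a random subtree pair across a random
    internal edge. Trees without an internal edge are returned unchanged."""
    adj, labels = tree_to_adjacency(tree)
    internal_edges = [(u, v) for u, v in edges_of(adj) if u not in labels and v not in labels]
    if not internal_edges:
        return tree
    u, v = rng.choice(internal_edges)
    a = rng.choice(sorted(x for x in adj[u] if x != v))
    b = rng.choice(sorted(x for x in adj[v] if x != u))
    adj[u] = [b if x == a else x for x in adj[u]]
    adj[v] = [a if x == b else x for x in adj[v]]
    adj[a] = [v if x == u else x for x in adj[a]]
    adj[b] = [u if x == v else x for x in adj[b]]
    return adjacency_to_tree(adj, labels, rooted=tree.rooted)


def contract_random_edges(tree: Tree, prob: float, rng: random.Random) -> Tree:
    """Contract each internal edge independently with probability ``prob``."""
    if prob <= 0:
        return tree
    adj, labels = tree_to_adjacency(tree)
    for u, v in edges_of(adj):
        if u in labels or v in labels or v not in adj.get(u, []):
            continue
        if rng.random() < prob:
            # merge v into u
            adj[u] = [x for x in adj[u] if x != v]
            for x in adj[v]:
                if x != u:
                    adj[u].append(x)
                    adj[x] = [u if y == v else y for y in adj[x]]
            del adj[v]
    return adjacency_to_tree(adj, labels, rooted=tree.rooted)


def _random_clade(model: Tree, size_range: tuple[int, int], rng: random.Random) -> set[str]:
    """A clade of a random rooting of the model with size in ``size_range``."""
    index = TaxonIndex(model.leaf_labels())
    rootings = all_rootings(model)
    lo, hi = size_range
    # a particular rooting may have no clade in the window; sample rootings
    # without replacement until one does
    order = list(range(len(rootings)))
    rng.shuffle(order)
    for i in order:
        clades = [
            m for m in sorted(rooted_clades(rootings[i], index)) if lo <= m.bit_count() <= hi
        ]
        if clades:
            return set(index.labels_of(rng.choice(clades)))
    raise RfsolveError(f"no rooting of the model tree has a clade of size in {size_range}")


def simulate_sources(model: Tree, config: SimulationConfig) -> list[Tree]:
    """Scaffold + clade-based source trees from a binary model tree.

    The scaffold restricts the model to a uniform random subset of
    round(scaffold_density * n) taxa; each clade tree restricts it to a
    random clade of a random rooting. Sources are then perturbed by NNI
    moves and random edge contraction. Leafset coverage of the full taxon
    set is enforced by retrying the sampling, then erroring out.
    """
    labels = model.leaf_labels()
    n = len(labels)
    if n != config.n_taxa:
        raise ValueError("model tree size does not match config.n_taxa")
    rng = random.Random(config.seed)
    scaffold_size = max(1, round(config.scaffold_density * n))
    for _attempt in range(config.max_coverage_retries):
        scaffold_taxa = set(rng.sample(labels, scaffold_size))
        clade_sets = [
            _random_clade(model, config.clade_size_range, rng)
            for _ in range(config.n_clade_trees)
        ]
        covered = set(scaffold_taxa)
        for cs in clade_sets:
            covered |= cs
        if covered == set(labels):
            break
    else:
        raise RfsolveError(
            f"could not cover all taxa in {config.max_coverage_retries} sampling attempts; "
            "raise scaffold_density or n_clade_trees"
        )
    sources = [restrict_tree(model, scaffold_taxa)]
    sources.extend(restrict_tree(model, cs) for cs in clade_sets)
    perturbed = []
    for t in sources:
        for _ in range(config.nni_perturbations):
            t = random_nni(t, rng)
        t = contract_random_edges(t, config.polytomy_contract_prob, rng)
        perturbed.append(t)
    return perturbed
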