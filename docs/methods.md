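# Methods

## Model and criterion

All algorithms are purely topological. A source tree *t* is unrooted, has
distinct leaf labels drawn from the global taxon set *S*, and may contain
polytomies; branch lengths and internal labels are parsed and discarded.
Multi-labeled trees (more than one leaf per taxon, as arise from gene
duplication) are rejected at parse time — the criterion below is not
defined for them.

The criterion minimized is the summed Robinson–Foulds distance from a
binary supertree *T* on *S* to the sources, where RF against a source on a
smaller leafset is computed after restricting *T* to that leafset and
suppressing degree-2 nodes. RF counts **nontrivial bipartitions only**
(both sides ≥ 2 taxa). Trivial bipartitions are present in every tree on a
given leafset, so including them would add a per-source constant and change
no optimum; the nontrivial convention also makes the conversion identity
below exact. For a binary supertree and source *t* with ℓ_t leaves and m_t
nontrivial bipartitions,

    RF(T, t) = max(ℓ_t − 3, 0) + m_t − 2 · (shared bipartitions),

and summing over sources gives

    RFS(T) = Σ_t [max(ℓ_t − 3, 0) + m_t] − 2 · BPS(T),

where BPS(T) is the total bipartition support. The solver maximizes BPS and
converts; `rfsolve.scoring` recomputes the score directly from the tree,
and the test suite asserts the identity for arbitrary (non-optimal)
supertrees. Polytomous sources contribute one bipartition per internal
edge, so m_t < ℓ_t − 3 and the identity uses the actual count.

## Support assignment and the dynamic program

For a rooted binary tree, deleting an internal node *v* with child clades
A₁, A₂ defines the tripartition (A₁, A₂, rest). A source bipartition
[U′, V′] of *t* (leafset S′) is charged to *v* iff, for some orientation,
A₁ ∩ S′ = U′, V′ ∩ A₁ = ∅ and V′ ∩ A₂ ≠ ∅; the two orientations are
counted once. This charge is unique per tree when it exists, exists iff the
bipartition is preserved in T|S′, and depends only on (A₁, A₂) — which is
what makes the recursion

    BPS(A) = max { BPS(A₁) + BPS(A₂) + support(A₁, A₂) }

valid over the allowed clades 𝒞. Implementation notes:

- Taxon sets are Python integers used as bit vectors; taxa are bit-indexed
  in lexicographic label order. Bipartitions canonicalize on the side
  containing the lowest-index taxon *of their own leafset*, so restrictions
  of the same split canonicalize consistently.
- support(A₁, A₂) is evaluated lazily with memoization when the DP first
  visits the pair, rather than precomputed for all disjoint pairs; results
  are identical and the worst case is unchanged (O(|X|² n k)). Per source
  we cache the leafset mask and side masks, so one evaluation is a few
  bitwise comparisons per source bipartition.
- Clades are processed in (cardinality, bitset) order. A clade with no
  admissible split into two allowed clades gets no table entry (a −∞
  sentinel) and is excluded from parent maximizations: a clade unreachable
  by any constrained binary tree must not contribute a score of 0. If the
  full set S has no entry the constraint set is infeasible and the solver
  raises; the built constraint sets below can never trigger this.
- Ties in the maximization keep the first maximizer in canonical clade
  order, and the backtracked tree is therefore deterministic. Among
  co-optimal trees no preference is claimed beyond determinism.

## Constraint-set construction

The solver can only return trees inside its constraint space, so the
builder must produce an *X* that is informed by the input and contains at
least one compatible subset of n − 3 bipartitions. The pipeline:

1. **Internode matrix.** Entry (i, j) is the mean, over sources containing
   both taxa, of the edge count on the i–j path. Pairs that never co-occur
   are masked. Missing entries are imputed by shortest-path closure over
   the known entries (Dijkstra on the graph whose edge weights are the
   known distances); still-disconnected pairs are set to the maximum finite
   entry plus 2. Any complete matrix suffices here, because the matrix only
   seeds the constraint set, never the final tree.
2. **Reference tree.** Neighbor joining on the imputed matrix, with ties in
   the Q-criterion resolved to the lowest-index pair (no randomness).
3. **Completion.** Every nontrivial source bipartition is extended to *S*:
   each absent taxon joins the side of its topologically nearest retained
   leaf in the reference tree, ties to the lowest-index tied leaf.
4. **Backbone.** A greedy consensus of the completed bipartitions —
   descending frequency, ties by canonical bitset, accept iff compatible
   with everything accepted — refined to binary by seeded random resolution
   of remaining polytomies. The backbone is binary on *S*, so its n − 3
   bipartitions are the required compatible subset.
5. **X** = completions of the source bipartitions against the backbone, ∪
   backbone bipartitions, ∪ nontrivial bipartitions of every candidate
   supertree (enhanced mode). Because candidate bipartitions enter *X*
   whole, the constrained optimum is at least as good as every candidate.

An explicit *X* can also be supplied verbatim (text file of
`a,b|c,d`-style lines or a newick file whose bipartitions are harvested),
e.g. to reproduce a run made with an externally computed constraint set.
The builder requires |S| ≥ 4 and candidate trees on exactly *S*.

One deliberate simplification: the reference for the first-pass completion
is always the NJ tree on the imputed matrix, whether or not the matrix had
missing entries. Keeping a single code path costs nothing in the properties
that matter (X derived from input; resolvability witnessed by the
backbone) and keeps the builder deterministic per seed.

## Synthetic data

The generator emulates supertree benchmark inputs built from mixed taxon
sampling: a binary model tree (uniform stepwise leaf insertion), one
scaffold source = the model restricted to a uniform random subset of
round(density · n) taxa, plus `n_clade_trees` sources each restricted to a
clade (of a random rooting of the model) with size in `clade_size_range`.
Defaults: scaffold density 0.75, 5 clade trees, clade sizes (3, n − 2), 1
NNI move per source, no polytomy contraction, seed 0. The clade-size upper
bound n − 2 (any informative clade) matters: taxa whose smallest enclosing
clade is large would otherwise be unsampleable, and leafset coverage of *S*
— enforced by bounded retries — would fail spuriously.

Noise is topological: per source, a number of random NNI moves (swap a
random subtree pair across a random internal edge) and independent
contraction of internal edges with a given probability. This emulates
gene-tree estimation error only in its effect on the solver's input — there
is no sequence evolution, no gene birth/death process, and no inference
step, so passing tests say nothing about alignment-level error models.
Error rates under this generator are not comparable in magnitude to results
on estimated gene trees; only ordinal statements (e.g. denser scaffolds →
lower mean error) are asserted, on fixed seed sets.

## Oracle

`enumerate_binary_trees` produces all (2n−5)!! unrooted binary topologies
by stepwise leaf insertion (taxon i attached to every edge of every
(i−1)-taxon topology), capped at 9 taxa by default. `exact_rfs_search` and
`exact_constrained_search` score every topology directly from bipartition
sets. The oracle shares no code with the DP beyond the bitset primitives,
and the test suite replays the DP against it on hundreds of seeded
instances (n ∈ {5, 6, 7}, k ∈ {3, 5}, NNI noise ∈ {0, 1, 2}) — sizes chosen
so a complete enumeration stays trivially cheap while still exercising
missing taxa, polytomies, and conflicting sources.

## Numerical and degenerate-input choices

- NJ requires n ≥ 4; enumeration requires 3 ≤ n ≤ cap; the constraint
  builder requires n ≥ 4. Restriction accepts any nonempty leaf subset.
- A rooted binary newick shape `(A,B);` is silently unrooted (the degree-2
  junction is suppressed); all unrooted trees keep root degree ≥ 3.
- Newick output is canonical: unrooted trees are re-hung on the node
  adjacent to the lowest-label leaf and children sort by smallest contained
  leaf label, so equal topologies serialize identically and seeded runs are
  byte-reproducible.
- Two-leaf trees store their connecting junction, so the internode distance
  between the pair is 2 (consistent with the ≥ 2 bound for co-occurring
  distinct leaves; such sources carry no bipartitions and cannot affect any
  optimum).
- All randomness (backbone refinement, synthetic generation) flows through
  integer seeds; `seed` parameters accepted for interface symmetry by
  deterministic steps (NJ) are documented as unused.

## Limitations

- The constraint-set builder is this package's own design; it guarantees
  feasibility and candidate dominance but does not claim equivalence to any
  other tool's search-space heuristic, so criterion scores on published
  datasets depend on the *X* supplied.
- The exact solver's cost grows with |X|²; it is intended for constraint
  sets of the size the builder produces, not for |X| approaching 2^n.
- No multi-labeled trees, no branch-length-aware distances, no quartet- or
  likelihood-based criteria, and no heuristic tree search over the
  unconstrained space.
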