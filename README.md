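# rfsolve

Exact constrained Robinson–Foulds supertrees.

## The problem

Supertree estimation combines unrooted *source trees* — each on a subset of
a taxon set *S*, possibly multifurcating — into one binary tree on all of
*S*. The Robinson–Foulds (RF) supertree criterion asks for the binary tree
*T* minimizing

&nbsp;&nbsp;&nbsp;&nbsp;RF(T, 𝒯) = Σ_{t ∈ 𝒯} RF(T|L(t), t),

where T|L(t) restricts *T* to the leafset of source *t* and RF is the size
of the symmetric difference of the two trees' nontrivial bipartition sets.
The unconstrained problem is NP-hard. `rfsolve` instead solves the
**constrained** problem exactly: given a set *X* of allowed full-leafset
bipartitions, it finds the optimum over all binary trees drawing every
bipartition from *X*, in O(|X|² n k) time.

The key identity is that minimizing the summed RF distance is equivalent to
maximizing the *bipartition support* — the number of source bipartitions
preserved in the supertree's restrictions. Each preserved source bipartition
can be charged to exactly one node of any rooted version of the supertree,
determined only by that node's pair of child clades (A₁, A₂). Writing
support(A₁, A₂) for the number of source bipartitions charged to that pair,
the best support over a clade A ∈ 𝒞 (the halves of *X*, plus singletons and
*S*) satisfies

&nbsp;&nbsp;&nbsp;&nbsp;BPS(A) = max { BPS(A₁) + BPS(A₂) + support(A₁, A₂) :
A = A₁ ∪̇ A₂, Aᵢ ∈ 𝒞 },&nbsp;&nbsp;BPS({s}) = 0,

so a dynamic program over clades in cardinality order, followed by
backtracking from BPS(S) and unrooting, returns an exact constrained
optimum.

The package provides:

- `tree_core` primitives: newick I/O, bitset bipartitions, restriction, RF
  distances on identical and nested leafsets (`rfsolve.tree`);
- the constraint-set builder (`rfsolve.constraints`): average internode
  distances, neighbor joining, nearest-leaf completion of partial
  bipartitions, and a greedy-consensus backbone guaranteeing a fully
  resolved constrained tree always exists; in *enhanced* mode, bipartitions
  of user-supplied candidate supertrees enlarge *X*, so the optimum is at
  least as good as every candidate;
- the exact DP solver (`rfsolve.dp`) and criterion/accuracy scoring
  (`rfsolve.scoring`);
- a brute-force oracle over all (2n−5)!! topologies (`rfsolve.oracle`) and a
  seeded scaffold-plus-clades synthetic generator (`rfsolve.simulate`).

## Worked example

Three quartets on five taxa, two of them sharing the split `ab|..` and one
resolving `d,e` together:

```sh
$ cat sources.nwk
((a,b),(c,d));
((a,b),(c,e));
((b,c),(d,e));
$ rfsolve supertree --sources sources.nwk --out super.nwk --report report.json
$ cat super.nwk
(a,b,(c,(d,e)));
$ cat report.json
{
  "C_size": 10,
  "X_size": 2,
  "bps": 3,
  "k": 3,
  "mode": "basic",
  "n": 5,
  "per_source": [
    0,
    0,
    0
  ],
  "rfs_score": 0,
  "seed": 0,
  "tree": "(a,b,(c,(d,e)));"
}
```

The solver builds a constraint set with |X| = 2 allowed bipartitions
(`ab|cde` and `abc|de`, completions of the source splits), and the DP finds
the tree preserving all 3 source bipartitions (`bps`), hence total RF
distance 0 to the sources (`rfs_score`, with per-source distances
`[0, 0, 0]`). The brute-force oracle confirms this is the unique global
optimum over all 15 five-taxon topologies:

```sh
$ rfsolve oracle --sources sources.nwk
{
  "best_score": 0,
  "constrained": false,
  "num_optima": 1,
  "tree": "(a,b,(c,(d,e)));"
}
```

Other subcommands: `rfsolve score --supertree F --sources F2 [--true-tree F3]`
scores an existing supertree (and reports the normalized RF error rate
against a known model tree); `rfsolve simulate` generates seeded synthetic
model trees and scaffold-plus-clades source collections.

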