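# Methods

## Scope and assumptions

All trees are rooted, full binary phylogenies; only leaves carry labels.
The species tree must have unique leaf labels; gene trees may repeat labels
(multi-copy families).  Gene leaf labels resolve to species labels either
identically or, with a configured delimiter, by taking the prefix before
its first occurrence (`speciesX_gene1 → speciesX`).  Non-binary input is
rejected rather than resolved: the cost models and the neighborhood
machinery are defined on binary trees, and silently binarizing would change
the question being asked.  Branch lengths are read and discarded — all
three cost models are purely topological.

Gene trees are assumed correctly rooted (in practice by an outgroup; the
CLI offers `--root-with LABEL` as a convenience).  Lateral gene transfer is
not modeled.

## Reconciliation costs

The LCA mapping M is computed bottom-up in linear time after the species
tree is preprocessed for constant-time LCA and depth queries (Euler tour
plus a sparse range-minimum table).  Per-vertex scores use only the depths
of M-images, so each is O(1):

* duplication: vertex g is a duplication iff M(g) equals the image of one
  of its children;
* duplication-loss: duplications plus losses, where losses at g are
  Σ_h |d(M(g), M(h)) − 1| over children h, except 0 when both children map
  to M(g) itself;
* deep coalescence: Σ_h d(M(g), M(h)) per vertex, and |E(S)| subtracted
  from the total.

Two conventions deserve comment.  First, the deep-coalescence
normalization subtracts the species tree's *edge* count; this is the only
choice under which a congruent one-copy gene tree scores zero, and the unit
tests pin that property (an alternative internal-vertex-count convention
circulates in the literature and fails it).  Second, the leaf mapping is
nominally a surjection, but real gene families under-sample species, so all
costs are computed against the species tree restricted to the species
present in the gene tree (suppressing degree-two vertices).  This restores
surjectivity and keeps every model's cost non-negative; an independent
per-species-edge "extra lineages" implementation cross-checks the
deep-coalescence formula on exhaustive small instances.

## The fast SPR search

For a fixed pruned subtree G_v, the candidate set is "G_v regrafted above
y" for every position y outside G_v.  These candidates form a tree X:
rooted at the candidate that regrafts above the root, with candidate
"above y" the child of candidate "above parent-of-y".  Adjacent candidates
differ by a single NNI that relocates G_v's attachment point, and along
that move the LCA mapping changes *only* at the two vertices flanking it —
everything below either vertex and everything above their parent keeps its
leaf set.  The solver therefore walks X depth-first, maintaining the
current tree in place together with its mapping and the running cost
difference from the root candidate; each step updates one mapping entry
(the new attachment vertex's sibling image via one LCA query) and the two
affected per-vertex scores.  Backtracking pops an undo record — the swapped
child pointers, the single overwritten mapping entry, and the previous
delta — restoring the state exactly.

One subtlety, discovered while testing and worth recording: if one joins
candidates whenever they are one *generic* NNI apart, the resulting graph
is not always a tree.  Regrafting above two sibling positions yields
candidates that are also one NNI apart by moving the *other* subtree, which
adds chords (a five-leaf instance suffices:
`((s0,(s1,s2)),(s4,s3))` pruning `(s1,s2)`).  The structure that matters —
and the one the solver walks and the tests verify — is adjacency via NNI
moves that relocate the pruned subtree; that graph is a rooted binary tree
with exactly one degree-2 vertex (the root candidate) and all others of
degree 1 or 3.

Scanning all prune choices v gives the full SPR optimum.  The work is one
O(n) mapping build plus O(1) per candidate for each of the 2n−2 choices of
v: Θ(n²) overall, which the tests confirm empirically (log-log slope of
candidates examined vs leaf count ≈ 2.1 over 16–128 leaves).

## TBR: rooting and regraft decompose

A TBR move is an SPR move whose pruned subtree may first be rerooted.  The
score contributions of vertices inside the pruned subtree depend only on
its rooting, and those outside only on the regraft position; the vertex
joining the two parts maps to the species LCA of the pruned subtree's
leaves, which is invariant under rerooting.  The optimum therefore
decomposes: first find the best rooting of G_v, then the best regraft for
that rooting.  Best rooting is itself a linear-time scan: moving the root
across one edge changes the children of exactly two vertices (the root and
the pivot), so adjacent rootings differ by a constant-time two-vertex
delta, using precomputed "down" mappings (ordinary LCA images) and "up"
mappings (image of the complement of each subtree).  A brute-force rescan
over all rerootings is kept behind an `exhaustive=True` flag as an
independent cross-check.

## Tie-breaking and degenerate inputs

* If no neighbor is *strictly* cheaper, the original tree is returned with
  `edit=None` (minimal-change bias); among improving candidates the first
  in the deterministic traversal order wins (v in preorder of G; within
  one v, preorder of the adjacency tree X).
* Gene trees with fewer than three leaves are returned unchanged — their
  neighborhoods contain only trees isomorphic to the input.
* Pruning a child of the root makes the root candidate isomorphic to the
  input; the walk handles it like any other candidate.
* Costs, deltas, and scores are exact integers throughout; deltas may be
  negative.

`debug=True` on the solvers re-derives, for every NNI edge traversed, the
full mapping and total cost from scratch and verifies both the two-vertex
delta and the locality of the mapping change, raising on any disagreement.
This is the package's runtime proof-of-correctness hook and is exercised
over >10⁴ edges in the test suite.

## Synthetic data

The generator stands in for real curated datasets so that every test and
the acceptance script are self-contained.  A species tree over n taxa is
grown by a Yule process (repeatedly splitting a uniformly chosen leaf) —
adequate because correctness, not topology distribution, is what the tests
consume.  A gene tree starts congruent to the species tree and is degraded
by three mechanisms with separately configurable rates: species drop-out
(unsampled lineages; at least two leaves always survive), leaf expansion
into a same-label cherry (a clean gene duplication: it adds exactly one
duplication event and nothing else), and uniformly random SPR moves with
null moves rejected (an "error" must change the topology).  Generation is
a pure function of its configuration; the default study condition mirrors
a classic benchmark shape — 106 gene families over 8 taxa, each one SPR
from congruent.

What the generator does *not* emulate: sequence-level estimation noise
(errors here are exactly k SPR moves, real error is not), birth–death
duplication/loss along the species tree, coalescent variance, and rooting
error.  Passing tests therefore demonstrate that the solvers find true
neighborhood optima and recover single-move corruptions — not that one SPR
pass fixes real gene trees, whose error may well extend beyond one edit.

## Problem sizes used in the tests

Exhaustive-oracle agreement uses species trees of 4–12 leaves (SPR) and
4–10 (TBR), gene trees with up to two copies per species, 540 and 510
solver-vs-oracle comparisons respectively; adjacency-structure checks use
100 random instances of up to 8 taxa; recovery uses 20 replicates at 16
leaves; scaling uses 16–128 leaves.  These sizes keep the brute-force
oracles (the binding cost) comfortable while exercising every code path;
the fast solvers themselves handle far larger trees.

## Known limitations

* One edit per pass: the search returns the best single SPR/TBR neighbor.
  Repeated passes (`--rounds`) monotonically reduce cost but, pushed far
  enough, simply converge every gene tree onto the species-tree topology —
  the flag's help text carries that warning.
* The duplication-only model is blind to losses by design; with incomplete
  sampling the duplication-loss model inflates loss counts (the restriction
  convention mitigates, not eliminates, this).
* No support weighting: all clades are equally rearrangeable regardless of
  how well-supported they are in the underlying alignment.
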