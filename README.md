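# treemend

Gene tree error correction against a species tree by fast SPR/TBR local
search under the duplication, duplication-loss, and deep-coalescence
reconciliation cost models.

## The problem

Gene trees estimated from single-gene alignments are noisy, and topological
error inflates every downstream gene-tree / species-tree reconciliation
analysis: spurious duplications, phantom losses, exaggerated deep
coalescence.  A cheap and effective remedy is *error correction by local
rearrangement*: assume the true gene tree lies within one edit of the
estimated one, and replace the estimate with the tree in its SPR (subtree
prune and regraft) or TBR (tree bisection and reconnection) neighborhood
that minimizes the reconciliation cost with a trusted species tree.

`treemend` implements this search in Θ(n²) total time for a gene tree with
n taxa — an n-fold speedup over naive SPR re-scoring and an n²-fold speedup
for TBR — so whole-genome cohorts of gene families can be corrected in
seconds.  It is aimed at phylogenomics practitioners running gene tree
parsimony or reconciliation-based analyses of multi-copy gene families.

## The model

Let G be a rooted binary gene tree whose leaves are labeled with species,
and S a rooted binary species tree.  The *LCA mapping* M sends each gene
vertex g to the lowest species vertex that could have contained it: a leaf
maps to its species, and an internal vertex maps to the species-tree LCA of
its children's images.  With d(·,·) the path length in S, the per-vertex
event counts for internal g with children g₁, g₂ are

* **duplication** (D):  1 if M(g) ∈ {M(g₁), M(g₂)}, else 0;
* **duplication-loss** (DL):  the duplication indicator plus the loss count
  Σᵢ |d(M(g), M(gᵢ)) − 1|  (0 when both children map to M(g));
* **deep coalescence** (DC):  Σᵢ d(M(g), M(gᵢ)), with |E(S)| subtracted
  from the tree-level total so congruent trees score 0.

The tree-level cost is the sum over internal vertices (all integer
arithmetic).  Before scoring, S is restricted to the species actually
sampled in G.

The solver's engine organizes the SPR neighborhood with a fixed pruned
subtree as a rooted binary tree of candidates in which adjacent candidates
differ by one NNI; along one NNI step the LCA mapping changes at most at
the two vertices flanking the move, so the cost difference of adjacent
candidates is computed in constant time.  For TBR, the optimal rooting of
the pruned subtree and the optimal regraft position are independent and are
optimized separately, each in linear time.

## Worked example

Generate a synthetic cohort — 10 gene trees over 8 species, each exactly
one random SPR move away from the species tree — and correct it:

```bash
treemend generate --n-taxa 8 --n-genes 10 --seed 0 --out demo
treemend correct --species demo/species.nwk --genes demo/genes.nwk \
                 --model deepcoal --neighborhood spr --out demo_out
```

which prints

```
Error correction summary (model=deepcoal, neighborhood=spr, rounds=1)

Reconciliation Cost     Original   Post-Correction
0                              0                10
1                              3                 0
2                              1                 0
3                              4                 0
4                              0                 0
>4                             2                 0

Total cost: 28 -> 0 over 10 gene trees
```

Before correction the 10 gene trees imply 28 extra lineages in total (three
trees imply one, one implies two, and so on); a single SPR rearrangement
per gene removes every implied deep-coalescence event, as expected when
each tree carries exactly one SPR's worth of error.  `demo_out/` also
contains the corrected trees (`corrected.nwk`, input order preserved) and a
per-gene table (`report.tsv`) listing original cost, corrected cost, and
the edit applied, e.g. `SPR prune=3 regraft=14`.

The same machinery is available as a library:

```python
>>> import treemend as tm
>>> g = tm.parse_newick("((A,C),B);")        # misplaced B
>>> s = tm.parse_newick("((A,B),C);")
>>> tm.reconciliation_cost(g, s, "duploss")
4
>>> res = tm.solve_sec(g, s, "duploss")      # best SPR neighbor
>>> res.best_cost, tm.write_newick(res.best_tree)
(0, '(C,(A,B));')
```

`solve_tec` searches the larger TBR neighborhood; `--verify` (or
`treemend.oracle`) cross-checks any result against exhaustive enumeration.

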