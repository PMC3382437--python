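"""Seeded generation of species trees and corrupted gene trees.

Real gene trees are estimated from alignments and carry topological error;
this module manufactures that situation deterministically.  A species tree
is grown by a Yule (random leaf split) process; a gene tree starts congruent
to it and is then degraded by (i) unsampled species (leaf drops), (ii) gene
duplications (a leaf expanded into a same-label cherry), and (iii) a number
of random topology-changing SPR moves — the "errors" the solvers are asked
to undo.  Everything is a pure function of its configuration, so test
fixtures need never be stored.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treekit import Tree, is_isomorphic, tree_from_nested
from .reconcile import restrict_species_tree
from .editops import EditDescriptor, admissible_regrafts, spr


@dataclass(frozen=True)
class GenConfig:
    """Recipe for one corrupted gene tree."""

    n_taxa: int = 8
    dup_leaf_prob: float = 0.0
    n_spr_errors: int = 1
    drop_leaf_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        for p in (self.dup_leaf_prob, self.drop_leaf_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_spr_errors < 0:
            raise ValueError("n_spr_errors must be >= 0")


def random_species_tree(n_taxa: int, seed: int) -> Tree:
    """Yule-grown full binary species tree with leaves sp01..spNN.

    A uniformly chosen leaf is split into a cherry until ``n_taxa`` leaves
    exist; labels are assigned left-to-right afterwards.  Identical
    (n_taxa, seed) pairs give identical trees.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root: list = ["?"]
    leaves = [root]
    while len(leaves) < n_taxa:
        i = int(rng.integers(len(leaves)))
        node = leaves[i]
        a: list = ["?"]
        b: list = ["?"]
        node[:] = [a, b]
        leaves[i] = a
        leaves.append(b)

    width = max(2, len(str(n_taxa)))
    counter = [0]

    def to_nested(item):
        if len(item) == 1:
            counter[0] += 1
            return f"sp{counter[0]:0{width}d}"
        return (to_nested(item[0]), to_nested(item[1]))

    return tree_from_nested(to_nested(root))


def corrupt_gene_tree(s: Tree, cfg: GenConfig) -> tuple[Tree, list[EditDescriptor]]:
    """A gene tree for species tree ``s`` degraded per ``cfg``.

    Starts from a one-copy congruent gene tree; drops species leaves, then
    expands surviving leaves into same-label cherries, then applies
    ``n_spr_errors`` uniformly random SPR moves, rejecting moves that leave
    the topology unchanged.  Returns the tree and the list of SPR edits
    actually applied (ground truth for recovery experiments).

    With no SPR errors, the duplication cost of the result equals the number
    of cherry expansions and its deep-coalescence cost is 0.
    """
    rng = np.random.default_rng(cfg.seed)
    g = s.copy()

    if cfg.drop_leaf_prob > 0:
        leaves = list(g.leaves())
        kept = [lf for lf in leaves if rng.random() >= cfg.drop_leaf_prob]
        if len(kept) < 2:
            for lf in leaves:           # deterministic refill, preorder
                if lf not in kept:
                    kept.append(lf)
                if len(kept) >= 2:
                    break
        if len(kept) < len(leaves):
            g = restrict_species_tree(g, {lf.label for lf in kept})

    if cfg.dup_leaf_prob > 0:
        for leaf in list(g.leaves()):
            if rng.random() < cfg.dup_leaf_prob:
                c1 = g.new_node(leaf.label)
                c2 = g.new_node(leaf.label)
                c1.parent = c2.parent = leaf
                leaf.children = [c1, c2]
                leaf.label = None

    edits: list[EditDescriptor] = []
    for _ in range(cfg.n_spr_errors):
        if g.n_leaves < 3:
            break
        pairs = [(v, y) for v in g.preorder() if v.parent is not None
                 for y in admissible_regrafts(g, v)]
        for _attempt in range(100):
            v, y = pairs[int(rng.integers(len(pairs)))]
            candidate = spr(g, v, y)
            if not is_isomorphic(candidate, g):
                edits.append(EditDescriptor("SPR", v.id, y.id))
                g = candidate
                break
        else:
            break   # no topology-changing move found at this size
    return g, edits


def gene_family_battery(n_genes: int = 106, n_taxa: int = 8, seed: int = 0,
                        n_spr_errors: int = 1, dup_leaf_prob: float = 0.0,
                        drop_leaf_prob: float = 0.0
                        ) -> tuple[Tree, list[Tree], list[list[EditDescriptor]]]:
    """A cohort of corrupted gene trees over one species tree.

    The defaults mirror the shape of a classic benchmark: 106 gene families
    over 8 taxa, each one SPR move away from the species-tree topology.
    Gene i uses seed ``seed + i``.
    """
    species = random_species_tree(n_taxa, seed)
    genes, edit_log = [], []
    for i in range(n_genes):
        cfg = GenConfig(n_taxa=n_taxa, dup_leaf_prob=dup_leaf_prob,
                        n_spr_errors=n_spr_errors,
                        drop_leaf_prob=drop_leaf_prob, seed=seed + i)
        gt, edits = corrupt_gene_tree(species, cfg)
        genes.append(gt)
        edit_log.append(edits)
    return species, genes, edit_log
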