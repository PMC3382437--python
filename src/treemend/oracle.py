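"""Naive neighborhood baselines: enumerate every neighbor, score from scratch.

These are the quadratic/cubic-per-problem baselines the fast solvers improve
on.  They share the neighborhood enumeration with :mod:`treemend.editops` but
deliberately not the incremental scorer of :mod:`treemend.fastsearch`, so
they serve as an independent correctness oracle.  Also here: an independent
"extra lineages" implementation of the deep-coalescence cost, counted per
species-tree edge rather than per gene-tree vertex.
"""
from __future__ import annotations

from .treekit import Tree
from .editops import enumerate_spr, enumerate_tbr
from .fastsearch import CorrectionResult
from .reconcile import (
    CostModel,
    gene_species_labels,
    lca_mapping,
    prepare_species,
    reconciliation_cost,
)

#: Instance-size guards: the oracle is deliberately simple and is meant for
#: desk-scale cross-checks only.
MAX_SPR_TAXA = 16
MAX_TBR_TAXA = 12


def _check_size(g: Tree, move: str, allow_large: bool) -> None:
    if allow_large:
        return
    taxa = len(gene_species_labels(g))
    cap = MAX_SPR_TAXA if move == "spr" else MAX_TBR_TAXA
    if taxa > cap:
        raise ValueError(
            f"oracle capped at {cap} taxa for {move.upper()} "
            f"(got {taxa}); pass allow_large=True to override"
        )


def neighborhood_costs(g: Tree, s: Tree, models, move: str = "spr",
                       v=None, allow_large: bool = False,
                       species_delimiter: str | None = None):
    """Cost of every neighbor under each model, in enumeration order.

    Returns ``{model: [(cost, descriptor), ...]}``.  Each neighbor is scored
    by a full recomputation of its reconciliation cost.
    """
    move = move.lower()
    if move not in ("spr", "tbr"):
        raise ValueError(f"move must be 'spr' or 'tbr', got {move!r}")
    _check_size(g, move, allow_large)
    models = [CostModel.coerce(m) for m in models]
    s_eff, idx = prepare_species(s, g, species_delimiter)
    enum = enumerate_spr if move == "spr" else enumerate_tbr
    out = {m: [] for m in models}
    for desc, t2 in enum(g, v):
        for m in models:
            cost = reconciliation_cost(t2, s_eff, m, species_delimiter, idx)
            out[m].append((cost, desc))
    return out


def naive_best_in_neighborhood(g: Tree, s: Tree, model, move: str = "spr",
                               v=None, allow_large: bool = False,
                               species_delimiter: str | None = None
                               ) -> CorrectionResult:
    """True neighborhood minimum by brute force (ties: original tree first,
    then enumeration order)."""
    move = move.lower()
    if move not in ("spr", "tbr"):
        raise ValueError(f"move must be 'spr' or 'tbr', got {move!r}")
    _check_size(g, move, allow_large)
    model = CostModel.coerce(model)
    s_eff, idx = prepare_species(s, g, species_delimiter)
    original = reconciliation_cost(g, s_eff, model, species_delimiter, idx)
    enum = enumerate_spr if move == "spr" else enumerate_tbr
    best = None          # (cost, descriptor, tree)
    count = 0
    for desc, t2 in enum(g, v):
        count += 1
        cost = reconciliation_cost(t2, s_eff, model, species_delimiter, idx)
        if best is None or cost < best[0]:
            best = (cost, desc, t2)
    if best is None or best[0] >= original:
        return CorrectionResult(g.copy(), original, original, None, count)
    return CorrectionResult(best[2], best[0], original, best[1], count)


def extra_lineages_cost(g: Tree, s: Tree,
                        species_delimiter: str | None = None) -> int:
    """Deep-coalescence cost counted as extra lineages per species edge.

    A gene lineage (u, w) crosses the species edge above vertex c when
    M(w) <= c < M(u); the cost is the total excess over one lineage per
    edge.  Intended for completely sampled gene families, where every edge
    carries at least one lineage; an independent cross-check for the
    vertex-sum deep-coalescence formula.
    """
    s_eff, idx = prepare_species(s, g, species_delimiter)
    m = lca_mapping(g, s_eff, idx, species_delimiter)
    lca = idx.lca

    def is_ancestor(a, b) -> bool:     # a <= b in species-tree order
        return lca(a, b) is b

    gene_edges = [(n.parent, n) for n in g.preorder() if n.parent is not None]
    total = 0
    for c in s_eff.preorder():
        if c.parent is None:
            continue
        crossing = 0
        for u, w in gene_edges:
            mw, mu = m.map[w.id], m.map[u.id]
            if is_ancestor(mw, c) and is_ancestor(c, mu) and mu is not c:
                crossing += 1
        total += max(crossing - 1, 0)
    return total
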