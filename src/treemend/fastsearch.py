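"""Fast SPR and TBR error-correction solvers.

The SPR neighborhood of a gene tree G for a fixed pruned subtree G_v can be
organized as a tree X whose vertices are the candidate regraft positions and
whose edges connect candidates one NNI apart.  X is rooted at the candidate
that regrafts G_v above the root of G.  Walking X depth-first, each step is a
single in-place NNI under which the LCA mapping changes at most at the two
vertices flanking the move; the cost difference of adjacent candidates is
therefore computable in constant time.  One restricted problem (all regraft
positions for one v) costs Θ(n); scanning all v costs Θ(n²).

For TBR the pruned subtree may additionally be rerooted before regrafting.
The cost contributions of the pruned subtree and of the remainder are
independent, so the optimum decomposes: find the best rooting of G_v
(linear time, again by constant-time two-vertex deltas between adjacent
rootings), then find the best regraft position for that rooting with the
SPR machinery.
"""
from __future__ import annotations

from dataclasses import dataclass

from .treekit import LCAIndex, Node, Tree
from .reconcile import (
    CostModel,
    lca_mapping,
    prepare_species,
    reconciliation_cost,
    score_vertex,
)
from .editops import EditDescriptor, _detach, _attach_above, spr, tbr

#: Counters updated while a solver runs with ``debug=True``: every traversed
#: NNI edge is re-verified against a from-scratch recomputation.
DEBUG_STATS = {"edges_checked": 0}


def reset_debug_stats() -> None:
    DEBUG_STATS["edges_checked"] = 0


@dataclass
class CorrectionResult:
    """Outcome of one neighborhood search."""

    best_tree: Tree
    best_cost: int
    original_cost: int
    edit: EditDescriptor | None
    candidates_examined: int


class _DebugCheckError(AssertionError):
    """An incremental update disagreed with a from-scratch recomputation."""


def _walk_restricted(g: Tree, v: Node, model: CostModel, s_eff: Tree,
                     idx: LCAIndex, species_delimiter: str | None,
                     debug: bool):
    """Scan all regraft positions for pruning ``v`` by NNI steps.

    Returns (base, best_delta, best_pos_id, positions), where ``base`` is the
    un-normalized vertex-score sum of the root candidate (G_v regrafted above
    the root), ``best_delta`` the minimum cumulative score difference over
    all candidates, and ``best_pos_id`` the regraft coordinate achieving it
    (a node id of ``g``).
    """
    work = g.copy()
    vb = work.node(v.id)
    u = _detach(work, vb)
    remainder_root = work.root
    gbar_pos_id = remainder_root.id
    _attach_above(work, u, vb, remainder_root)

    M = lca_mapping(work, s_eff, idx, species_delimiter).map
    lca = idx.lca

    def sc(node: Node) -> int:
        c1, c2 = node.children
        return score_vertex(model, idx, M[node.id], M[c1.id], M[c2.id])

    base = sum(sc(n) for n in work.preorder() if not n.is_leaf)

    state = {"delta": 0, "best_delta": 0, "best_pos": gbar_pos_id,
             "positions": 1}

    def descend(k: Node):
        """One NNI: move v's attachment from above Sb(v) to above ``k``."""
        A = vb.parent
        B = vb.sibling()
        z = k.sibling()
        old = sc(A) + sc(B)
        ai = A.children.index(vb)
        bi = B.children.index(z)
        A.children[ai] = z
        z.parent = A
        B.children[bi] = vb
        vb.parent = B
        saved_mb = M[B.id]
        M[B.id] = lca(M[vb.id], M[k.id])
        state["delta"] += sc(A) + sc(B) - old
        return (A, B, z, ai, bi, saved_mb)

    def undo(frame, saved_delta: int) -> None:
        A, B, z, ai, bi, saved_mb = frame
        A.children[ai] = vb
        vb.parent = A
        B.children[bi] = z
        z.parent = B
        M[B.id] = saved_mb
        state["delta"] = saved_delta

    def debug_check(frame, total_parent: int, delta_parent: int) -> int:
        """Verify one NNI edge against a from-scratch recomputation.

        Checks that the mapping changed at no vertex outside the flanking
        pair, that the incremental mapping matches, and that the two-vertex
        delta equals the full cost difference.  Returns the recomputed total.
        """
        A, B = frame[0], frame[1]
        fresh = lca_mapping(work, s_eff, idx, species_delimiter).map
        changed = {nid for nid in fresh if fresh[nid] is not M[nid]}
        if not changed <= {A.id, B.id}:
            raise _DebugCheckError(
                f"mapping changed outside the NNI pair: {sorted(changed)}"
            )
        total = sum(
            score_vertex(model, idx, fresh[n.id],
                         fresh[n.children[0].id], fresh[n.children[1].id])
            for n in work.preorder() if not n.is_leaf
        )
        if total - total_parent != state["delta"] - delta_parent:
            raise _DebugCheckError(
                "two-vertex delta disagrees with full recomputation"
            )
        DEBUG_STATS["edges_checked"] += 1
        return total

    def walk(pos: Node, total_here: int) -> None:
        for k in list(pos.children):
            saved_delta = state["delta"]
            frame = descend(k)
            total_k = (debug_check(frame, total_here, saved_delta)
                       if debug else 0)
            state["positions"] += 1
            if state["delta"] < state["best_delta"]:
                state["best_delta"] = state["delta"]
                state["best_pos"] = k.id
            walk(k, total_k)
            undo(frame, saved_delta)

    walk(remainder_root, base)
    return base, state["best_delta"], state["best_pos"], state["positions"]


def _norm(model: CostModel, s_eff: Tree) -> int:
    return (len(s_eff) - 1) if model is CostModel.DEEPCOAL else 0


def solve_r_sec(g: Tree, s: Tree, v, model, *,
                species_delimiter: str | None = None,
                debug: bool = False,
                _prepared: tuple[Tree, LCAIndex] | None = None) -> CorrectionResult:
    """Best tree in the SPR neighborhood for a fixed pruned subtree ``v``."""
    model = CostModel.coerce(model)
    v = g.node(v.id if isinstance(v, Node) else v)
    if v.parent is None:
        raise ValueError("v must not be the root")
    s_eff, idx = _prepared or prepare_species(s, g, species_delimiter)
    original = reconciliation_cost(g, s_eff, model, species_delimiter, idx)
    base, best_delta, best_pos, positions = _walk_restricted(
        g, v, model, s_eff, idx, species_delimiter, debug
    )
    best_cost = base + best_delta - _norm(model, s_eff)
    if best_cost < original:
        tree = spr(g, v, g.node(best_pos))
        edit = EditDescriptor("SPR", v.id, best_pos)
        return CorrectionResult(tree, best_cost, original, edit, positions)
    return CorrectionResult(g.copy(), original, original, None, positions)


def solve_sec(g: Tree, s: Tree, model, *,
              species_delimiter: str | None = None,
              debug: bool = False) -> CorrectionResult:
    """Minimum-cost tree in the full SPR neighborhood of ``g``.

    Ties are broken toward the original tree (returned with ``edit=None``
    when no neighbor is strictly better), then toward the first improving
    candidate in the deterministic traversal order.
    """
    model = CostModel.coerce(model)
    s_eff, idx = prepare_species(s, g, species_delimiter)
    original = reconciliation_cost(g, s_eff, model, species_delimiter, idx)
    if g.n_leaves < 3:
        return CorrectionResult(g.copy(), original, original, None, 0)
    norm = _norm(model, s_eff)
    best_cost = original
    best_v = best_pos = None
    candidates = 0
    for v in g.preorder():
        if v.parent is None:
            continue
        base, delta, pos, count = _walk_restricted(
            g, v, model, s_eff, idx, species_delimiter, debug
        )
        candidates += count
        cost = base + delta - norm
        if cost < best_cost:
            best_cost, best_v, best_pos = cost, v, pos
    if best_v is None:
        return CorrectionResult(g.copy(), original, original, None, candidates)
    tree = spr(g, best_v, g.node(best_pos))
    edit = EditDescriptor("SPR", best_v.id, best_pos)
    return CorrectionResult(tree, best_cost, original, edit, candidates)


# ---------------------------------------------------------------------------
# TBR: best rooting of the pruned subtree, then best regraft
# ---------------------------------------------------------------------------

def best_rooting(gv: Tree, s: Tree, model, *,
                 species_delimiter: str | None = None,
                 species_index: LCAIndex | None = None,
                 exhaustive: bool = False) -> tuple[Node, int]:
    """The vertex x minimizing the internal-vertex score sum of RR(gv, x).

    The mapping of the rerooted subtree's root is the species LCA of all its
    leaves, identical for every x; only the two vertices flanking the moved
    root change between adjacent rootings, so a single depth-first pass over
    the edges of ``gv`` evaluates every rooting in constant time per step.
    ``exhaustive=True`` switches to a brute-force scan over all rerootings
    (an independent cross-check path).
    """
    model = CostModel.coerce(model)
    if species_index is None:
        s, species_index = prepare_species(s, gv, species_delimiter)
    idx = species_index
    if gv.n_leaves == 1:
        return gv.root, 0

    if exhaustive:
        from .editops import reroot
        best = None
        for x in gv.preorder():
            rr = reroot(gv, x)
            m = lca_mapping(rr, s, idx, species_delimiter)
            tot = 0
            for n in rr.preorder():
                if n.is_leaf:
                    continue
                c1, c2 = n.children
                tot += score_vertex(model, idx, m.map[n.id],
                                    m.map[c1.id], m.map[c2.id])
            if best is None or tot < best[1]:
                best = (x, tot)
        return best

    D = lca_mapping(gv, s, idx, species_delimiter).map
    root = gv.root
    mall = D[root.id]

    def sc_triple(mg, m1, m2):
        return score_vertex(model, idx, mg, m1, m2)

    identity = 0
    for n in gv.preorder():
        if n.is_leaf:
            continue
        c1, c2 = n.children
        identity += sc_triple(D[n.id], D[c1.id], D[c2.id])

    if gv.n_leaves == 2:
        return root, identity

    lca = idx.lca
    U: dict[int, Node] = {}
    a, b = root.children
    U[a.id] = D[b.id]
    U[b.id] = D[a.id]
    for w in gv.preorder():
        if w is root or w.is_leaf:
            continue
        c1, c2 = w.children
        U[c1.id] = lca(U[w.id], D[c2.id])
        U[c2.id] = lca(U[w.id], D[c1.id])

    best_x, best_score = root, identity

    def visit(p: Node, score_p: int) -> None:
        nonlocal best_x, best_score
        for w in p.children:
            w2 = w.sibling()
            score_w = (score_p
                       - sc_triple(mall, D[p.id], U[p.id])
                       - sc_triple(D[p.id], D[w.id], D[w2.id])
                       + sc_triple(mall, D[w.id], U[w.id])
                       + sc_triple(U[w.id], D[w2.id], U[p.id]))
            if score_w < best_score:
                best_x, best_score = w, score_w
            if not w.is_leaf:
                visit(w, score_w)

    for c in root.children:
        # rooting on an edge incident to the root is the identity tree
        if not c.is_leaf:
            visit(c, identity)

    return best_x, best_score


def _splice_rerooted(g: Tree, v: Node, x: Node) -> tuple[Tree, Node]:
    """Copy of ``g`` with subtree ``v`` replaced by RR(G_v, x)."""
    from .editops import reroot
    gv = g.extract_subtree(v)
    sub_r = reroot(gv, gv.node(x.id))
    g2 = g.copy()
    v2 = g2.node(v.id)
    p = v2.parent
    g2._unregister_subtree(v2)
    p.children[p.children.index(v2)] = sub_r.root
    sub_r.root.parent = p
    g2._register_subtree(sub_r.root)
    return g2, sub_r.root


def solve_r_tec(g: Tree, s: Tree, v, model, *,
                species_delimiter: str | None = None,
                debug: bool = False,
                _prepared: tuple[Tree, LCAIndex] | None = None) -> CorrectionResult:
    """Best tree in the TBR neighborhood for a fixed pruned subtree ``v``."""
    model = CostModel.coerce(model)
    v = g.node(v.id if isinstance(v, Node) else v)
    if v.parent is None:
        raise ValueError("v must not be the root")
    s_eff, idx = _prepared or prepare_species(s, g, species_delimiter)
    original = reconciliation_cost(g, s_eff, model, species_delimiter, idx)

    gv = g.extract_subtree(v)
    xstar, _ = best_rooting(gv, s_eff, model,
                            species_delimiter=species_delimiter,
                            species_index=idx)
    rootings = len(gv)
    if xstar is gv.root or xstar.parent is gv.root:
        g2, v2 = g, v
    else:
        g2, v2 = _splice_rerooted(g, v, xstar)
    base, delta, pos, positions = _walk_restricted(
        g2, v2, model, s_eff, idx, species_delimiter, debug
    )
    best_cost = base + delta - _norm(model, s_eff)
    candidates = positions + rootings
    if best_cost < original:
        tree = tbr(g, v, g.node(xstar.id), g.node(pos))
        edit = EditDescriptor("TBR", v.id, pos, xstar.id)
        return CorrectionResult(tree, best_cost, original, edit, candidates)
    return CorrectionResult(g.copy(), original, original, None, candidates)


def solve_tec(g: Tree, s: Tree, model, *,
              species_delimiter: str | None = None,
              debug: bool = False) -> CorrectionResult:
    """Minimum-cost tree in the full TBR neighborhood of ``g``."""
    model = CostModel.coerce(model)
    s_eff, idx = prepare_species(s, g, species_delimiter)
    original = reconciliation_cost(g, s_eff, model, species_delimiter, idx)
    if g.n_leaves < 3:
        return CorrectionResult(g.copy(), original, original, None, 0)
    norm = _norm(model, s_eff)
    best_cost = original
    best: tuple[Node, Node, int] | None = None   # (v, xstar, pos)
    candidates = 0
    for v in g.preorder():
        if v.parent is None:
            continue
        gv = g.extract_subtree(v)
        xstar, _ = best_rooting(gv, s_eff, model,
                                species_delimiter=species_delimiter,
                                species_index=idx)
        candidates += len(gv)
        if xstar is gv.root or xstar.parent is gv.root:
            g2, v2 = g, v
        else:
            g2, v2 = _splice_rerooted(g, v, xstar)
        base, delta, pos, positions = _walk_restricted(
            g2, v2, model, s_eff, idx, species_delimiter, debug
        )
        candidates += positions
        cost = base + delta - norm
        if cost < best_cost:
            best_cost = cost
            best = (v, g.node(xstar.id), pos)
    if best is None:
        return CorrectionResult(g.copy(), original, original, None, candidates)
    v, xstar, pos = best
    tree = tbr(g, v, xstar, g.node(pos))
    edit = EditDescriptor("TBR", v.id, pos, xstar.id)
    return CorrectionResult(tree, best_cost, original, edit, candidates)
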