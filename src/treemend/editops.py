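"""Tree edit operations: rerooting, NNI, SPR, TBR, and their neighborhoods.

All operations are defined on the *planted* tree (the tree with a formal
root edge above its root), which makes "regraft above the root" a valid
position.  A regraft position is always named by the vertex ``y`` below the
edge being subdivided; ``y`` equal to the current root means the pruned
subtree is reattached above the root.

Operations never mutate their input: they return fresh trees in which every
surviving node keeps its id, the suppressed parent of the pruned subtree is
reused as the new attachment vertex (so it, too, keeps its id), and the
pruned subtree's nodes are preserved verbatim.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .treekit import Node, Tree


class EditError(ValueError):
    """An edit operation was requested with invalid coordinates."""


@dataclass(frozen=True)
class EditDescriptor:
    """A (prune, reroot, regraft) coordinate triple naming one edit."""

    kind: str                     # "NNI" | "SPR" | "TBR"
    pruned: int                   # id of v, the root of the pruned subtree
    regraft_above: int            # id of y; y == root id means above the root
    reroot_at: int | None = None  # id of x for TBR, else None

    def __str__(self) -> str:
        parts = [f"{self.kind} prune={self.pruned}"]
        if self.reroot_at is not None:
            parts.append(f"reroot={self.reroot_at}")
        parts.append(f"regraft={self.regraft_above}")
        return " ".join(parts)


def _as_node(t: Tree, v) -> Node:
    node = v if isinstance(v, Node) else t.node(v)
    node = t.node(node.id)
    return node


def _detach(t: Tree, v: Node) -> Node:
    """Remove subtree ``v`` and suppress its parent u; return u (unlinked).

    The v-subtree stays registered in the tree (callers either reattach it
    or explicitly unregister it).
    """
    u = v.parent
    w = v.sibling()
    p = u.parent
    if p is None:
        t.root = w
        w.parent = None
    else:
        p.children[p.children.index(u)] = w
        w.parent = p
    del t._nodes[u.id]
    v.parent = None
    u.parent = None
    u.children = []
    return u


def _attach_above(t: Tree, u: Node, sub_root: Node, y: Node) -> None:
    """Insert ``u`` on the edge above ``y`` with children (sub_root, y)."""
    py = y.parent
    u.children = [sub_root, y]
    sub_root.parent = u
    y.parent = u
    if py is None:
        t.root = u
        u.parent = None
    else:
        py.children[py.children.index(y)] = u
        u.parent = py
    t._nodes[u.id] = u


def reroot(t: Tree, x) -> Tree:
    """Move the root onto the edge above ``x``.

    Identity (a plain copy) when x is the root or a child of the root;
    otherwise the old root is suppressed and a new root — reusing the old
    root's id — subdivides the edge (Pa(x), x).
    """
    x = _as_node(t, x)
    t2 = t.copy()
    x2 = t2.node(x.id)
    if x2 is t2.root or x2.parent is t2.root:
        return t2

    path = [x2]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    k = len(path) - 1          # path[k] is the old root; k >= 2 here
    sib = {i: (path[i].children[1] if path[i].children[0] is path[i - 1]
               else path[i].children[0])
           for i in range(1, k + 1)}

    new_root = path[k]          # reuse the old root node (stable id)
    new_root.children = [x2, path[1]]
    for i in range(1, k):
        nxt = path[i + 1] if i + 1 <= k - 1 else sib[k]
        path[i].children = [sib[i], nxt]
    for node in [new_root] + path[1:k]:
        for c in node.children:
            c.parent = node
    new_root.parent = None
    t2.root = new_root
    return t2


def _check_spr_coords(t: Tree, v: Node, y: Node) -> None:
    if v.parent is None:
        raise EditError("cannot prune at the root")
    in_v = {n.id for n in t.subtree_nodes(v)}
    if y.id in in_v:
        raise EditError("regraft inside pruned subtree")
    if y is v.parent:
        raise EditError("regraft position is the suppressed vertex")


def spr(t: Tree, v, y) -> Tree:
    """Prune subtree ``v`` and regraft it above ``y`` (SPR = TBR with x=v)."""
    v = _as_node(t, v)
    y = _as_node(t, y)
    _check_spr_coords(t, v, y)
    t2 = t.copy()
    v2 = t2.node(v.id)
    y2 = t2.node(y.id)
    u2 = _detach(t2, v2)
    _attach_above(t2, u2, v2, y2)
    return t2


def tbr(t: Tree, v, x, y) -> Tree:
    """Bisect above ``v``, reroot the pruned part at ``x``, regraft above ``y``."""
    v = _as_node(t, v)
    x = _as_node(t, x)
    y = _as_node(t, y)
    in_v = {n.id for n in t.subtree_nodes(v)}
    if x.id not in in_v:
        raise EditError("reroot vertex outside the pruned subtree")
    _check_spr_coords(t, v, y)
    if x is v or x.parent is v:
        return spr(t, v, y)     # identity branch of RR
    sub = t.extract_subtree(v)
    sub_r = reroot(sub, sub.node(x.id))
    t2 = t.copy()
    v2 = t2.node(v.id)
    y2 = t2.node(y.id)
    u2 = _detach(t2, v2)
    t2._unregister_subtree(v2)
    t2._register_subtree(sub_r.root)
    _attach_above(t2, u2, sub_r.root, y2)
    return t2


def nni(t: Tree, v) -> Tree:
    """Nearest-neighbor interchange: regraft ``v`` above its grandparent
    (or above the planted root when v's parent is the root)."""
    v = _as_node(t, v)
    if v.parent is None:
        raise EditError("cannot prune at the root")
    gp = v.parent.parent
    y = gp if gp is not None else v.sibling()
    return spr(t, v, y)


def admissible_regrafts(t: Tree, v) -> list[Node]:
    """All regraft positions for pruning ``v``: every vertex outside the
    pruned subtree except the suppressed parent, in preorder.  The current
    root (when it is not the parent of v) names the above-the-root position.
    """
    v = _as_node(t, v)
    if v.parent is None:
        raise EditError("cannot prune at the root")
    in_v = {n.id for n in t.subtree_nodes(v)}
    u = v.parent
    return [n for n in t.preorder() if n.id not in in_v and n is not u]


def enumerate_spr(t: Tree, v=None) -> Iterator[tuple[EditDescriptor, Tree]]:
    """Yield every SPR neighbor once per (v, y) coordinate pair.

    No isomorphism deduplication is applied: the neighborhood deliberately
    contains the null move (and possibly other trees isomorphic to ``t``).
    """
    if v is not None:
        vs = [_as_node(t, v)]
    else:
        vs = [n for n in t.preorder() if n.parent is not None]
    for vv in vs:
        for y in admissible_regrafts(t, vv):
            yield EditDescriptor("SPR", vv.id, y.id), spr(t, vv, y)


def enumerate_tbr(t: Tree, v=None) -> Iterator[tuple[EditDescriptor, Tree]]:
    """Yield every TBR neighbor once per (v, x, y) coordinate triple."""
    if v is not None:
        vs = [_as_node(t, v)]
    else:
        vs = [n for n in t.preorder() if n.parent is not None]
    for vv in vs:
        xs = t.subtree_nodes(vv)
        ys = admissible_regrafts(t, vv)
        for x in xs:
            for y in ys:
                yield EditDescriptor("TBR", vv.id, y.id, x.id), tbr(t, vv, x, y)
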