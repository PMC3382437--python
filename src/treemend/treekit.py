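"""Rooted full binary phylogenetic trees: Newick I/O, isomorphism, O(1) LCA.

Every tree in this package is a *rooted full binary* phylogeny: each internal
node has exactly two children, and only leaves carry labels.  Leaf labels may
repeat within a gene tree (multi-copy gene families) but must be unique within
a species tree.  Node handles are stable small integers assigned at parse or
construction time; edit operations elsewhere in the package preserve the id of
every node that survives an edit, so results can refer to nodes unambiguously.
"""
from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np
import dendropy


class TreeError(ValueError):
    """Malformed, non-binary, or otherwise unusable tree input."""


class Node:
    """A single tree vertex. Internal nodes have exactly two children."""

    __slots__ = ("id", "parent", "children", "label")

    def __init__(self, id: int, label: str | None = None):
        self.id = id
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def sibling(self) -> "Node | None":
        """The other child of this node's parent (None at the root)."""
        p = self.parent
        if p is None:
            return None
        a, b = p.children
        return b if a is self else a

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Node({self.id}, {self.label!r})"
        return f"Node({self.id}, children={[c.id for c in self.children]})"


class Tree:
    """Rooted full binary tree with an id -> node registry."""

    def __init__(self, root: Node):
        self.root = root
        self._nodes: dict[int, Node] = {}
        for node in _iter_preorder(root):
            if node.id in self._nodes:
                raise TreeError(f"duplicate node id {node.id}")
            self._nodes[node.id] = node
        self._next_id = max(self._nodes) + 1 if self._nodes else 0

    # -- registry -----------------------------------------------------------

    def node(self, node_id: int) -> Node:
        return self._nodes[node_id]

    def __contains__(self, node: Node) -> bool:
        return self._nodes.get(node.id) is node

    def __len__(self) -> int:
        return len(self._nodes)

    def new_node(self, label: str | None = None) -> Node:
        """Create and register a fresh node with an unused id."""
        node = Node(self._next_id, label)
        self._next_id += 1
        self._nodes[node.id] = node
        return node

    def _register_subtree(self, root: Node) -> None:
        for node in _iter_preorder(root):
            self._nodes[node.id] = node
            if node.id >= self._next_id:
                self._next_id = node.id + 1

    def _unregister_subtree(self, root: Node) -> None:
        for node in _iter_preorder(root):
            del self._nodes[node.id]

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return _iter_preorder(self.root)

    def postorder(self) -> Iterator[Node]:
        return _iter_postorder(self.root)

    def leaves(self) -> Iterator[Node]:
        return (n for n in _iter_preorder(self.root) if n.is_leaf)

    @property
    def n_leaves(self) -> int:
        return (len(self._nodes) + 1) // 2

    def leaf_labels(self) -> list[str]:
        """Leaf labels in preorder (a multiset for multi-copy gene trees)."""
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    def subtree_nodes(self, v: Node) -> list[Node]:
        return list(_iter_preorder(v))

    # -- copying ------------------------------------------------------------

    def copy(self) -> "Tree":
        """Deep copy preserving node ids (stable handles across copies)."""
        return Tree(_copy_subtree(self.root))

    def extract_subtree(self, v: Node) -> "Tree":
        """The subtree rooted at ``v`` as an independent tree (ids kept)."""
        return Tree(_copy_subtree(v))

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise TreeError on violation."""
        n_leaf = 0
        for node in self.preorder():
            if node.is_leaf:
                n_leaf += 1
                if not node.label:
                    raise TreeError(f"leaf {node.id} has no label")
            elif len(node.children) != 2:
                raise TreeError(f"node {node.id} has {len(node.children)} children")
            for c in node.children:
                if c.parent is not node:
                    raise TreeError(f"broken parent link at node {c.id}")
        if self.root.parent is not None:
            raise TreeError("root has a parent")
        if len(self._nodes) != 2 * n_leaf - 1:
            raise TreeError("node count != 2*leaves - 1")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({write_newick(self)!r})"


def _iter_preorder(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def _iter_postorder(root: Node) -> Iterator[Node]:
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded or node.is_leaf:
            yield node
        else:
            stack.append((node, True))
            stack.extend((c, False) for c in reversed(node.children))


def _copy_subtree(root: Node) -> Node:
    new_root = Node(root.id, root.label)
    stack = [(root, new_root)]
    while stack:
        old, new = stack.pop()
        for c in old.children:
            nc = Node(c.id, c.label)
            nc.parent = new
            new.children.append(nc)
            stack.append((c, nc))
    return new_root


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_DENDROPY_KW = dict(
    schema="newick",
    preserve_underscores=True,
    suppress_internal_node_taxa=True,
    suppress_leaf_node_taxa=True,
)


def parse_newick(text: str) -> Tree:
    """Parse one rooted Newick expression into a Tree.

    Branch lengths and internal node labels are read and discarded (the cost
    models here are purely topological).  Non-binary input is rejected.
    """
    try:
        dtree = dendropy.Tree.get(data=text, **_DENDROPY_KW)
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise TreeError(f"Newick parse error: {exc}") from None

    counter = [0]

    def convert(dnode) -> Node:
        node = Node(counter[0])
        counter[0] += 1
        kids = dnode.child_nodes()
        if not kids:
            if not dnode.label:
                raise TreeError("leaf without a label")
            node.label = dnode.label
        elif len(kids) == 2:
            for k in kids:
                child = convert(k)
                child.parent = node
                node.children.append(child)
        else:
            raise TreeError(
                f"non-binary tree: internal node with {len(kids)} children"
            )
        return node

    return Tree(convert(dtree.seed_node))


def parse_newick_file(path) -> list[Tree]:
    """Parse a file with one Newick tree per line (blank lines skipped)."""
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(parse_newick(line))
            except TreeError as exc:
                raise TreeError(f"{path}:{lineno}: {exc}") from None
    return trees


def write_newick(t: Tree) -> str:
    """Serialize to Newick with no branch lengths; child order as stored."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return node.label  # type: ignore[return-value]
        return "(" + ",".join(fmt(c) for c in node.children) + ")"

    return fmt(t.root) + ";"


def tree_from_nested(spec) -> Tree:
    """Build a tree from nested 2-tuples/lists of leaf labels.

    ``tree_from_nested((("A", "B"), "C"))`` is the tree ``((A,B),C);``.
    Convenient for tests and programmatic construction.
    """
    counter = [0]

    def build(item) -> Node:
        node = Node(counter[0])
        counter[0] += 1
        if isinstance(item, str):
            node.label = item
        else:
            if len(item) != 2:
                raise TreeError("nested spec must be binary")
            for sub in item:
                child = build(sub)
                child.parent = node
                node.children.append(child)
        return node

    return Tree(build(spec))


# ---------------------------------------------------------------------------
# Isomorphism
# ---------------------------------------------------------------------------

def _canonical_key(node: Node):
    if node.is_leaf:
        return (0, node.label)
    a = _canonical_key(node.children[0])
    b = _canonical_key(node.children[1])
    return (1, a, b) if a <= b else (1, b, a)


def is_isomorphic(t1: Tree, t2: Tree) -> bool:
    """True iff the trees match vertex-for-vertex over identical leaf
    multisets, ignoring child order."""
    return _canonical_key(t1.root) == _canonical_key(t2.root)


# ---------------------------------------------------------------------------
# Constant-time LCA / depth queries (Euler tour + sparse table)
# ---------------------------------------------------------------------------

class LCAIndex:
    """O(1) least-common-ancestor and depth queries after O(n log n) setup.

    Classic reduction: the LCA of u and v is the minimum-depth vertex on the
    Euler tour between the first occurrences of u and v; range-minimum is
    answered by a sparse table of doubling windows.
    """

    def __init__(self, tree: Tree):
        self.tree = tree
        tour: list[Node] = []
        depth_of: dict[int, int] = {tree.root.id: 0}
        first: dict[int, int] = {}
        stack: list[list] = [[tree.root, 0]]
        while stack:
            node, child_idx = stack[-1]
            if node.id not in first:
                first[node.id] = len(tour)
            tour.append(node)
            if child_idx < len(node.children):
                stack[-1][1] += 1
                child = node.children[child_idx]
                depth_of[child.id] = len(stack)
                stack.append([child, 0])
            else:
                stack.pop()

        self._tour = tour
        self._first = first
        self._depth = depth_of
        d = np.array([depth_of[n.id] for n in tour], dtype=np.int64)
        self._d = d
        m = len(tour)
        levels = max(1, m.bit_length())
        sp = np.zeros((levels, m), dtype=np.int64)
        sp[0] = np.arange(m)
        for k in range(1, levels):
            half = 1 << (k - 1)
            span = m - (1 << k) + 1
            if span <= 0:
                break
            left = sp[k - 1, :span]
            right = sp[k - 1, half:span + half]
            sp[k, :span] = np.where(d[left] <= d[right], left, right)
        self._sp = sp

    def depth(self, v: Node) -> int:
        """Edges from the root (depth(root) = 0)."""
        return self._depth[v.id]

    def lca(self, u: Node, v: Node) -> Node:
        i = self._first[u.id]
        j = self._first[v.id]
        if i > j:
            i, j = j, i
        k = (j - i + 1).bit_length() - 1
        a = self._sp[k, i]
        b = self._sp[k, j - (1 << k) + 1]
        d = self._d
        return self._tour[a if d[a] <= d[b] else b]

    def distance(self, u: Node, v: Node) -> int:
        """Number of edges on the path between u and v."""
        w = self.lca(u, v)
        return self._depth[u.id] + self._depth[v.id] - 2 * self._depth[w.id]


def build_lca_index(t: Tree) -> LCAIndex:
    """Preprocess ``t`` for constant-time LCA/depth/distance queries."""
    return LCAIndex(t)
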