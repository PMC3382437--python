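"""Shared fixtures and brute-force helpers for the test suite.

The helpers here (ancestor-walk LCA, exhaustive topology enumeration) are
deliberately naive re-implementations used as oracles; they must stay
independent of the package's fast code paths.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import strategies as st

from treemend import Node, Tree, parse_newick, tree_from_nested


# ---------------------------------------------------------------------------
# naive oracles
# ---------------------------------------------------------------------------

def ancestors(node: Node) -> list[Node]:
    """node and all its ancestors up to the root (naive walk)."""
    out = [node]
    while out[-1].parent is not None:
        out.append(out[-1].parent)
    return out


def naive_lca(u: Node, v: Node) -> Node:
    """Lowest common ancestor by ancestor-set intersection."""
    up = set(id(a) for a in ancestors(u))
    for a in ancestors(v):
        if id(a) in up:
            return a
    raise AssertionError("nodes share no ancestor")


def naive_depth(v: Node) -> int:
    return len(ancestors(v)) - 1


def all_rooted_topologies(labels):
    """Every rooted binary topology over the labels, as nested tuples.

    (2k-3)!! shapes for k labels: 15 for four, 105 for five."""
    labels = list(labels)
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for r in range(len(rest)):
        for extra in itertools.combinations(rest, r):
            left_labels = [first, *extra]
            right_labels = [x for x in rest if x not in extra]
            if not right_labels:
                continue
            for lt in all_rooted_topologies(left_labels):
                for rt in all_rooted_topologies(right_labels):
                    yield (lt, rt)


def random_topology(rng: np.random.Generator, labels) -> Tree:
    """A uniformly random-ish tree by random sequential pair merging."""
    items = list(labels)
    rng.shuffle(items)
    while len(items) > 1:
        i = int(rng.integers(len(items)))
        a = items.pop(i)
        j = int(rng.integers(len(items)))
        b = items.pop(j)
        items.append((a, b))
    return tree_from_nested(items[0])


# ---------------------------------------------------------------------------
# hypothesis strategies
# ---------------------------------------------------------------------------

@st.composite
def nested_topology(draw, min_leaves=2, max_leaves=40, duplicate_labels=False):
    n = draw(st.integers(min_leaves, max_leaves))
    if duplicate_labels:
        pool = [f"t{i:03d}" for i in range(max(2, n // 2))]
        labels = [pool[draw(st.integers(0, len(pool) - 1))] for _ in range(n)]
    else:
        labels = [f"t{i:03d}" for i in range(n)]
    rnd = draw(st.randoms(use_true_random=False))
    items = list(labels)
    rnd.shuffle(items)
    while len(items) > 1:
        a = items.pop(rnd.randrange(len(items)))
        b = items.pop(rnd.randrange(len(items)))
        items.append((a, b))
    return items[0]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def s_abc() -> Tree:
    """The species tree ((A,B),C)."""
    return parse_newick("((A,B),C);")


@pytest.fixture
def g_acb() -> Tree:
    """The misplaced-B gene tree ((A,C),B)."""
    return parse_newick("((A,C),B);")


def leaf(t: Tree, label: str) -> Node:
    """The first leaf carrying ``label`` (preorder)."""
    for lf in t.leaves():
        if lf.label == label:
            return lf
    raise AssertionError(f"no leaf {label!r}")
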