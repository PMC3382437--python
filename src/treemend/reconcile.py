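"""LCA mapping of a gene tree into a species tree and reconciliation costs.

Three classic event-count models measure the incongruence between a gene tree
G and a species tree S once every gene-tree vertex is mapped to the most
recent species vertex that could have contained it (the LCA mapping M):

* duplication (D): a vertex g is a duplication if M(g) equals the image of
  one of its children; the cost is the number of duplications.
* duplication-loss (DL): duplications plus losses, where the losses charged
  at g count the edges skipped between M(g) and its children's images
  (each gap of length d contributes |d - 1| losses, or 0 when both children
  map to M(g) itself).
* deep coalescence (DC): the number of extra gene lineages that persist
  through species-tree edges; per vertex it is the total path length from
  M(g) down to its children's images, and the tree-level cost subtracts
  |E(S)| so that a congruent one-copy gene tree scores 0.

All costs are exact integers.  Before any cost is computed the species tree
is restricted to the species actually present in the gene tree, so that
under-sampled gene families are charged no phantom events.
"""
from __future__ import annotations

from enum import Enum

from .treekit import LCAIndex, Node, Tree, TreeError, build_lca_index


class CostModel(str, Enum):
    """Which reconciliation cost to optimize."""

    DUP = "dup"
    DUPLOSS = "duploss"
    DEEPCOAL = "deepcoal"

    @classmethod
    def coerce(cls, value) -> "CostModel":
        if isinstance(value, cls):
            return value
        aliases = {
            "d": cls.DUP, "dup": cls.DUP, "duplication": cls.DUP,
            "dl": cls.DUPLOSS, "duploss": cls.DUPLOSS,
            "duplication-loss": cls.DUPLOSS,
            "dc": cls.DEEPCOAL, "deepcoal": cls.DEEPCOAL,
            "deep-coalescence": cls.DEEPCOAL,
        }
        try:
            return aliases[str(value).lower()]
        except KeyError:
            raise ValueError(f"unknown cost model: {value!r}") from None


ALL_MODELS = (CostModel.DUP, CostModel.DUPLOSS, CostModel.DEEPCOAL)


class ReconcileError(ValueError):
    """Gene and species tree cannot be reconciled (label mismatch etc.)."""


def resolve_label(label: str, species_delimiter: str | None = None) -> str:
    """Map a gene leaf label to its species label.

    By default the gene label *is* the species label; with a delimiter, the
    prefix before its first occurrence is used (``"spec3_g12" -> "spec3"``).
    """
    if species_delimiter and species_delimiter in label:
        return label.split(species_delimiter, 1)[0]
    return label


def gene_species_labels(g: Tree, species_delimiter: str | None = None) -> set[str]:
    """The set of species sampled in the gene tree."""
    return {resolve_label(l, species_delimiter) for l in g.leaf_labels()}


def restrict_species_tree(s: Tree, labels) -> Tree:
    """Restriction of ``s`` to the named leaves, degree-two vertices suppressed.

    Surviving nodes keep their ids.  Raises ReconcileError for unknown labels.
    """
    labels = set(labels)
    if not labels:
        raise ReconcileError("cannot restrict to an empty label set")
    known = set(s.leaf_labels())
    unknown = labels - known
    if unknown:
        raise ReconcileError(
            "species not in tree: " + ", ".join(sorted(unknown))
        )

    def build(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in labels:
                return Node(node.id, node.label)
            return None
        kept = [k for k in (build(c) for c in node.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = Node(node.id)
        for k in kept:
            k.parent = new
            new.children.append(k)
        return new

    root = build(s.root)
    assert root is not None
    return Tree(root)


class LCAMapping:
    """The mapping M from gene-tree vertices to species-tree vertices.

    Leaves map to the species leaf with the matching (resolved) label; every
    internal vertex maps to the species-tree LCA of its children's images.
    """

    __slots__ = ("gene", "species", "map", "species_index")

    def __init__(self, gene: Tree, species: Tree, mapping: dict[int, Node],
                 species_index: LCAIndex):
        self.gene = gene
        self.species = species
        self.map = mapping          # gene node id -> species Node
        self.species_index = species_index

    def of(self, g: Node) -> Node:
        return self.map[g.id]


def lca_mapping(g: Tree, s: Tree, species_index: LCAIndex | None = None,
                species_delimiter: str | None = None) -> LCAMapping:
    """Compute the LCA mapping of ``g`` into ``s`` bottom-up.

    ``s`` is used as given (restrict first for under-sampled families).
    Linear in |V(G)| after LCA preprocessing of the species tree.
    """
    if species_index is None:
        species_index = build_lca_index(s)
    by_label: dict[str, Node] = {}
    for leaf in s.leaves():
        if leaf.label in by_label:
            raise ReconcileError(f"duplicate species label: {leaf.label}")
        by_label[leaf.label] = leaf

    mapping: dict[int, Node] = {}
    lca = species_index.lca
    for node in g.postorder():
        if node.is_leaf:
            label = resolve_label(node.label, species_delimiter)
            try:
                mapping[node.id] = by_label[label]
            except KeyError:
                raise ReconcileError(
                    f"incomparable trees: gene leaf label {label!r} "
                    "not found among species"
                ) from None
        else:
            c1, c2 = node.children
            mapping[node.id] = lca(mapping[c1.id], mapping[c2.id])
    return LCAMapping(g, s, mapping, species_index)


def score_vertex(model: CostModel, idx: LCAIndex,
                 mg: Node, mc1: Node, mc2: Node) -> int:
    """Per-vertex cost given the images of a vertex and its two children.

    Constant time: the images are comparable (mg is an ancestor-or-self of
    both children's images), so path lengths are depth differences.
    """
    if model is CostModel.DUP:
        return 1 if (mc1 is mg or mc2 is mg) else 0
    dg = idx.depth(mg)
    if model is CostModel.DUPLOSS:
        if mc1 is mg and mc2 is mg:
            loss = 0
        else:
            loss = abs(idx.depth(mc1) - dg - 1) + abs(idx.depth(mc2) - dg - 1)
        return loss + (1 if (mc1 is mg or mc2 is mg) else 0)
    # deep coalescence: lineages from g to its children
    return (idx.depth(mc1) - dg) + (idx.depth(mc2) - dg)


def vertex_score(m: LCAMapping, g: Node, model) -> int:
    """C(G, S, g): the cost contribution of internal gene vertex ``g``."""
    model = CostModel.coerce(model)
    if g.is_leaf:
        raise ValueError("vertex_score is defined for internal vertices only")
    c1, c2 = g.children
    return score_vertex(model, m.species_index,
                        m.map[g.id], m.map[c1.id], m.map[c2.id])


def prepare_species(s: Tree, g: Tree,
                    species_delimiter: str | None = None) -> tuple[Tree, LCAIndex]:
    """Restrict ``s`` to the species sampled in ``g`` and index it for LCA."""
    s_eff = restrict_species_tree(s, gene_species_labels(g, species_delimiter))
    return s_eff, build_lca_index(s_eff)


def reconciliation_cost(g: Tree, s: Tree, model,
                        species_delimiter: str | None = None,
                        species_index: LCAIndex | None = None) -> int:
    """Total reconciliation cost from ``g`` to ``s`` under ``model``.

    If ``species_index`` is given, ``s`` is taken to be already restricted to
    the gene tree's species (a reuse hook for scoring many gene trees or
    neighborhoods against one species tree); otherwise the restriction is
    applied here.
    """
    model = CostModel.coerce(model)
    if species_index is None:
        s, species_index = prepare_species(s, g, species_delimiter)
    m = lca_mapping(g, s, species_index, species_delimiter)
    total = 0
    mp = m.map
    for node in g.postorder():
        if node.is_leaf:
            continue
        c1, c2 = node.children
        total += score_vertex(model, species_index,
                              mp[node.id], mp[c1.id], mp[c2.id])
    if model is CostModel.DEEPCOAL:
        total -= len(s) - 1  # |E(S_effective)|
    return total
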