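"""LCA mapping and the duplication / duplication-loss / deep-coalescence costs."""
import numpy as np
import pytest
from hypothesis import given, settings

from treemend import (
    ALL_MODELS,
    CostModel,
    ReconcileError,
    build_lca_index,
    is_isomorphic,
    lca_mapping,
    parse_newick,
    reconciliation_cost,
    restrict_species_tree,
    tree_from_nested,
    vertex_score,
    write_newick,
)
from conftest import all_rooted_topologies, naive_lca, nested_topology, leaf


class TestRestriction:
    @pytest.mark.parametrize("labels,expect", [
        ({"A", "B"}, "(A,B);"),
        ({"A", "C"}, "(A,C);"),
        ({"A", "B", "C"}, "((A,B),C);"),
        ({"C"}, "C;"),
    ])
    def test_examples(self, labels, expect):
        s = parse_newick("((A,B),C);")
        assert is_isomorphic(restrict_species_tree(s, labels),
                             parse_newick(expect))

    def test_unknown_label_raises(self):
        with pytest.raises(ReconcileError, match="species not in tree: X"):
            restrict_species_tree(parse_newick("((A,B),C);"), {"A", "X"})

    def test_surviving_ids_kept(self):
        s = parse_newick("(((A,B),C),D);")
        r = restrict_species_tree(s, {"A", "D"})
        original_ids = {n.label: n.id for n in s.leaves()}
        assert {n.label: n.id for n in r.leaves()} == {
            "A": original_ids["A"], "D": original_ids["D"]}


class TestLCAMapping:
    def test_worked_example(self, g_acb, s_abc):
        m = lca_mapping(g_acb, s_abc)
        ac = leaf(g_acb, "A").parent
        assert m.of(ac) is s_abc.root
        assert m.of(g_acb.root) is s_abc.root
        assert m.of(leaf(g_acb, "B")).label == "B"

    def test_identity_mapping_for_congruent_trees(self):
        s = parse_newick("((A,(B,C)),(D,E));")
        g = parse_newick("((A,(B,C)),(D,E));")
        m = lca_mapping(g, s)
        for gn in g.preorder():
            assert sorted(lf.label for lf in g.subtree_nodes(gn) if lf.is_leaf) \
                == sorted(lf.label for lf in s.subtree_nodes(m.of(gn)) if lf.is_leaf)

    def test_multicopy_after_restriction(self):
        g = parse_newick("((A,A),B);")
        s_eff = restrict_species_tree(parse_newick("((A,B),C);"), {"A", "B"})
        m = lca_mapping(g, s_eff)
        assert m.of(leaf(g, "A").parent).label == "A"
        assert m.of(g.root) is s_eff.root

    def test_matches_naive_lca_of_leaf_images(self):
        """M(g) is the species LCA of the images of g's leaves (by definition,
        but here checked against the ancestor-walk LCA on random instances)."""
        rng = np.random.default_rng(11)
        from conftest import random_topology
        for rep in range(10):
            labels = [f"s{i}" for i in range(int(rng.integers(3, 10)))]
            s = random_topology(rng, labels)
            g = random_topology(rng, labels + labels[:2])
            m = lca_mapping(g, s)
            s_leaf = {lf.label: lf for lf in s.leaves()}
            for gn in g.preorder():
                images = [s_leaf[lf.label] for lf in g.subtree_nodes(gn)
                          if lf.is_leaf]
                expect = images[0]
                for im in images[1:]:
                    expect = naive_lca(expect, im)
                assert m.of(gn) is expect

    def test_monotone_along_gene_tree(self):
        rng = np.random.default_rng(12)
        from conftest import random_topology
        labels = [f"s{i}" for i in range(8)]
        s = random_topology(rng, labels)
        g = random_topology(rng, labels)
        m = lca_mapping(g, s)
        idx = m.species_index
        for gn in g.preorder():
            if gn.parent is not None:
                assert idx.lca(m.of(gn), m.of(gn.parent)) is m.of(gn.parent)

    def test_unmappable_label_raises(self):
        with pytest.raises(ReconcileError, match="incomparable.*X"):
            lca_mapping(parse_newick("(A,X);"), parse_newick("((A,B),C);"))

    def test_species_delimiter_resolution(self):
        g = parse_newick("((A_g1,C_g2),B_g1);")
        s = parse_newick("((A,B),C);")
        assert reconciliation_cost(g, s, "dup", species_delimiter="_") == 1


class TestVertexScore:
    def test_worked_instance_root(self, g_acb, s_abc):
        m = lca_mapping(g_acb, s_abc)
        g = g_acb.root
        assert vertex_score(m, g, "dup") == 1
        assert vertex_score(m, g, "duploss") == 3   # dup + |0-1| + |2-1|
        assert vertex_score(m, g, "deepcoal") == 2

    def test_worked_instance_internal(self, g_acb, s_abc):
        m = lca_mapping(g_acb, s_abc)
        ac = leaf(g_acb, "A").parent
        assert vertex_score(m, ac, "dup") == 0
        assert vertex_score(m, ac, "duploss") == 1
        assert vertex_score(m, ac, "deepcoal") == 3

    def test_children_mapping_equal_case(self):
        g = parse_newick("((A,A),B);")
        s_eff = restrict_species_tree(parse_newick("((A,B),C);"), {"A", "B"})
        m = lca_mapping(g, s_eff)
        cherry = leaf(g, "A").parent
        assert vertex_score(m, cherry, "dup") == 1
        assert vertex_score(m, cherry, "duploss") == 1   # loss part is 0
        assert vertex_score(m, cherry, "deepcoal") == 0

    def test_leaf_rejected(self, g_acb, s_abc):
        m = lca_mapping(g_acb, s_abc)
        with pytest.raises(ValueError):
            vertex_score(m, leaf(g_acb, "A"), "dup")


class TestReconciliationCost:
    def test_worked_totals(self, g_acb, s_abc):
        assert reconciliation_cost(g_acb, s_abc, "dup") == 1
        assert reconciliation_cost(g_acb, s_abc, "duploss") == 4
        assert reconciliation_cost(g_acb, s_abc, "deepcoal") == 1

    def test_congruent_is_free(self):
        s = parse_newick("(((A,B),(C,D)),(E,F));")
        for model in ALL_MODELS:
            assert reconciliation_cost(s.copy(), s, model) == 0

    def test_undersampled_multicopy(self):
        g = parse_newick("((A,A),B);")
        s = parse_newick("((A,B),C);")
        assert reconciliation_cost(g, s, "dup") == 1
        assert reconciliation_cost(g, s, "duploss") == 1
        assert reconciliation_cost(g, s, "deepcoal") == 0

    def test_total_is_sum_of_vertex_scores(self):
        """The per-vertex decomposition must be exact (it is what makes
        constant-time deltas possible)."""
        rng = np.random.default_rng(5)
        from conftest import random_topology, ancestors
        from treemend.reconcile import prepare_species
        labels = [f"s{i}" for i in range(9)]
        s = random_topology(rng, labels)
        g = random_topology(rng, labels + labels[:3])
        s_eff, idx = prepare_species(s, g)
        m = lca_mapping(g, s_eff, idx)
        for model in ALL_MODELS:
            total = sum(vertex_score(m, n, model)
                        for n in g.preorder() if not n.is_leaf)
            if model is CostModel.DEEPCOAL:
                total -= len(s_eff) - 1
            assert total == reconciliation_cost(g, s, model)

    def test_duploss_dominates_dup(self):
        rng = np.random.default_rng(6)
        from conftest import random_topology
        for rep in range(20):
            labels = [f"s{i}" for i in range(int(rng.integers(3, 9)))]
            s = random_topology(rng, labels)
            g = random_topology(rng, labels + labels[:rep % 3])
            assert reconciliation_cost(g, s, "duploss") >= \
                reconciliation_cost(g, s, "dup")

    def test_zero_iff_congruent_exhaustive(self):
        """On all 4- and 5-leaf one-copy instances, every model is zero
        exactly when gene and species topologies are isomorphic."""
        for labels in (["A", "B", "C", "D"], ["A", "B", "C", "D", "E"]):
            shapes = [tree_from_nested(t) for t in all_rooted_topologies(labels)]
            s = shapes[0]
            for g in shapes:
                congruent = is_isomorphic(g, s)
                for model in ALL_MODELS:
                    cost = reconciliation_cost(g, s, model)
                    assert (cost == 0) is congruent, (
                        write_newick(g), model)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(nested_topology(min_leaves=3, max_leaves=12, duplicate_labels=True))
    def test_cost_invariant_under_child_order(self, spec):
        g = tree_from_nested(spec)
        labels = sorted(set(g.leaf_labels()))
        if len(labels) < 2:
            return
        rng = np.random.default_rng(3)
        from conftest import random_topology
        s = random_topology(rng, labels)
        # mirror every internal node of both trees
        g2 = g.copy()
        for n in g2.preorder():
            n.children.reverse()
        s2 = s.copy()
        for n in s2.preorder():
            n.children.reverse()
        for model in ALL_MODELS:
            assert reconciliation_cost(g, s, model) == \
                reconciliation_cost(g2, s2, model)
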