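"""Newick parsing, queries and serialization."""

import dendropy
import pytest
from hypothesis import given, settings, strategies as st

import topophylo as tp
from topophylo.tree_io import NewickError


class TestParse:
    def test_smallest_tree(self):
        t = tp.parse_newick("(A:1,B:2);")
        assert [l.name for l in t.leaves] == ["A", "B"]
        assert all(l.depth == 1 for l in t.leaves)
        assert t.total_length == pytest.approx(3.0)

    def test_internal_numeric_label_is_support(self):
        t = tp.parse_newick("((A:1,B:1)95:0.5,C:2);")
        internal = t.root.children[0]
        assert internal.support == 95
        assert internal.name == ""
        assert t.max_depth == 2

    def test_polytomy_passes_through(self):
        t = tp.parse_newick("((A:1,B:1,C:1):1,D:2);")
        assert t.n_leaves == 4
        assert len(t.root.children[0].children) == 3

    def test_missing_lengths_get_default(self):
        t = tp.parse_newick("((A,B),C);", default_branch_length=2.5)
        assert t.total_length == pytest.approx(4 * 2.5)

    def test_quoted_label_is_name_even_if_numeric(self):
        t = tp.parse_newick("((A:1,B:1)'42':1,C:1);")
        internal = t.root.children[0]
        assert internal.name == "42"
        assert internal.support is None

    def test_basal_trifurcation_kept_as_root(self):
        t = tp.parse_newick("(A:1,B:1,C:1);")
        assert len(t.root.children) == 3
        assert t.max_depth == 1

    def test_ids_are_stable_preorder(self):
        t = tp.parse_newick("((A:1,B:1):1,C:1);")
        assert t.root.id == 0
        assert [n.id for n in t.nodes()] == list(range(5))

    @pytest.mark.parametrize(
        "text",
        ["", "   ", "((A,B);", "(A,B));", "(A:-1,B:1);", "(A,B);(C,D);", "(A,B)"],
    )
    def test_malformed_input_raises_with_offset(self, text):
        with pytest.raises(NewickError) as exc:
            tp.parse_newick(text)
        assert exc.value.offset >= 0
        assert "character" in str(exc.value)


class TestWrite:
    def test_round_trip_smallest(self):
        assert tp.write_newick(tp.parse_newick("(A:1,B:2);")) == "(A:1,B:2);"

    def test_supports_survive_round_trip(self):
        s = "((A:1,B:1)95:0.5,C:2);"
        assert tp.write_newick(tp.parse_newick(s)) == s

    def test_unnamed_internal_nodes_emit_no_label(self):
        out = tp.write_newick(tp.parse_newick("((A:1,B:1):1,C:1);"))
        assert out == "((A:1,B:1):1,C:1);"

    def test_round_trip_preserves_yule_splits(self):
        tree = tp.yule_tree(tp.TreeGenSpec(n_leaves=16, seed=7))
        back = tp.parse_newick(tp.write_newick(tree))
        assert _splits(tree) == _splits(back)
        assert back.total_length == pytest.approx(tree.total_length, rel=1e-5)

    def test_deep_caterpillar_serializes_iteratively(self):
        tree = tp.caterpillar_tree(2000)
        back = tp.parse_newick(tp.write_newick(tree))
        assert back.n_leaves == 2000
        assert back.max_depth == 1999


def _splits(tree):
    """Sorted leaf-name sets of every internal node (topology fingerprint)."""
    out = set()
    for node in tree.nodes():
        if not node.is_leaf:
            names = frozenset(
                l.name for l in tree.leaves
                if node in (l, *l.ancestors())
            )
            out.add(names)
    return out


def test_parse_agrees_with_dendropy_oracle():
    """Topology and branch lengths match an independent Newick reader."""
    text = tp.write_newick(tp.yule_tree(tp.TreeGenSpec(n_leaves=12, seed=3)))
    ours = tp.parse_newick(text)
    ref = dendropy.Tree.get(data=text, schema="newick")
    ref_leaves = {l.taxon.label for l in ref.leaf_node_iter()}
    assert {l.name for l in ours.leaves} == ref_leaves
    ref_total = sum(
        e.length for e in ref.preorder_edge_iter() if e.length is not None
    )
    assert ours.total_length == pytest.approx(ref_total, rel=1e-6)
    # per-leaf root-to-tip distances
    ref_depths = {
        l.taxon.label: l.distance_from_root() for l in ref.leaf_node_iter()
    }
    for leaf in ours.leaves:
        ours_dist = tp.path_length_to_ancestor(leaf, 0)
        assert ours_dist == pytest.approx(ref_depths[leaf.name], rel=1e-6)


class TestQueries:
    def test_mrca_sisters(self, three_leaf_tree):
        a, b, c = three_leaf_tree.leaves
        assert tp.mrca_depth(three_leaf_tree, a, b) == 1

    def test_mrca_root_only(self, three_leaf_tree):
        a, _, c = three_leaf_tree.leaves
        assert tp.mrca_depth(three_leaf_tree, a, c) == 0

    def test_mrca_matches_bruteforce_on_random_pairs(self, yule16):
        """Oracle: max depth over the intersection of ancestor sets."""
        leaves = yule16.leaves
        for i, u in enumerate(leaves):
            for v in leaves[i + 1:]:
                anc_u = {id(a): a.depth for a in (u, *u.ancestors())}
                common = [
                    anc_u[id(a)] for a in (v, *v.ancestors()) if id(a) in anc_u
                ]
                assert tp.mrca_depth(yule16, u, v) == max(common)

    def test_mrca_symmetric(self, yule16):
        u, v = yule16.leaves[0], yule16.leaves[-1]
        assert tp.mrca_depth(yule16, u, v) == tp.mrca_depth(yule16, v, u)

    def test_path_length_examples(self):
        t = tp.parse_newick("((A:1,B:1):2,C:1);")
        a = t.leaves[0]
        assert tp.path_length_to_ancestor(a, 1) == pytest.approx(1.0)
        assert tp.path_length_to_ancestor(a, 0) == pytest.approx(3.0)
        assert tp.path_length_to_ancestor(a, 2) == 0.0

    def test_path_length_monotone_nonincreasing(self, yule16):
        for leaf in yule16.leaves:
            vals = [
                tp.path_length_to_ancestor(leaf, lvl)
                for lvl in range(leaf.depth + 1)
            ]
            assert vals[-1] == 0.0
            assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_level_out_of_range_raises(self, three_leaf_tree):
        with pytest.raises(ValueError):
            tp.path_length_to_ancestor(three_leaf_tree.leaves[0], 99)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 24))
def test_round_trip_property(seed, n):
    tree = tp.yule_tree(tp.TreeGenSpec(n_leaves=n, seed=seed))
    back = tp.parse_newick(tp.write_newick(tree))
    assert _splits(tree) == _splits(back)
    assert back.n_leaves == n
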