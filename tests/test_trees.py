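"""Tree model, newick/nexus I/O, and primitive operations."""

import numpy as np
import pytest

from chronograft.trees import (
    TimeTree,
    TreeParseError,
    TreeSet,
    TreeValidationError,
    bind_at_edge,
    clade_tips,
    is_ultrametric,
    mrca,
    node_ages,
    parse_tree,
    parse_trees,
    prune_to,
    scale_branch_lengths,
)


def ages_by_clade(tree):
    return {
        clade_tips(n): a for n, a in node_ages(tree).items() if not n.is_leaf
    }


class TestParsing:
    def test_minimal_two_tip_tree(self):
        t = parse_tree("(A:1,B:1);")
        assert sorted(t.tip_labels) == ["A", "B"]
        assert all(tip.length == 1.0 for tip in t.tips())

    def test_write_parse_round_trip_random_trees(self, yule_trees):
        for t in yule_trees:
            back = parse_tree(t.write())
            assert ages_by_clade(back) == pytest.approx(ages_by_clade(t), abs=1e-9)

    def test_nexus_translate_table(self):
        text = (
            "#NEXUS\nbegin trees;\n"
            "  translate 1 Homo_sapiens, 2 Pan_troglodytes, 3 Mus_musculus;\n"
            "  tree t1 = ((1:1,2:1):2,3:3);\nend;\n"
        )
        t = parse_tree(text)
        assert sorted(t.tip_labels) == [
            "Homo_sapiens",
            "Mus_musculus",
            "Pan_troglodytes",
        ]
        assert max(node_ages(t).values()) == pytest.approx(3.0)

    def test_malformed_text_raises(self):
        with pytest.raises(TreeParseError):
            parse_tree("((A:1,B:1;")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            parse_tree("(A:1,A:1);")

    def test_multitree_file_order(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("(A:1,B:1);\n((A:1,B:1):1,C:2);\n".replace("C", "B2"))
        with pytest.raises(TreeValidationError):
            parse_trees(str(path))  # differing tip sets must be rejected
        path.write_text("(A:1,B:1);\n(A:2,B:2);\n")
        ts = parse_trees(str(path))
        assert len(ts) == 2
        assert max(node_ages(ts[1]).values()) == pytest.approx(2.0)


class TestNodeAges:
    def test_hand_summed_ages(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        by_clade = ages_by_clade(t)
        assert by_clade[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert by_clade[frozenset({"A", "B", "C"})] == pytest.approx(2.0)
        assert all(a == 0 for n, a in node_ages(t).items() if n.is_leaf)

    def test_scaling_branch_lengths_scales_ages(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        scaled = scale_branch_lengths(t, 3.5)
        a, b = ages_by_clade(t), ages_by_clade(scaled)
        for clade in a:
            assert b[clade] == pytest.approx(3.5 * a[clade])

    def test_ages_monotone_root_to_tip(self, yule_trees):
        for t in yule_trees:
            ages = node_ages(t)
            for node, age in ages.items():
                for child in node.children:
                    assert age > ages[child] - 1e-12

    def test_non_ultrametric_rejected(self):
        with pytest.raises(TreeValidationError, match="spread"):
            node_ages(parse_tree("(A:1,B:2);"))


class TestUltrametric:
    @pytest.mark.parametrize(
        "newick,expected",
        [("(A:1,B:1);", True), ("(A:1,B:2);", False)],
    )
    def test_examples(self, newick, expected):
        assert is_ultrametric(parse_tree(newick), 1e-6) is expected

    def test_zero_depth_tree_is_ultrametric(self):
        assert is_ultrametric(parse_tree("(A:0,B:0);"))


class TestMrca:
    def test_all_tips_gives_root(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        assert mrca(t, {"A", "B", "C"}) is t.root

    def test_singleton_gives_tip(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        assert mrca(t, {"A"}).label == "A"

    def test_unknown_label_named_in_error(self):
        t = parse_tree("(A:1,B:1);")
        with pytest.raises(KeyError, match="Z"):
            mrca(t, {"A", "Z"})

    def test_against_ancestor_set_intersection(self, yule_trees):
        """Exhaustive pairwise check vs a brute-force ancestor-set oracle."""
        for t in yule_trees[:10]:
            ancestors = {}
            for tip in t.tips():
                chain, node = [], tip
                while node is not None:
                    chain.append(node)
                    node = node.parent
                ancestors[tip.label] = chain
            labels = t.tip_labels
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    shared = [n for n in ancestors[a] if n in ancestors[b]]
                    assert mrca(t, {a, b}) is shared[0]


class TestPrune:
    def test_prune_to_all_is_identity(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        p = prune_to(t, set(t.tip_labels))
        assert ages_by_clade(p) == ages_by_clade(t)

    def test_path_sums_after_pruning(self):
        p = prune_to(parse_tree("((A:1,B:1):1,C:2);"), {"A", "C"})
        assert sorted(p.tip_labels) == ["A", "C"]
        assert all(tip.length == pytest.approx(2.0) for tip in p.tips())

    def test_retained_node_ages_unchanged(self, yule_trees):
        for t in yule_trees[:10]:
            keep = set(t.tip_labels[::2])
            pruned = prune_to(t, keep)
            root_unary = len(pruned.root.children) == 1
            for clade, age in ages_by_clade(pruned).items():
                if clade == frozenset(keep) and root_unary:
                    # the retained (unary) root keeps the original root age
                    original = max(node_ages(t).values())
                else:
                    original = node_ages(t)[mrca(t, clade)]
                assert age == pytest.approx(original, abs=1e-9)

    def test_empty_keep_rejected(self):
        with pytest.raises(ValueError):
            prune_to(parse_tree("(A:1,B:1);"), set())


class TestBind:
    def test_hand_construction(self):
        host = parse_tree("(R:10,O:10);")
        graft = parse_tree("(a:6,b:6);")
        out = bind_at_edge(host, graft, "R", 6.0)
        assert sorted(out.tip_labels) == ["O", "a", "b"]
        by_clade = ages_by_clade(out)
        assert by_clade[frozenset({"a", "b"})] == pytest.approx(6.0)
        assert by_clade[frozenset({"O", "a", "b"})] == pytest.approx(10.0)
        assert is_ultrametric(out)

    def test_tip_count_bookkeeping(self):
        host = parse_tree("((R:10,O:10):5,Z:15);")
        graft = parse_tree("((a:3,b:3):3,c:6);")
        out = bind_at_edge(host, graft, "R", 6.0)
        assert out.n_tips == host.n_tips - 1 + graft.n_tips

    def test_attach_outside_pendant_edge_rejected(self):
        host = parse_tree("((R:10,O:10):5,Z:15);")
        graft = parse_tree("(a:6,b:6);")
        with pytest.raises(TreeValidationError, match="negative-branch"):
            bind_at_edge(host, graft, "R", 12.0)

    def test_bind_then_prune_round_trip(self):
        host = parse_tree("((R:10,O:10):5,Z:15);")
        graft = parse_tree("(a:6,b:6);")
        out = bind_at_edge(host, graft, "R", 6.0)
        back = prune_to(out, {"a", "O", "Z"})
        back.find_tip("a").label = "R"
        assert ages_by_clade(back) == pytest.approx(ages_by_clade(host))


class TestTreeSet:
    def test_shared_tip_universe_enforced(self):
        t1 = parse_tree("(A:1,B:1);")
        t2 = parse_tree("(A:1,C:1);")
        with pytest.raises(TreeValidationError):
            TreeSet([t1, t2])

    def test_order_is_stable(self):
        trees = [parse_tree(f"(A:{i},B:{i});") for i in (1, 2, 3)]
        ts = TreeSet(trees)
        assert [max(node_ages(t).values()) for t in ts] == [1, 2, 3]
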