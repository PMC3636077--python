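"""Tree I/O and split algebra."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from phyloconcord.treeio import (
    Bipartition,
    NewickParseError,
    TaxonUniverse,
    TreeError,
    are_compatible,
    leaf_set,
    nontrivial_splits,
    parse_newick,
    parse_newick_list,
    parse_nexus_trees,
    restrict_to_taxa,
    tree_from_splits,
    write_newick,
)
from phyloconcord.pd_selection import phylogenetic_diversity

from conftest import all_unrooted_binary_trees, random_tree


def split(members, universe_labels):
    return Bipartition(members, TaxonUniverse(tuple(universe_labels)))


class TestParseNewick:
    def test_basic_tree(self):
        tree = parse_newick("(A:1,B:2,(C:3,D:4):5);")
        assert sorted(tree.leaf_labels()) == ["A", "B", "C", "D"]
        assert len(nontrivial_splits(tree)) == 1

    @pytest.mark.parametrize(
        "bad", ["(A,B;", "", "   ", "((A,B)"]
    )
    def test_malformed_input(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("((A,A),B);")

    def test_branch_lengths_and_supports_preserved(self):
        tree = parse_newick("((A:0.5,B:1.5)75:2.25,C:1,D:3);")
        lengths = {
            n.name: n.length for n in tree.preorder() if n.is_leaf
        }
        assert lengths == {"A": 0.5, "B": 1.5, "C": 1.0, "D": 3.0}
        supports = [n.support for n in tree.internal_nodes(exclude_root=True)]
        assert supports == [75.0]

    def test_quoted_and_underscore_labels(self):
        tree = parse_newick("('Escherichia coli',Bacillus_subtilis,(X,Y));")
        labels = set(tree.leaf_labels())
        assert "Escherichia coli" in labels
        assert "Bacillus_subtilis" in labels

    def test_multi_tree_file_and_bad_statement_index(self):
        trees = parse_newick_list("(A,B,(C,D));\n\n(A,(B,(C,D)));\n")
        assert len(trees) == 2
        with pytest.raises(NewickParseError, match="statement 2"):
            parse_newick_list("(A,B,(C,D));\n(A,B;\n")

    def test_nexus_translate_table_resolved(self):
        text = (
            "#NEXUS\nbegin trees;\n"
            "translate 1 Alpha, 2 Beta, 3 Gamma, 4 Delta;\n"
            "tree one = ((1,2),(3,4));\n"
            "end;\n"
        )
        (tree,) = parse_nexus_trees(text)
        assert sorted(tree.leaf_labels()) == ["Alpha", "Beta", "Delta", "Gamma"]


class TestWriteNewick:
    def test_star_tree_without_lengths(self):
        tree = parse_newick("(A,B,C);")
        assert write_newick(tree) == "(A,B,C);"

    def test_length_written(self):
        assert ":0.5" in write_newick(parse_newick("(A:0.5,B,C);"))

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_preserves_splits_and_lengths(self, seed):
        tree = random_tree(seed, n_taxa=20, collapse=0.3 if seed % 2 else 0.0)
        back = parse_newick(write_newick(tree))
        assert nontrivial_splits(back) == nontrivial_splits(tree)
        original = sorted(
            n.length for n in tree.preorder() if n is not tree.root
        )
        recovered = sorted(
            n.length for n in back.preorder() if n is not back.root
        )
        assert recovered == pytest.approx(original)


class TestSplits:
    def test_leaf_set(self):
        assert leaf_set(parse_newick("(A,(B,C));")).labels == ("A", "B", "C")

    def test_resolved_tree_has_n_minus_3(self):
        tree = parse_newick("(((((A,B),C),D),E),F);")
        assert len(nontrivial_splits(tree)) == 3

    def test_star_tree_has_none(self):
        assert nontrivial_splits(parse_newick("(A,B,C,D,E);")) == set()

    def test_hand_enumerated_splits(self):
        tree = parse_newick("((A,B),(C,D),(E,F));")
        uni = leaf_set(tree)
        expected = {
            Bipartition({"A", "B"}, uni),
            Bipartition({"C", "D"}, uni),
            Bipartition({"E", "F"}, uni),
        }
        assert nontrivial_splits(tree) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_split_count_bounded_by_n_minus_3(self, seed):
        tree = random_tree(seed, n_taxa=15, collapse=0.4)
        assert len(nontrivial_splits(tree)) <= 15 - 3


class TestCompatibility:
    UNI = ("A", "B", "C", "D", "E")

    def test_nested_clades_compatible(self):
        assert are_compatible(
            split({"A", "B"}, self.UNI), split({"A", "B", "C"}, self.UNI)
        )

    def test_overlapping_clades_incompatible(self):
        assert not are_compatible(
            split({"A", "B"}, self.UNI), split({"B", "C"}, self.UNI)
        )

    def test_self_compatible(self):
        s = split({"A", "B"}, self.UNI)
        assert are_compatible(s, s)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(TreeError):
            are_compatible(
                split({"A", "B"}, self.UNI), split({"A", "B"}, ("A", "B", "C", "D"))
            )

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_agrees_with_co_occurrence_in_some_tree(self, n):
        """Two splits are compatible iff some binary tree contains both
        (checked by exhaustive enumeration of all topologies)."""
        labels = tuple("ABCDEFG"[:n])
        universe = TaxonUniverse(labels)
        trees = all_unrooted_binary_trees(labels)
        split_sets = [nontrivial_splits(t) for t in trees]
        all_splits = sorted(
            {s for ss in split_sets for s in ss},
            key=lambda s: sorted(s.members),
        )
        for s1, s2 in itertools.combinations_with_replacement(all_splits, 2):
            co_occur = any(s1 in ss and s2 in ss for ss in split_sets)
            assert are_compatible(s1, s2) == co_occur


class TestTreeFromSplits:
    def test_empty_set_gives_star(self):
        uni = TaxonUniverse(("A", "B", "C", "D", "E"))
        tree = tree_from_splits([], uni)
        assert nontrivial_splits(tree) == set()
        assert sorted(tree.leaf_labels()) == list(uni.labels)

    def test_inverts_split_extraction_on_resolved_tree(self):
        tree = parse_newick("(((A,B),C),((D,E),F));")
        splits = nontrivial_splits(tree)
        rebuilt = tree_from_splits(splits, leaf_set(tree))
        assert nontrivial_splits(rebuilt) == splits

    def test_incompatible_pair_rejected(self):
        uni = ("A", "B", "C", "D", "E")
        with pytest.raises(TreeError, match="incompatible"):
            tree_from_splits(
                [split({"A", "B"}, uni), split({"B", "C"}, uni)],
                TaxonUniverse(uni),
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_identity_on_arbitrary_topologies(self, seed):
        tree = random_tree(seed, n_taxa=12, collapse=0.3)
        splits = nontrivial_splits(tree)
        rebuilt = tree_from_splits(splits, leaf_set(tree))
        assert nontrivial_splits(rebuilt) == splits


class TestRestrictToTaxa:
    def test_pair_restriction_gives_path_length(self):
        tree = parse_newick("(A:1,B:2,(C:3,D:4):5);")
        sub = restrict_to_taxa(tree, ["C", "D"])
        assert sorted(sub.leaf_labels()) == ["C", "D"]
        assert sub.total_length() == pytest.approx(7.0)

    def test_restriction_to_all_leaves_is_identity(self):
        tree = random_tree(3, n_taxa=10)
        sub = restrict_to_taxa(tree, sorted(tree.leaf_labels()))
        assert nontrivial_splits(sub) == nontrivial_splits(tree)

    def test_unknown_label_rejected(self):
        with pytest.raises(TreeError, match="not in tree"):
            restrict_to_taxa(parse_newick("(A,B,(C,D));"), ["A", "Z"])

    @pytest.mark.parametrize("seed", range(6))
    def test_pd_preserved_under_restriction(self, seed):
        """PD of a leaf subset equals the total length of the tree
        restricted to that subset (cross-check of the two computations)."""
        tree = random_tree(seed, n_taxa=10)
        labels = sorted(tree.leaf_labels())[:5]
        sub = restrict_to_taxa(tree, labels)
        assert sub.total_length() == pytest.approx(
            phylogenetic_diversity(tree, labels)
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_splits_are_restrictions_of_original(self, seed):
        tree = random_tree(seed, n_taxa=12)
        keep = sorted(tree.leaf_labels())[:7]
        sub = restrict_to_taxa(tree, keep)
        sub_uni = leaf_set(sub)
        keep_set = set(keep)
        expected = set()
        for s in nontrivial_splits(tree):
            side = s.members & keep_set
            if 2 <= len(side) <= len(keep) - 2:
                expected.add(Bipartition(side, sub_uni))
        assert nontrivial_splits(sub) == expected


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(4, 30))
def test_round_trip_property(seed, n):
    """Newick serialization round-trips split sets for arbitrary random trees."""
    tree = random_tree(seed, n_taxa=n)
    assert nontrivial_splits(parse_newick(write_newick(tree))) == nontrivial_splits(
        tree
    )
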