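"""Split frequencies, concordance factors, and the primary concordance tree."""

import pytest

from phyloconcord.concordance import (
    ConcordanceError,
    ConcordanceTable,
    TreeSample,
    concordance_factors,
    primary_concordance_tree,
    read_tree_sample,
    split_frequencies,
)
from phyloconcord.synthetic_data import (
    simulate_gene_trees,
    simulate_replicate_sample,
    simulate_species_tree,
)
from phyloconcord.treecompare import majority_rule_consensus, rf_distance
from phyloconcord.treeio import (
    Bipartition,
    TaxonUniverse,
    leaf_set,
    nontrivial_splits,
    parse_newick,
)

T1 = "((A,B),(C,D),E);"
T2 = "((A,C),(B,D),E);"


class TestReadTreeSample:
    def test_newick_per_line(self):
        sample = read_tree_sample(f"{T1}\n{T1}\n{T2}\n", gene="g1")
        assert sample.size == 3
        assert sample.universe.labels == ("A", "B", "C", "D", "E")

    def test_nexus_with_translate(self):
        text = (
            "#NEXUS\nbegin trees;\n"
            "translate 1 A, 2 B, 3 C, 4 D;\n"
            "tree a = ((1,2),(3,4));\n"
            "tree b = ((1,3),(2,4));\n"
            "end;\n"
        )
        sample = read_tree_sample(text, gene="g1")
        assert sample.size == 2
        assert sample.universe.labels == ("A", "B", "C", "D")

    def test_leafset_mismatch_names_replicate(self):
        with pytest.raises(ConcordanceError, match="replicate 3"):
            read_tree_sample(f"{T1}\n{T1}\n((A,B),(C,F),E);\n", gene="g1")


class TestSplitFrequencies:
    def test_identical_resolved_trees_all_one(self):
        sample = read_tree_sample(f"{T1}\n" * 4, gene="g")
        table = split_frequencies(sample)
        assert set(table.frequencies.values()) == {1.0}
        assert len(table.frequencies) == 2

    def test_mixed_sample_exact_fractions(self):
        sample = read_tree_sample(f"{T1}\n{T1}\n{T2}\n", gene="g")
        table = split_frequencies(sample)
        uni = sample.universe
        assert table.frequencies[Bipartition({"A", "B"}, uni)] == pytest.approx(2 / 3)
        assert table.frequencies[Bipartition({"A", "C"}, uni)] == pytest.approx(1 / 3)

    def test_star_trees_give_empty_table(self):
        sample = read_tree_sample("(A,B,C,D,E);\n(A,B,C,D,E);\n", gene="g")
        assert split_frequencies(sample).frequencies == {}


class TestConcordanceFactors:
    def test_two_of_three_genes_share_a_split(self):
        tables = [
            split_frequencies(read_tree_sample(f"{t}\n", gene=f"g{i}"))
            for i, t in enumerate([T1, T1, T2])
        ]
        cf = concordance_factors(tables)
        uni = tables[0].universe
        assert cf.factors[Bipartition({"A", "B"}, uni)] == pytest.approx(2 / 3)
        assert cf.factors[Bipartition({"A", "C"}, uni)] == pytest.approx(1 / 3)

    def test_identical_genes_give_cf_one_everywhere(self):
        tables = [
            split_frequencies(read_tree_sample(f"{T1}\n{T1}\n", gene=f"g{i}"))
            for i in range(3)
        ]
        cf = concordance_factors(tables)
        assert set(cf.factors.values()) == {1.0}

    def test_mean_of_partial_frequencies(self):
        ta = split_frequencies(
            read_tree_sample(f"{T1}\n{T1}\n{T1}\n{T2}\n{T2}\n", gene="a")
        )
        tb = split_frequencies(read_tree_sample(f"{T2}\n", gene="b"))
        cf = concordance_factors([ta, tb])
        uni = ta.universe
        # gene a: 0.6 for AB|CDE, gene b: 0 -> CF 0.3
        assert cf.factors[Bipartition({"A", "B"}, uni)] == pytest.approx(0.3)

    def test_universe_mismatch_rejected(self):
        ta = split_frequencies(read_tree_sample(f"{T1}\n", gene="a"))
        tb = split_frequencies(
            read_tree_sample("((A,B),(C,F),E);\n", gene="b")
        )
        with pytest.raises(ConcordanceError):
            concordance_factors([ta, tb])


class TestPrimaryConcordanceTree:
    def test_unanimous_genes_reproduce_common_tree(self):
        tables = [
            split_frequencies(read_tree_sample(f"{T1}\n", gene=f"g{i}"))
            for i in range(4)
        ]
        cf = concordance_factors(tables)
        tree = primary_concordance_tree(cf)
        assert nontrivial_splits(tree) == nontrivial_splits(parse_newick(T1))
        supports = [
            n.support for n in tree.internal_nodes(exclude_root=True)
        ]
        assert supports == [1.0, 1.0]

    def test_higher_cf_split_wins_conflict(self):
        tables = [
            split_frequencies(read_tree_sample(f"{t}\n", gene=f"g{i}"))
            for i, t in enumerate([T1, T1, T2])
        ]
        tree = primary_concordance_tree(concordance_factors(tables))
        uni = leaf_set(tree)
        splits = nontrivial_splits(tree)
        assert Bipartition({"A", "B"}, uni) in splits
        assert Bipartition({"A", "C"}, uni) not in splits

    def test_tied_incompatible_splits_all_rejected(self):
        tables = [
            split_frequencies(read_tree_sample(f"{t}\n", gene=f"g{i}"))
            for i, t in enumerate(["((A,B),(C,D));", "((A,C),(B,D));"])
        ]
        tree = primary_concordance_tree(concordance_factors(tables))
        assert nontrivial_splits(tree) == set()

    def test_cf_floor_prunes_weak_splits(self):
        tables = [
            split_frequencies(read_tree_sample(f"{t}\n", gene=f"g{i}"))
            for i, t in enumerate([T1, T1, T2])
        ]
        tree = primary_concordance_tree(
            concordance_factors(tables), cf_floor=0.5
        )
        uni = leaf_set(tree)
        assert nontrivial_splits(tree) == {
            Bipartition({"A", "B"}, uni),
            Bipartition({"C", "D"}, uni),
        }

    def test_accepted_splits_pairwise_compatible_under_noise(self):
        species = simulate_species_tree(12, 3)
        genes = simulate_gene_trees(species, 8, 0.8, 3, seed=4)
        tables = [
            split_frequencies(
                simulate_replicate_sample(g, 100, 9, 50.0, seed=i, label=f"g{i}")
            )
            for i, g in enumerate(genes)
        ]
        tree = primary_concordance_tree(concordance_factors(tables))
        # assembly succeeded; splits of a tree are compatible by construction
        assert len(nontrivial_splits(tree)) <= 12 - 3

    def test_single_gene_floor_half_equals_majority_consensus(self):
        """With one gene, the primary concordance tree at cf_floor 0.5 is the
        majority-rule consensus of that gene's replicate sample."""
        species = simulate_species_tree(10, 8)
        sample = simulate_replicate_sample(species, 100, 25, 60.0, seed=2, label="g")
        pct = primary_concordance_tree(
            concordance_factors([split_frequencies(sample)]), cf_floor=0.5
        )
        consensus = majority_rule_consensus(sample.trees, threshold=0.5)
        assert rf_distance(pct, consensus).raw == 0

    def test_recovery_without_discordance(self):
        species = simulate_species_tree(15, 21)
        genes = simulate_gene_trees(species, 6, 0.0, 1, seed=5)
        tables = [
            split_frequencies(
                simulate_replicate_sample(g, 600, 11, 1.0, seed=i, label=f"g{i}")
            )
            for i, g in enumerate(genes)
        ]
        pct = primary_concordance_tree(concordance_factors(tables))
        assert rf_distance(pct, species).raw == 0

    def test_species_split_cf_declines_with_discordance(self):
        """Mean CF of species-tree splits decreases (in expectation over
        seeds) as the gene-tree discordance probability rises."""
        means = []
        for p in (0.0, 0.4, 0.8):
            acc = 0.0
            for seed in range(20):
                species = simulate_species_tree(10, 100 + seed)
                genes = simulate_gene_trees(species, 12, p, 2, seed=seed)
                tables = [
                    split_frequencies(TreeSample(f"g{i}", [g]))
                    for i, g in enumerate(genes)
                ]
                cf = concordance_factors(tables)
                true_splits = nontrivial_splits(species)
                acc += sum(cf.factors.get(s, 0.0) for s in true_splits) / len(
                    true_splits
                )
            means.append(acc / 20)
        assert means[0] == pytest.approx(1.0)
        assert means[0] > means[1] > means[2]

    def test_floor_out_of_range_rejected(self):
        cf = ConcordanceTable(TaxonUniverse(("A", "B", "C", "D")), {}, 1)
        with pytest.raises(ConcordanceError):
            primary_concordance_tree(cf, cf_floor=1.0)
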