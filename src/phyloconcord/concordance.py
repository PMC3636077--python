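"""Concordance factors and the primary concordance tree.

The supertree side of the pipeline: each gene contributes a sample of trees
(ML bootstrap replicates or posterior draws) over one shared taxon set; the
per-gene frequency of each split is tabulated, and the concordance factor
(CF) of a split is its mean frequency across genes — an estimate of the
proportion of gene trees containing that clade. The primary concordance
tree is assembled greedily: splits ranked by CF from high to low, a split
accepted only if compatible with every higher-ranked accepted split.
Equal-CF splits that conflict with each other are all rejected, so ties in
the evidence surface as polytomies rather than arbitrary resolutions.

The CF estimator here is the independence-limit sample-wide average; the
hierarchical prior over gene-to-tree groupings used by full Bayesian
concordance analysis is deliberately not modelled (empirically its prior
weight barely moves the tree on weak per-gene signal, which is the regime
this pipeline targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .treeio import (
    Bipartition,
    TaxonUniverse,
    Tree,
    TreeError,
    leaf_set,
    nontrivial_splits,
    parse_newick_list,
    parse_nexus_trees,
    tree_from_splits,
)


class ConcordanceError(TreeError):
    """Invalid tree sample or concordance-table operation."""


@dataclass
class TreeSample:
    """An ordered collection of trees on one shared taxon universe."""

    gene: str
    trees: list[Tree]
    universe: TaxonUniverse = field(init=False)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ConcordanceError(f"gene {self.gene!r}: empty tree sample")
        self.universe = leaf_set(self.trees[0])
        for idx, tree in enumerate(self.trees[1:], start=2):
            if leaf_set(tree) != self.universe:
                raise ConcordanceError(
                    f"gene {self.gene!r}: replicate {idx} has a different leaf set"
                )

    @property
    def size(self) -> int:
        return len(self.trees)


@dataclass
class SplitFrequencyTable:
    """Per-gene split frequencies: occurrences / sample size; splits absent
    from the mapping have frequency 0."""

    gene: str
    universe: TaxonUniverse
    frequencies: dict[Bipartition, float]
    sample_size: int


@dataclass
class ConcordanceTable:
    """Across-gene mean split frequencies (concordance factors), zero
    entries omitted; ``per_gene`` retains each gene's frequency for export."""

    universe: TaxonUniverse
    factors: dict[Bipartition, float]
    n_genes: int
    per_gene: dict[Bipartition, dict[str, float]] = field(default_factory=dict)

    def to_tsv(self) -> str:
        genes = sorted({g for row in self.per_gene.values() for g in row})
        header = "split\tcf" + "".join(f"\t{g}" for g in genes)
        lines = [header]
        ordered = sorted(
            self.factors.items(), key=lambda kv: (-kv[1], sorted(kv[0].members))
        )
        for split, cf in ordered:
            row = self.per_gene.get(split, {})
            cells = "".join(f"\t{row.get(g, 0.0):.6g}" for g in genes)
            lines.append(f"{'|'.join(sorted(split.members))}\t{cf:.6g}{cells}")
        return "\n".join(lines) + "\n"


def read_tree_sample(text: str, gene: str) -> TreeSample:
    """Read a multi-tree sample: one Newick per line, or a Nexus trees block
    (detected by a leading ``#NEXUS``) with its translate table resolved."""
    if text.lstrip().lower().startswith("#nexus"):
        trees = parse_nexus_trees(text)
    else:
        trees = parse_newick_list(text)
    return TreeSample(gene, trees)


def split_frequencies(sample: TreeSample) -> SplitFrequencyTable:
    """Exact fraction of the sample's trees containing each nontrivial split."""
    counts: dict[Bipartition, int] = {}
    for tree in sample.trees:
        for split in nontrivial_splits(tree):
            counts[split] = counts.get(split, 0) + 1
    n = sample.size
    return SplitFrequencyTable(
        sample.gene,
        sample.universe,
        {s: c / n for s, c in counts.items()},
        n,
    )


def concordance_factors(
    tables: list[SplitFrequencyTable],
) -> ConcordanceTable:
    """CF(split) = mean over genes of that gene's split frequency (0 where
    absent); replicates are weighted equally within a gene, genes equally
    across genes, regardless of differing sample sizes."""
    if not tables:
        raise ConcordanceError("need at least one gene")
    universe = tables[0].universe
    for t in tables[1:]:
        if t.universe != universe:
            raise ConcordanceError(
                f"gene {t.gene!r} is on a different taxon universe"
            )
    g = len(tables)
    sums: dict[Bipartition, float] = {}
    per_gene: dict[Bipartition, dict[str, float]] = {}
    for t in tables:
        for split, freq in t.frequencies.items():
            sums[split] = sums.get(split, 0.0) + freq
            per_gene.setdefault(split, {})[t.gene] = freq
    factors = {s: total / g for s, total in sums.items() if total > 0}
    return ConcordanceTable(universe, factors, g, per_gene)


def primary_concordance_tree(
    cf: ConcordanceTable,
    universe: TaxonUniverse | None = None,
    cf_floor: float = 0.0,
) -> Tree:
    """Greedy assembly of the primary concordance tree.

    Splits are visited in descending CF order; a split is accepted iff its
    CF is at least ``cf_floor`` and it is compatible with every
    already-accepted split. Splits tied on CF that conflict *with each
    other* are all rejected (the tie resolves to a polytomy). Accepted
    splits are assembled into a tree whose internal nodes carry their CF as
    the node label.
    """
    if universe is None:
        universe = cf.universe
    if not 0.0 <= cf_floor < 1.0:
        raise ConcordanceError("cf_floor must be in [0, 1)")
    from .treeio import are_compatible  # local import avoids cycle at module load

    items = sorted(
        cf.factors.items(), key=lambda kv: (-kv[1], sorted(kv[0].members))
    )
    accepted: list[tuple[Bipartition, float]] = []
    i = 0
    while i < len(items):
        j = i
        value = items[i][1]
        while j < len(items) and items[j][1] == value:
            j += 1
        group = [s for s, _ in items[i:j]]
        i = j
        if value < cf_floor:
            break
        candidates = [
            s
            for s in group
            if all(are_compatible(s, a) for a, _ in accepted)
        ]
        for s in candidates:
            if all(
                are_compatible(s, other) for other in candidates if other is not s
            ):
                accepted.append((s, value))
    tree = tree_from_splits([s for s, _ in accepted], universe)
    cf_by_members = {s.members: v for s, v in accepted}
    # annotate: a created internal node's leaf cluster is a canonical side
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.name,))
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            value = cf_by_members.get(below[id(node)])
            if value is not None:
                node.name = f"{value:.6g}"
    return tree
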