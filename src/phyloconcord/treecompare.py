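"""Tree and tree-sample comparison: Robinson-Foulds distances, consensus,
support distributions, and the alignment-length vs. replicate-variance
correlation.

RF here is the PHYLIP ``treedist`` symmetric distance: the number of
nontrivial unrooted splits present in exactly one of the two trees.
Polytomies are handled natively — an unresolved node simply contributes
fewer splits — and no arbitrary resolution is ever introduced.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .concordance import TreeSample
from .treeio import (
    Tree,
    TreeError,
    leaf_set,
    nontrivial_splits,
    restrict_to_taxa,
    tree_from_splits,
)


class CompareError(TreeError):
    """Invalid tree-comparison request."""


@dataclass(frozen=True)
class RFResult:
    """Split bookkeeping for one tree pair."""

    raw: int
    only_in_first: int
    only_in_second: int
    shared: int
    n_splits_first: int
    n_splits_second: int


def rf_distance(
    t1: Tree, t2: Tree, prune_to_shared: bool = False
) -> RFResult:
    """Symmetric difference of the two trees' nontrivial split sets.

    Leaf sets must match exactly unless ``prune_to_shared`` is set, in which
    case both trees are first restricted to their common taxa (at least 4
    required). Zero iff the unrooted topologies are identical.
    """
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        if not prune_to_shared:
            raise CompareError(
                f"leaf sets differ: only in first {sorted(l1 - l2)[:5]}..., "
                f"only in second {sorted(l2 - l1)[:5]}..."
            )
        shared_taxa = l1 & l2
        if len(shared_taxa) < 4:
            raise CompareError("fewer than 4 shared taxa")
        t1 = restrict_to_taxa(t1, sorted(shared_taxa))
        t2 = restrict_to_taxa(t2, sorted(shared_taxa))
    s1 = nontrivial_splits(t1)
    s2 = nontrivial_splits(t2)
    only1 = len(s1 - s2)
    only2 = len(s2 - s1)
    return RFResult(
        raw=only1 + only2,
        only_in_first=only1,
        only_in_second=only2,
        shared=len(s1 & s2),
        n_splits_first=len(s1),
        n_splits_second=len(s2),
    )


def normalized_rf(
    result: RFResult,
    mode: str = "max_possible",
    reference_splits: Optional[int] = None,
) -> float:
    """RF as a percentage of a denominator: ``max_possible`` uses the sum of
    both trees' split counts; ``reference_splits`` a caller-supplied count
    (no single normalization convention is universal, so both are exposed)."""
    if mode == "max_possible":
        denom = result.n_splits_first + result.n_splits_second
    elif mode == "reference_splits":
        if reference_splits is None:
            raise CompareError("reference_splits required for that mode")
        denom = reference_splits
    else:
        raise CompareError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        raise CompareError("zero denominator for normalized RF")
    return 100.0 * result.raw / denom


def mean_pairwise_rf(
    sample: TreeSample, max_pairs: int = 10_000, seed: int = 0
) -> float:
    """Mean raw RF over unordered replicate pairs; all pairs when their
    count is at most ``max_pairs``, else a seeded uniform pair sample.
    The topological variance of a bootstrap sample in one number."""
    if sample.size < 2:
        raise CompareError("need at least 2 trees")
    split_sets = [nontrivial_splits(t) for t in sample.trees]
    pairs = list(itertools.combinations(range(sample.size), 2))
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    total = 0
    for i, j in pairs:
        total += len(split_sets[i] ^ split_sets[j])
    return total / len(pairs)


def pairwise_rf_tsv(sample: TreeSample) -> str:
    """Full pairwise RF matrix of a sample, for plotting distributions."""
    split_sets = [nontrivial_splits(t) for t in sample.trees]
    n = len(split_sets)
    lines = ["\t" + "\t".join(str(j + 1) for j in range(n))]
    for i in range(n):
        row = [str(len(split_sets[i] ^ split_sets[j])) for j in range(n)]
        lines.append(f"{i + 1}\t" + "\t".join(row))
    return "\n".join(lines) + "\n"


def majority_rule_consensus(
    trees: Sequence[Tree], threshold: float = 0.5
) -> Tree:
    """Consensus containing the splits whose frequency strictly exceeds the
    threshold (at threshold 1.0: the strict consensus, frequency exactly 1).

    The strict ``>`` at 0.5 guarantees the retained splits are pairwise
    compatible, so assembly cannot fail; supports are annotated as
    frequencies on the internal nodes.
    """
    if not trees:
        raise CompareError("need at least one tree")
    if not 0.5 <= threshold <= 1.0:
        raise CompareError("threshold must be in [0.5, 1.0]")
    universe = leaf_set(trees[0])
    counts: dict = {}
    for idx, tree in enumerate(trees, start=1):
        if leaf_set(tree) != universe:
            raise CompareError(f"tree {idx} has a different leaf set")
        for split in nontrivial_splits(tree):
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    if threshold == 1.0:
        kept = {s: c / n for s, c in counts.items() if c == n}
    else:
        kept = {s: c / n for s, c in counts.items() if c / n > threshold}
    tree = tree_from_splits(list(kept), universe)
    freq_by_members = {s.members: f for s, f in kept.items()}
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.name,))
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            f = freq_by_members.get(below[id(node)])
            if f is not None:
                node.name = f"{f:.6g}"
    return tree


def support_histogram(tree: Tree, bin_width: float) -> dict[float, int]:
    """Histogram of internal-edge support values in half-open bins
    [lo, lo + width); keys are bin lower edges, values counts."""
    if bin_width <= 0:
        raise CompareError("bin width must be positive")
    supports = [
        node.support
        for node in tree.internal_nodes(exclude_root=True)
        if node.support is not None
    ]
    if not supports:
        raise CompareError("tree carries no numeric internal-edge supports")
    bins: dict[float, int] = {}
    for value in supports:
        lo = math.floor(value / bin_width) * bin_width
        bins[lo] = bins.get(lo, 0) + 1
    return bins


def histogram_tsv(bins: Mapping[float, int]) -> str:
    lines = ["bin_lower\tcount"]
    for lo in sorted(bins):
        lines.append(f"{lo:g}\t{bins[lo]}")
    return "\n".join(lines) + "\n"


def length_rf_correlation(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between alignment length and
    average replicate RF — the signal-vs-variance relationship: shorter
    genes carry less information, so their bootstrap replicates scatter
    further apart."""
    if len(pairs) < 3:
        raise CompareError("need at least 3 (length, avg_rf) pairs")
    lengths = np.array([p[0] for p in pairs], dtype=float)
    rfs = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(lengths) == 0 or np.ptp(rfs) == 0:
        raise CompareError("constant column; correlation undefined")
    r, p = stats.pearsonr(lengths, rfs)
    return float(r), float(p)
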