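"""Shared fixtures and independent oracles used across the test modules."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phyloconcord.synthetic_data import simulate_species_tree
from phyloconcord.treeio import Node, Tree


def random_tree(seed: int, n_taxa: int = 10, collapse: float = 0.0) -> Tree:
    """A random binary tree with branch lengths; optionally collapse a
    fraction of internal edges into polytomies."""
    tree = simulate_species_tree(n_taxa, seed)
    if collapse > 0:
        rng = np.random.default_rng(seed + 1)
        for node in list(tree.postorder()):
            if (
                node is not tree.root
                and not node.is_leaf
                and rng.random() < collapse
            ):
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx : idx + 1] = node.children
                for child in node.children:
                    child.parent = parent
    return tree


def all_unrooted_binary_trees(labels: tuple[str, ...]):
    """Every unrooted binary tree topology on the given labels, generated by
    recursive edge insertion; yielded as rooted Tree objects (rooting is
    irrelevant for split comparison)."""

    def grow(trees, label):
        out = []
        for tree in trees:
            edges = [n for n in tree.preorder() if n is not tree.root]
            for edge_child in edges:
                clone = tree.copy()
                clone_edges = [n for n in clone.preorder() if n is not clone.root]
                target = clone_edges[edges.index(edge_child)]
                parent = target.parent
                mid = Node()
                idx = parent.children.index(target)
                parent.children[idx] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(Node(label))
                out.append(Tree(clone.root))
        return out

    root = Node()
    root.add_child(Node(labels[0]))
    root.add_child(Node(labels[1]))
    if len(labels) > 2:
        root.add_child(Node(labels[2]))
    trees = [Tree(root)]
    for label in labels[3:]:
        trees = grow(trees, label)
    return trees


def brute_force_bicliques(matrix) -> set[tuple[frozenset, frozenset]]:
    """Exhaustive maximal-biclique enumeration over all taxon subsets: for
    each nonempty taxon set T take the genes common to T; the pair is a
    maximal biclique iff T is exactly the support of those genes."""
    taxa = matrix.taxa
    genes = matrix.genes
    cells = matrix.df.to_numpy()
    out: set[tuple[frozenset, frozenset]] = set()
    for r in range(1, len(taxa) + 1):
        for combo in itertools.combinations(range(len(taxa)), r):
            shared = [j for j in range(len(genes)) if all(cells[i, j] for i in combo)]
            if not shared:
                continue
            support = [
                i for i in range(len(taxa)) if all(cells[i, j] for j in shared)
            ]
            if set(support) == set(combo):
                out.add(
                    (
                        frozenset(taxa[i] for i in combo),
                        frozenset(genes[j] for j in shared),
                    )
                )
    return out


@pytest.fixture
def four_gene_matrix():
    from phyloconcord.marker_matrix import load_presence_matrix

    return load_presence_matrix(
        "taxon\tg1\tg2\tg3\n" "t1\t1\t1\t0\n" "t2\t1\t1\t1\n" "t3\t0\t1\t1\n"
    )
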