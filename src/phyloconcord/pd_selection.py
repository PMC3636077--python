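"""Greedy maximum phylogenetic diversity (PD) taxon subsampling.

Given a guide tree over all candidate genomes, repeatedly add the leaf that
contributes the most new branch length to the spanning subtree of the
selection (Steel's greedy algorithm, which attains the maximum possible PD
for every prefix size when initialized with the farthest leaf pair). The
stopping rule mirrors the study design: stop when the best remaining
contribution falls below a threshold in substitutions per site (default
pipeline value 0.02, i.e. 2 substitutions per 100 sites).

All PD quantities are unrooted: the root junction is traversed but a root
edge is never counted, because guide trees (e.g. FastTree output) are
arbitrarily rooted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .treeio import Node, Tree, TreeError


class PDError(TreeError):
    """Invalid input for a phylogenetic-diversity computation."""


@dataclass(frozen=True)
class PDRecord:
    """One greedy step: the taxa added (a pair for the initial step, a single
    leaf afterwards), the PD increment they contributed, and the running total."""

    taxa: tuple[str, ...]
    increment: float
    cumulative: float


@dataclass
class PDRanking:
    """The ordered output of greedy max-PD selection."""

    records: list[PDRecord]

    @property
    def selected_taxa(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            out.extend(rec.taxa)
        return out

    @property
    def total_pd(self) -> float:
        return self.records[-1].cumulative if self.records else 0.0

    def __len__(self) -> int:
        return len(self.selected_taxa)

    def to_tsv(self) -> str:
        lines = ["rank\ttaxon\tincrement\tcumulative_pd"]
        rank = 0
        for rec in self.records:
            rank += 1
            lines.append(
                f"{rank}\t{','.join(rec.taxa)}\t{rec.increment!r}\t{rec.cumulative!r}"
            )
        return "\n".join(lines) + "\n"


def _adjacency(tree: Tree) -> tuple[dict[int, list[tuple[int, float]]], dict[str, int], dict[int, Node]]:
    """Unrooted weighted adjacency over node ids; refuses absent lengths."""
    adj: dict[int, list[tuple[int, float]]] = {}
    leaf_ids: dict[str, int] = {}
    nodes: dict[int, Node] = {}
    for node in tree.preorder():
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        if node.is_leaf:
            leaf_ids[node.name] = id(node)
        if node is not tree.root:
            if node.length is None:
                raise PDError("tree has absent branch lengths; refusing PD computation")
            adj[id(node)].append((id(node.parent), node.length))
            adj.setdefault(id(node.parent), []).append((id(node), node.length))
    return adj, leaf_ids, nodes


def phylogenetic_diversity(tree: Tree, subset: Iterable[str]) -> float:
    """Total branch length of the minimal unrooted subtree connecting the
    subset of leaves (the root is not forced into the spanning subtree)."""
    chosen = set(subset)
    if len(chosen) < 2:
        raise PDError("PD requires at least 2 taxa")
    labels = set(tree.leaf_labels())
    unknown = sorted(chosen - labels)
    if unknown:
        raise PDError(f"labels not in tree: {unknown}")
    if not tree.has_branch_lengths():
        raise PDError("tree has absent branch lengths; refusing PD computation")
    k = len(chosen)
    below: dict[int, int] = {}
    total = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = 1 if node.name in chosen else 0
        else:
            below[id(node)] = sum(below[id(c)] for c in node.children)
        if node is not tree.root and 0 < below[id(node)] < k:
            total += node.length
    return total


def _distances_from(
    adj: dict[int, list[tuple[int, float]]], sources: Iterable[int]
) -> tuple[dict[int, float], dict[int, int]]:
    """Multi-source distances on a tree (simple DFS; no cycles) plus
    predecessor links pointing back toward the nearest source."""
    dist: dict[int, float] = {}
    pred: dict[int, int] = {}
    stack = []
    for s in sources:
        dist[s] = 0.0
        stack.append(s)
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                pred[v] = u
                stack.append(v)
    return dist, pred


def _farthest_leaf(
    dist: dict[int, float], leaf_ids: dict[str, int], exclude: set[str]
) -> str:
    best_label: Optional[str] = None
    best = -1.0
    for label in sorted(leaf_ids):
        if label in exclude:
            continue
        d = dist[leaf_ids[label]]
        if d > best:
            best, best_label = d, label
    assert best_label is not None
    return best_label


def greedy_max_pd(
    tree: Tree,
    stop_increment: Optional[float] = None,
    max_taxa: Optional[int] = None,
) -> PDRanking:
    """Greedy maximum-PD leaf selection with deterministic tie-breaking.

    Starts from the globally farthest leaf pair (found by a double sweep
    from the lexicographically smallest leaf; ties broken to the smallest
    label), then repeatedly appends the leaf with the largest PD increment
    (ties again lexicographic). Stops when the best available increment is
    strictly below ``stop_increment``, when ``max_taxa`` labels have been
    selected, or when leaves run out. At least one stopping criterion must
    be supplied.
    """
    if stop_increment is None and max_taxa is None:
        raise PDError("need stop_increment and/or max_taxa")
    if max_taxa is not None and max_taxa < 2:
        raise PDError("max_taxa must be at least 2")
    labels = tree.leaf_labels()
    if len(labels) < 2:
        raise PDError("need at least 2 leaves")
    adj, leaf_ids, _ = _adjacency(tree)

    # farthest pair by double sweep (valid on trees with nonnegative weights)
    start = min(labels)
    d0, _ = _distances_from(adj, [leaf_ids[start]])
    x = _farthest_leaf(d0, leaf_ids, exclude=set())
    dx, pred_x = _distances_from(adj, [leaf_ids[x]])
    y = _farthest_leaf(dx, leaf_ids, exclude={x})
    path_len = dx[leaf_ids[y]]

    # spanning-subtree node set: the x-y path
    subtree: set[int] = set()
    node_id = leaf_ids[y]
    while True:
        subtree.add(node_id)
        if node_id == leaf_ids[x]:
            break
        node_id = pred_x[node_id]

    first, second = sorted((x, y))
    records = [PDRecord((first, second), path_len, path_len)]
    selected = {x, y}
    cumulative = path_len

    while True:
        if max_taxa is not None and len(selected) >= max_taxa:
            break
        if len(selected) == len(labels):
            break
        dist, pred = _distances_from(adj, subtree)
        best = _farthest_leaf(dist, leaf_ids, exclude=selected)
        increment = dist[leaf_ids[best]]
        if stop_increment is not None and increment < stop_increment:
            break
        cumulative += increment
        records.append(PDRecord((best,), increment, cumulative))
        selected.add(best)
        node_id = leaf_ids[best]
        while node_id not in subtree:
            subtree.add(node_id)
            node_id = pred[node_id]
    return PDRanking(records)
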