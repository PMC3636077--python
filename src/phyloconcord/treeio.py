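"""Trees, bipartitions, and the split algebra the rest of the pipeline consumes.

Trees are stored rooted, exactly as written in Newick, but every comparison
(split extraction, compatibility, Robinson-Foulds) treats them as unrooted,
matching the PHYLIP ``treedist`` semantics standard in phylogenomics. Branch
lengths are in substitutions per site; an absent length is recorded as
``None``, never silently as ``0.0`` — downstream phylogenetic-diversity code
refuses trees with absent lengths rather than corrupting PD rankings with
fake zeros.

Parsing is delegated to :mod:`dendropy` (Newick statements and Nexus
``trees`` blocks with translate tables); the in-memory structure here is a
minimal parent/child node graph so that split extraction, pruning and tree
assembly stay explicit and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "TaxonUniverse",
    "Node",
    "Tree",
    "Bipartition",
    "parse_newick",
    "parse_newick_list",
    "parse_nexus_trees",
    "write_newick",
    "leaf_set",
    "nontrivial_splits",
    "are_compatible",
    "tree_from_splits",
    "restrict_to_taxa",
]


class TreeError(Exception):
    """Invalid tree structure or unsupported tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick/Nexus input; message names the offending position."""


@dataclass(frozen=True)
class TaxonUniverse:
    """An ordered, duplicate-free set of leaf labels.

    The order is fixed at creation and is used to canonicalize bipartitions;
    universes derived from trees are created in sorted label order.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise TreeError(f"duplicate taxon labels in universe: {dupes}")

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(self.labels)

    @property
    def anchor(self) -> str:
        """The lexicographically smallest label; bipartition canonical sides
        are chosen not to contain it."""
        return min(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.label_set

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    # equality/hash on the *set* of labels: two universes with the same taxa
    # are interchangeable for split comparison regardless of stored order.
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonUniverse):
            return NotImplemented
        return self.label_set == other.label_set

    def __hash__(self) -> int:
        return hash(self.label_set)


class Node:
    """A tree node: leaf (``name`` = taxon label) or internal (``name`` = an
    optional label string, conventionally a support value in deposited trees)."""

    __slots__ = ("children", "parent", "length", "name")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
    ) -> None:
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length
        self.name = name

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def support(self) -> Optional[float]:
        """Internal-node label parsed as a number, if it is one."""
        if self.name is None:
            return None
        try:
            return float(self.name)
        except ValueError:
            return None

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name!r} {kind} len={self.length}>"


class Tree:
    """A rooted tree with uniquely labelled leaves and optional branch lengths."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self._validate()

    # ------------------------------------------------------------------ walks
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        labels = []
        for n in self.leaves():
            if n.name is None:
                raise TreeError("leaf without a label")
            labels.append(n.name)
        return labels

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        nodes = [n for n in self.preorder() if not n.is_leaf]
        if exclude_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def copy(self) -> "Tree":
        mapping: dict[int, Node] = {}
        for node in self.preorder():
            clone = Node(node.name, node.length)
            mapping[id(node)] = clone
            if node.parent is not None:
                mapping[id(node.parent)].add_child(clone)
        return Tree(mapping[id(self.root)])

    def has_branch_lengths(self) -> bool:
        """True iff every non-root edge carries a length."""
        return all(
            n.length is not None for n in self.preorder() if n is not self.root
        )

    def total_length(self) -> float:
        if not self.has_branch_lengths():
            raise TreeError("tree has absent branch lengths")
        return sum(n.length for n in self.preorder() if n is not self.root)

    def _validate(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        for node in self.preorder():
            if node is self.root:
                continue
            if not node.is_leaf and len(node.children) < 2:
                raise TreeError("non-root internal node with fewer than 2 children")
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length {node.length}")

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Tree with {len(self.leaves())} leaves>"


class Bipartition:
    """A canonicalized nontrivial split of a taxon universe.

    The stored side is the one *not* containing the universe's anchor label
    (its lexicographically smallest member), giving deterministic equality
    and hashing independent of which side an edge happened to induce.
    """

    __slots__ = ("members", "universe", "_hash")

    def __init__(self, side: Iterable[str], universe: TaxonUniverse) -> None:
        side = frozenset(side)
        uset = universe.label_set
        if not side <= uset:
            raise TreeError(f"split side {sorted(side - uset)} outside universe")
        if universe.anchor in side:
            side = uset - side
        if not (2 <= len(side) <= len(uset) - 2):
            raise TreeError(
                f"trivial split: side of size {len(side)} in universe of {len(uset)}"
            )
        self.members = side
        self.universe = universe
        self._hash = hash((side, universe.label_set))

    @property
    def complement(self) -> frozenset[str]:
        return self.universe.label_set - self.members

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return (
            self.members == other.members
            and self.universe.label_set == other.universe.label_set
        )

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        small = ",".join(sorted(self.members))
        return f"Bipartition({{{small}}} | rest)"


# --------------------------------------------------------------------- parsing


def _from_dendropy(dnode: "dendropy.Node") -> Node:
    """Convert a dendropy tree (rooted at ``dnode``) into our node graph,
    iteratively so deep (thousands-of-taxa) trees do not hit recursion limits."""
    root = Node()
    stack = [(dnode, root)]
    while stack:
        dn, mine = stack.pop()
        if dn.taxon is not None:
            mine.name = dn.taxon.label
        elif dn.label is not None:
            mine.name = dn.label
        mine.length = dn.edge.length
        for child in dn.child_nodes():
            stack.append((child, mine.add_child(Node())))
    return root


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Quoted labels are accepted; unquoted underscores are preserved verbatim
    (the convention of RAxML/FastTree output). Internal-node labels are kept
    in the node's ``name`` slot — in deposited trees they are bootstrap or
    concordance-factor values, exposed via ``Node.support``.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None
    return Tree(_from_dendropy(dtree.seed_node))


def parse_newick_list(text: str) -> list[Tree]:
    """Parse a multi-tree file, one Newick statement per line (blank lines
    ignored). Errors name the 1-based statement index."""
    trees = []
    idx = 0
    for line in text.splitlines():
        if not line.strip():
            continue
        idx += 1
        try:
            trees.append(parse_newick(line))
        except TreeError as exc:
            raise NewickParseError(f"statement {idx}: {exc}") from None
    if not trees:
        raise NewickParseError("no Newick statements found")
    return trees


def parse_nexus_trees(text: str) -> list[Tree]:
    """Parse a Nexus ``trees`` block (translate tables resolved to labels)."""
    try:
        dtrees = dendropy.TreeList.get(
            data=text,
            schema="nexus",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Nexus: {exc}") from None
    if not dtrees:
        raise NewickParseError("no trees in Nexus input")
    return [Tree(_from_dendropy(dt.seed_node)) for dt in dtrees]


# --------------------------------------------------------------------- writing


_NEEDS_QUOTING = set("(),:;[]' \t\n")


def _format_label(label: str) -> str:
    # write unquoted with underscores where possible; quote only when the
    # label contains structural characters that underscore-substitution
    # cannot hide.
    candidate = label.replace(" ", "_")
    if any(c in _NEEDS_QUOTING for c in candidate):
        return "'" + label.replace("'", "''") + "'"
    return candidate


def _format_length(length: float) -> str:
    return repr(length)


def write_newick(tree: Tree) -> str:
    """Serialize a tree to a single Newick statement.

    Round-trips through :func:`parse_newick` with identical split sets and
    branch lengths; absent lengths are simply omitted.
    """
    parts: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = _format_label(node.name or "")
        else:
            s = "(" + ",".join(parts.pop(id(c)) for c in node.children) + ")"
            if node.name is not None:
                s += _format_label(node.name)
        if node is not tree.root and node.length is not None:
            s += ":" + _format_length(node.length)
        parts[id(node)] = s
    return parts[id(tree.root)] + ";"


# ---------------------------------------------------------------- split algebra


def leaf_set(tree: Tree) -> TaxonUniverse:
    """The tree's taxon universe, in sorted label order."""
    return TaxonUniverse(tuple(sorted(tree.leaf_labels())))


def nontrivial_splits(tree: Tree) -> set[Bipartition]:
    """One bipartition per internal edge of the unrooted tree.

    A fully resolved unrooted tree on n leaves yields n - 3 splits; trees
    with fewer than 4 leaves yield the empty set. A bifurcating root's two
    child edges induce the same unrooted split and are deduplicated.
    """
    universe = leaf_set(tree)
    n = len(universe)
    if n < 4:
        return set()
    below: dict[int, frozenset[str]] = {}
    splits: set[Bipartition] = set()
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.name,))
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children)
            )
        if node is not tree.root:
            side = below[id(node)]
            if 2 <= len(side) <= n - 2:
                splits.add(Bipartition(side, universe))
    return splits


def are_compatible(s1: Bipartition, s2: Bipartition) -> bool:
    """Two splits are compatible iff some tree can contain both, i.e. at
    least one of the four pairwise side-intersections is empty."""
    if s1.universe.label_set != s2.universe.label_set:
        raise TreeError("splits from different taxon universes")
    a, b = s1.members, s2.members
    return (
        not (a & b)
        or a <= b
        or b <= a
        or (a | b) == s1.universe.label_set
    )


def tree_from_splits(
    splits: Iterable[Bipartition], universe: TaxonUniverse
) -> Tree:
    """Assemble the (unique) tree whose nontrivial splits are exactly the
    given pairwise-compatible set; unused resolution appears as polytomies
    and no branch lengths are assigned.

    Raises :class:`TreeError` naming the first incompatible pair found.
    """
    splits = list(splits)
    for s in splits:
        if s.universe.label_set != universe.label_set:
            raise TreeError("split universe does not match supplied universe")
    for i in range(len(splits)):
        for j in range(i + 1, len(splits)):
            if not are_compatible(splits[i], splits[j]):
                raise TreeError(
                    f"incompatible splits: {splits[i]!r} vs {splits[j]!r}"
                )
    # canonical sides exclude the anchor, so they form a laminar family:
    # build bottom-up, smallest clusters first.
    clusters = sorted({s.members for s in splits}, key=len)
    forest: dict[frozenset[str], Node] = {}
    for label in universe:
        leaf = Node(label)
        forest[frozenset((label,))] = leaf
    for cluster in clusters:
        node = Node()
        covered: frozenset[str] = frozenset()
        for key in [k for k in forest if k <= cluster]:
            node.add_child(forest.pop(key))
            covered |= key
        if covered != cluster:
            raise TreeError("splits are not laminar")  # unreachable if compatible
        forest[cluster] = node
    root = Node()
    for key in sorted(forest, key=lambda k: sorted(k)[0]):
        root.add_child(forest[key])
    return Tree(root)


def restrict_to_taxa(tree: Tree, keep: TaxonUniverse | Iterable[str]) -> Tree:
    """Prune the tree down to ``keep``, suppressing the degree-2 nodes this
    creates (their two incident branch lengths are summed). The result's
    splits are the input's splits restricted to ``keep`` with trivial ones
    dropped; path lengths among kept leaves are preserved.
    """
    if not isinstance(keep, TaxonUniverse):
        keep = TaxonUniverse(tuple(sorted(keep)))
    have = set(tree.leaf_labels())
    unknown = sorted(set(keep.labels) - have)
    if unknown:
        raise TreeError(f"labels not in tree: {unknown}")
    if len(keep) < 2:
        raise TreeError("need at least 2 taxa to restrict to")

    work = tree.copy()
    keep_set = keep.label_set
    # drop leaves not kept, bottom-up
    for node in list(work.postorder()):
        if node.is_leaf and node.name not in keep_set and node.parent is not None:
            node.parent.children.remove(node)
    # remove now-empty internals and splice unary chains, bottom-up
    for node in list(work.postorder()):
        parent = node.parent
        if parent is None:
            continue
        if not node.children and node.name not in keep_set:
            parent.children.remove(node)
        elif len(node.children) == 1:
            child = node.children[0]
            if node.length is None and child.length is None:
                combined = None
            else:
                combined = (node.length or 0.0) + (child.length or 0.0)
            child.length = combined
            child.parent = parent
            parent.children[parent.children.index(node)] = child
    root = work.root
    while len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
        root.parent = None
        root.length = None
    return Tree(root)
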