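"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: a species tree with
branch lengths; per-gene trees that deviate from it with controllable
discordance (NNI perturbation — deliberately agnostic to *why* genes
disagree, be it transfer, sorting, or artifact); bootstrap-like replicate
samples whose topological variance grows as the gene's alignment length
(signal) shrinks; presence/absence matrices with independent missingness;
and alignments evolved along the gene trees so supermatrix statistics run
end to end. One master seed fans out to per-gene and per-replicate streams,
so identical configurations produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .concordance import TreeSample
from .marker_matrix import PresenceMatrix
from .supermatrix import Alignment
from .treeio import Node, Tree, TreeError, write_newick

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Study-shaped defaults: a 24-gene panel with published alignment
    lengths, 500-replicate samples per gene, and moderate discordance."""

    seed: int = 0
    n_taxa: int = 50
    n_genes: int = 24
    discordance_prob: float = 0.25
    nni_moves_per_discordant_gene: int = 2
    replicate_count: int = 500
    gene_lengths: list[int] = field(default_factory=list)
    noise_scale: float = 20.0
    missingness_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.n_taxa < 4 or self.n_genes < 1 or self.replicate_count < 2:
            raise ValueError("counts out of range")
        if not 0 <= self.discordance_prob <= 1:
            raise ValueError("discordance_prob must be in [0, 1]")
        if not 0 <= self.missingness_prob <= 1:
            raise ValueError("missingness_prob must be in [0, 1]")
        if not self.gene_lengths:
            from .refdata import marker_gene_stats

            lengths = list(marker_gene_stats()["length"])
            self.gene_lengths = [
                lengths[i % len(lengths)] for i in range(self.n_genes)
            ]
        if len(self.gene_lengths) != self.n_genes:
            raise ValueError("gene_lengths must have n_genes entries")

    @property
    def gene_labels(self) -> list[str]:
        return [f"g{i + 1:03d}" for i in range(self.n_genes)]


# ------------------------------------------------------------------ species tree


def simulate_species_tree(
    n_taxa: int, seed: int, mean_branch_length: float = 0.1
) -> Tree:
    """Yule (pure-birth) topology with i.i.d. exponential branch lengths
    (default mean 0.1 substitutions/site); leaves labelled t0001, t0002, ...
    Deterministic per seed."""
    if n_taxa < 4:
        raise TreeError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    root = Node()
    tips = [root.add_child(Node()), root.add_child(Node())]
    while len(tips) < n_taxa:
        idx = int(rng.integers(len(tips)))
        tip = tips.pop(idx)
        tips.append(tip.add_child(Node()))
        tips.append(tip.add_child(Node()))
    for i, tip in enumerate(tips):
        tip.name = f"t{i + 1:04d}"
    tree = Tree(root)
    for node in tree.preorder():
        if node is not root:
            node.length = float(rng.exponential(mean_branch_length))
    return tree


# -------------------------------------------------------------------------- NNI


def _unroot_in_place(tree: Tree) -> None:
    """Collapse a bifurcating root into a trifurcation (standard unrooted
    representation); split set is unchanged."""
    root = tree.root
    if len(root.children) != 2:
        return
    internal = next((c for c in root.children if not c.is_leaf), None)
    if internal is None:
        return  # 2-leaf tree; nothing to do
    other = root.children[0] if root.children[1] is internal else root.children[1]
    if internal.length is not None or other.length is not None:
        other.length = (other.length or 0.0) + (internal.length or 0.0)
    root.children.remove(internal)
    for grandchild in internal.children:
        root.add_child(grandchild)


def _apply_random_nni(tree: Tree, rng: np.random.Generator) -> None:
    """One child-swap NNI: pick an internal (unrooted) edge (u, v) with v an
    internal non-root node, then swap a random child of v with a random
    other child of u. Changes exactly the split induced by that edge."""
    _unroot_in_place(tree)
    candidates = [
        n
        for n in tree.preorder()
        if n is not tree.root and not n.is_leaf and n.parent is not None
        and len(n.parent.children) >= 2
    ]
    if not candidates:
        return
    v = candidates[int(rng.integers(len(candidates)))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    s = siblings[int(rng.integers(len(siblings)))]
    c = v.children[int(rng.integers(len(v.children)))]
    # swap c and s, lengths travelling with their subtrees
    vi = v.children.index(c)
    ui = u.children.index(s)
    v.children[vi], u.children[ui] = s, c
    s.parent, c.parent = v, u


def perturb_tree(tree: Tree, moves: int, rng: np.random.Generator) -> Tree:
    """A copy of ``tree`` after ``moves`` random NNI rearrangements."""
    out = tree.copy()
    for _ in range(moves):
        _apply_random_nni(out, rng)
    return out


# -------------------------------------------------------------------- gene data


def simulate_gene_trees(
    species: Tree,
    n_genes: int,
    p: float,
    moves: int,
    seed: int,
) -> list[Tree]:
    """Each gene tree equals the species tree with probability 1 - p, else
    the species tree after ``moves`` random NNI moves; branch lengths are
    preserved wherever edges persist."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_genes):
        if rng.random() < p:
            out.append(perturb_tree(species, moves, rng))
        else:
            out.append(species.copy())
    return out


def simulate_replicate_sample(
    gene: Tree,
    gene_length: int,
    replicate_count: int,
    c: float,
    seed: int,
    label: str = "gene",
) -> TreeSample:
    """Bootstrap-like replicates: each is the gene tree perturbed by K
    random NNI moves with K ~ Poisson(c / gene_length) — shorter genes carry
    less signal, so their replicate samples scatter more."""
    if replicate_count < 2:
        raise ValueError("replicate_count must be at least 2")
    if gene_length < 1:
        raise ValueError("gene_length must be at least 1")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(replicate_count):
        k = int(rng.poisson(c / gene_length))
        trees.append(perturb_tree(gene, k, rng))
    return TreeSample(label, trees)


def simulate_presence_matrix(
    n_taxa: int,
    n_genes: int,
    m: float,
    seed: int,
    taxa: list[str] | None = None,
    genes: list[str] | None = None,
) -> PresenceMatrix:
    """Each cell absent independently with probability m."""
    if not 0 <= m <= 1:
        raise ValueError("missingness probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if taxa is None:
        taxa = [f"t{i + 1:04d}" for i in range(n_taxa)]
    if genes is None:
        genes = [f"g{j + 1:03d}" for j in range(n_genes)]
    cells = rng.random((n_taxa, n_genes)) >= m
    return PresenceMatrix(pd.DataFrame(cells, index=taxa, columns=genes))


def simulate_alignment(gene: Tree, length: int, seed: int, label: str = "gene") -> Alignment:
    """Evolve amino-acid sequences down the gene tree: root sequence uniform
    over the 20 residues; along each edge every site substitutes to a
    uniformly chosen different residue with probability 1 - exp(-branch
    length)."""
    if not gene.has_branch_lengths():
        raise TreeError("gene tree has absent branch lengths")
    if length < 1:
        raise ValueError("alignment length must be at least 1")
    rng = np.random.default_rng(seed)
    k = len(AMINO_ACIDS)
    seqs: dict[int, np.ndarray] = {}
    out: dict[str, str] = {}
    for node in gene.preorder():
        if node is gene.root:
            seq = rng.integers(k, size=length)
        else:
            parent_seq = seqs[id(node.parent)]
            p_sub = 1.0 - np.exp(-node.length)
            hit = rng.random(length) < p_sub
            seq = parent_seq.copy()
            if hit.any():
                # uniform over the 19 *other* residues
                shift = rng.integers(1, k, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % k
        seqs[id(node)] = seq
        if node.is_leaf:
            out[node.name] = "".join(AMINO_ACIDS[i] for i in seq)
    return Alignment(label, out)


# ------------------------------------------------------------------ full dataset


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete synthetic dataset in the formats the pipeline reads.

    Layout: ``species_tree.nwk`` (also the PD guide tree), ``alignments/``
    (FASTA per gene), ``samples/`` (multi-Newick per gene),
    ``presence_matrix.tsv`` and ``config.json``. Returns a summary dict.
    """
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)

    streams = np.random.SeedSequence(config.seed).spawn(3 + 2 * config.n_genes)
    species = simulate_species_tree(
        config.n_taxa, seed=streams[0].generate_state(1)[0] % (2**31)
    )
    gene_trees = simulate_gene_trees(
        species,
        config.n_genes,
        config.discordance_prob,
        config.nni_moves_per_discordant_gene,
        seed=streams[1].generate_state(1)[0] % (2**31),
    )
    matrix = simulate_presence_matrix(
        config.n_taxa,
        config.n_genes,
        config.missingness_prob,
        seed=streams[2].generate_state(1)[0] % (2**31),
        genes=config.gene_labels,
        taxa=[leaf for leaf in sorted(species.leaf_labels())],
    )

    (outdir / "species_tree.nwk").write_text(write_newick(species) + "\n")
    (outdir / "presence_matrix.tsv").write_text(matrix.to_tsv())
    from .supermatrix import write_fasta_alignment

    for i, (label, gtree) in enumerate(zip(config.gene_labels, gene_trees)):
        aln_seed = streams[3 + 2 * i].generate_state(1)[0] % (2**31)
        rep_seed = streams[4 + 2 * i].generate_state(1)[0] % (2**31)
        aln = simulate_alignment(gtree, config.gene_lengths[i], aln_seed, label)
        (outdir / "alignments" / f"{label}.fasta").write_text(
            write_fasta_alignment(aln)
        )
        sample = simulate_replicate_sample(
            gtree,
            config.gene_lengths[i],
            config.replicate_count,
            config.noise_scale,
            rep_seed,
            label,
        )
        (outdir / "samples" / f"{label}.trees").write_text(
            "".join(write_newick(t) + "\n" for t in sample.trees)
        )
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")
    return {
        "species_tree": str(outdir / "species_tree.nwk"),
        "presence_matrix": str(outdir / "presence_matrix.tsv"),
        "alignments_dir": str(outdir / "alignments"),
        "samples_dir": str(outdir / "samples"),
        "genes": config.gene_labels,
        "n_taxa": config.n_taxa,
    }
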