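"""Marker presence/absence across genomes and missing-data-free block selection.

Genome-scale phylogenies built from a panel of single-copy marker genes
(here a PhyloSift/AMPHORA-style panel) face structured missingness: draft
genomes lack some markers, and concordance analysis requires every taxon in
every single-gene alignment. This module represents the taxa x genes
detection matrix and selects taxon/gene blocks with no missing cells via
maximal biclique enumeration, plus the simpler "genes complete for a given
taxon set" query actually used by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd


class MatrixError(Exception):
    """Malformed presence matrix or invalid query."""


@dataclass
class PresenceMatrix:
    """Boolean taxa x genes matrix of marker detection.

    Backed by a pandas DataFrame with taxon labels as the index and gene
    labels as columns; row/column order is preserved from input.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.shape[0] < 1 or self.df.shape[1] < 1:
            raise MatrixError("presence matrix must be at least 1x1")
        if self.df.index.has_duplicates:
            raise MatrixError("duplicate taxon labels")
        if self.df.columns.has_duplicates:
            raise MatrixError("duplicate gene labels")
        self.df = self.df.astype(bool)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def genes(self) -> list[str]:
        return list(self.df.columns)

    def to_tsv(self) -> str:
        out = self.df.astype(int)
        return out.to_csv(sep="\t", index_label="taxon")


@dataclass(frozen=True)
class Biclique:
    """A maximal all-present block: every (taxon, gene) cell in the
    cross-product is detected and neither side can be extended."""

    taxa: tuple[str, ...]
    genes: tuple[str, ...]


def load_presence_matrix(table: str) -> PresenceMatrix:
    """Parse a rectangular TSV: first row gene labels, first column taxon
    labels, cells 0/1. Errors carry the offending 1-based line number."""
    lines = [ln for ln in table.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise MatrixError("presence matrix needs a header row and at least one taxon row")
    header = lines[0].rstrip("\n").split("\t")
    genes = header[1:]
    if not genes:
        raise MatrixError("line 1: no gene columns in header")
    if len(set(genes)) != len(genes):
        raise MatrixError("line 1: duplicate gene labels")
    taxa: list[str] = []
    rows: list[list[bool]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(genes) + 1:
            raise MatrixError(
                f"line {lineno}: expected {len(genes) + 1} columns, got {len(cells)}"
            )
        taxon = cells[0]
        if taxon in seen:
            raise MatrixError(f"line {lineno}: duplicate taxon label {taxon!r}")
        seen.add(taxon)
        row = []
        for gene, cell in zip(genes, cells[1:]):
            if cell == "0":
                row.append(False)
            elif cell == "1":
                row.append(True)
            else:
                raise MatrixError(
                    f"line {lineno}: non-binary cell {cell!r} for gene {gene!r}"
                )
        taxa.append(taxon)
        rows.append(row)
    return PresenceMatrix(pd.DataFrame(rows, index=taxa, columns=genes))


def filter_taxa_by_marker_count(
    matrix: PresenceMatrix, min_markers: int
) -> PresenceMatrix:
    """Retain exactly the taxa carrying at least ``min_markers`` of the
    panel (the study-design filter for usable genomes); genes unchanged."""
    if not 0 <= min_markers <= len(matrix.genes):
        raise MatrixError(
            f"min_markers must be in [0, {len(matrix.genes)}], got {min_markers}"
        )
    keep = matrix.df.sum(axis=1) >= min_markers
    kept = matrix.df.loc[keep]
    if kept.shape[0] == 0:
        raise MatrixError(
            f"no taxa have at least {min_markers} markers"
        )
    return PresenceMatrix(kept)


def enumerate_maximal_bicliques(matrix: PresenceMatrix) -> list[Biclique]:
    """Enumerate every maximal biclique (both sides nonempty) exactly once.

    Maximal bicliques of a bipartite incidence matrix are in bijection with
    closed gene sets that have nonempty taxon support; enumeration is a
    depth-first closed-set search over the gene side with prefix pruning
    (LCM-style), using taxon-set bitmasks. Output order is deterministic:
    |taxa| descending, then |genes| descending, then labels.
    """
    taxa = matrix.taxa
    genes = matrix.genes
    n_taxa = len(taxa)
    values = matrix.df.to_numpy()
    support = []  # per-gene bitmask of taxa carrying it
    for j in range(len(genes)):
        mask = 0
        for i in range(n_taxa):
            if values[i, j]:
                mask |= 1 << i
        support.append(mask)
    full = (1 << n_taxa) - 1

    def closure(taxon_mask: int) -> frozenset[int]:
        return frozenset(
            j for j in range(len(genes)) if support[j] & taxon_mask == taxon_mask
        )

    results: list[tuple[int, frozenset[int]]] = []

    def emit(taxon_mask: int, closed: frozenset[int]) -> None:
        if taxon_mask and closed:
            results.append((taxon_mask, closed))

    def descend(taxon_mask: int, closed: frozenset[int], start: int) -> None:
        emit(taxon_mask, closed)
        for j in range(start, len(genes)):
            if j in closed:
                continue
            narrowed = taxon_mask & support[j]
            if not narrowed:
                continue
            new_closed = closure(narrowed)
            # prefix test: adding j must not pull in an earlier unseen gene,
            # otherwise this closed set is reached from a smaller prefix.
            if any(h < j and h not in closed for h in new_closed):
                continue
            descend(narrowed, new_closed, j + 1)

    if n_taxa:
        descend(full, closure(full), 0)

    def to_biclique(item: tuple[int, frozenset[int]]) -> Biclique:
        taxon_mask, closed = item
        t = tuple(taxa[i] for i in range(n_taxa) if taxon_mask >> i & 1)
        g = tuple(genes[j] for j in sorted(closed))
        return Biclique(t, g)

    bicliques = [to_biclique(it) for it in results]
    bicliques.sort(key=lambda b: (-len(b.taxa), -len(b.genes), b.taxa, b.genes))
    return bicliques


def complete_marker_set(
    matrix: PresenceMatrix, required_taxa: Iterable[str]
) -> list[str]:
    """Genes present in *every* required taxon (the column-wise AND) — the
    gene side of the maximal biclique whose taxon side contains exactly the
    required set. Empty result is a warning, not an error."""
    required = list(required_taxa)
    unknown = sorted(set(required) - set(matrix.taxa))
    if unknown:
        raise MatrixError(f"unknown taxa: {unknown}")
    sub = matrix.df.loc[required]
    complete = [g for g in matrix.genes if bool(sub[g].all())]
    if not complete:
        warnings.warn(
            "no gene is present in all required taxa", stacklevel=2
        )
    return complete


def per_gene_missing_counts(
    matrix: PresenceMatrix, taxa: Iterable[str]
) -> dict[str, int]:
    """For each gene, the number of taxa in the subset lacking it."""
    subset = list(taxa)
    unknown = sorted(set(subset) - set(matrix.taxa))
    if unknown:
        raise MatrixError(f"unknown taxa: {unknown}")
    sub = matrix.df.loc[subset]
    return {g: int((~sub[g]).sum()) for g in matrix.genes}


def flag_excess_missing(
    counts: Mapping[str, int], ceiling: int = 6
) -> list[str]:
    """Genes whose missing-taxon count exceeds the ceiling (default 6 — the
    study's per-gene missing-data tolerance)."""
    return sorted(g for g, c in counts.items() if c > ceiling)


def selection_report(
    counts: Mapping[str, int], selected: Sequence[str], ceiling: int = 6
) -> str:
    """TSV report: gene, missing count, selected flag, over-ceiling flag."""
    chosen = set(selected)
    lines = ["gene\tmissing\tselected\tover_ceiling"]
    for gene in counts:
        lines.append(
            f"{gene}\t{counts[gene]}\t{int(gene in chosen)}"
            f"\t{int(counts[gene] > ceiling)}"
        )
    return "\n".join(lines) + "\n"
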