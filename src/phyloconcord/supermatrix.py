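"""Per-gene amino-acid alignments and partitioned supermatrix assembly.

A supermatrix is the concatenation of the per-gene alignments over one
shared taxon universe, partitioned by gene; a taxon absent from a gene is
gap-filled ('-') across that gene's column range, which is how downstream
ML tools are told the data are missing. Internal partition coordinates are
0-based half-open; the written partition file uses the 1-based inclusive
convention of RAxML-style model files.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .treeio import TaxonUniverse

GAP = "-"


class AlignmentError(Exception):
    """Malformed alignment or invalid supermatrix operation."""


@dataclass
class Alignment:
    """A fixed-length amino-acid alignment for one gene ('-' gap, 'X' unknown)."""

    gene: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"alignment {self.gene!r} has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"alignment {self.gene!r} is ragged: lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError(f"alignment {self.gene!r} has zero columns")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)


@dataclass
class Supermatrix:
    """Concatenated alignment with per-gene half-open [start, end) ranges."""

    universe: TaxonUniverse
    sequences: dict[str, str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def slice_gene(self, gene: str) -> Alignment:
        """Recover one gene's alignment (absent taxa appear as all-gap rows)."""
        for name, start, end in self.partitions:
            if name == gene:
                return Alignment(
                    gene, {t: self.sequences[t][start:end] for t in self.universe}
                )
        raise AlignmentError(f"no partition named {gene!r}")

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{self.sequences[t]}\n" for t in self.universe)

    def to_phylip(self) -> str:
        """Relaxed PHYLIP: name, whitespace, full sequence on one line."""
        width = max(len(t) for t in self.universe) + 2
        head = f" {len(self.universe)} {self.length}\n"
        body = "".join(
            f"{t:<{width}}{self.sequences[t]}\n" for t in self.universe
        )
        return head + body

    def partition_file(self, model: str = "AUTO") -> str:
        """RAxML-style partition file, 1-based inclusive coordinates."""
        return "".join(
            f"{model}, {gene} = {start + 1}-{end}\n"
            for gene, start, end in self.partitions
        )


def read_fasta_alignment(text: str, gene: str = "gene") -> Alignment:
    """Parse a FASTA alignment; the header up to the first whitespace is the
    taxon label. Duplicate labels and ragged sequences are errors."""
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise AlignmentError("empty or non-FASTA input")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise AlignmentError(f"duplicate taxon label {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    return Alignment(gene, sequences)


def write_fasta_alignment(aln: Alignment) -> str:
    return "".join(f">{t}\n{s}\n" for t, s in aln.sequences.items())


def concatenate(
    alignments: list[Alignment], universe: TaxonUniverse
) -> Supermatrix:
    """Assemble the partitioned supermatrix over ``universe`` in the given
    gene order; taxa missing a gene are gap-filled across its range."""
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    genes = [a.gene for a in alignments]
    if len(set(genes)) != len(genes):
        raise AlignmentError("duplicate gene labels among alignments")
    uset = universe.label_set
    for aln in alignments:
        extra = sorted(set(aln.taxa) - uset)
        if extra:
            raise AlignmentError(
                f"alignment {aln.gene!r} has taxa outside the universe: {extra}"
            )
    partitions: list[tuple[str, int, int]] = []
    pieces: dict[str, list[str]] = {t: [] for t in universe}
    offset = 0
    for aln in alignments:
        gap_row = GAP * aln.length
        for taxon in universe:
            pieces[taxon].append(aln.sequences.get(taxon, gap_row))
        partitions.append((aln.gene, offset, offset + aln.length))
        offset += aln.length
    sequences = {t: "".join(pieces[t]) for t in universe}
    return Supermatrix(universe, sequences, partitions)


def average_percent_identity(
    aln: Alignment,
    max_pairs: int = 10_000,
    seed: int = 0,
    count_gapped_columns: bool = False,
) -> float:
    """Mean pairwise percent identity over unordered sequence pairs.

    By default a column gapped in either sequence is excluded from the
    denominator; with ``count_gapped_columns`` the denominator is the full
    alignment length and such columns count as mismatches (the two modes
    bracket the common conventions). Pairs with no mutually ungapped column
    are dropped. When the number of pairs exceeds ``max_pairs`` a seeded
    uniform sample of pairs is used.
    """
    taxa = aln.taxa
    if len(taxa) < 2:
        raise AlignmentError("percent identity needs at least 2 sequences")
    all_pairs = list(itertools.combinations(range(len(taxa)), 2))
    if len(all_pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_pairs), size=max_pairs, replace=False)
        pairs = [all_pairs[i] for i in idx]
    else:
        pairs = all_pairs
    values: list[float] = []
    seqs = [aln.sequences[t] for t in taxa]
    for i, j in pairs:
        a, b = seqs[i], seqs[j]
        matches = 0
        comparable = 0
        for ca, cb in zip(a, b):
            if ca == GAP or cb == GAP:
                continue
            comparable += 1
            if ca == cb:
                matches += 1
        if count_gapped_columns:
            values.append(100.0 * matches / aln.length)
        elif comparable:
            values.append(100.0 * matches / comparable)
    if not values:
        raise AlignmentError("no comparable sequence pairs (all-gap overlaps)")
    return float(np.mean(values))


def per_gene_stats_tsv(
    alignments: list[Alignment], max_pairs: int = 10_000, seed: int = 0
) -> str:
    """Per-gene summary table (gene, alignment length, avg % identity)."""
    lines = ["gene\tlength\tavg_pct_identity"]
    for aln in alignments:
        pid = average_percent_identity(aln, max_pairs=max_pairs, seed=seed)
        lines.append(f"{aln.gene}\t{aln.length}\t{pid:.2f}")
    return "\n".join(lines) + "\n"
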