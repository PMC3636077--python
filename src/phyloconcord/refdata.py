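"""Published reference numbers for the 24-gene bacterial/archaeal marker panel.

The study that motivates this pipeline selected 24 single-copy, nearly
ubiquitous protein-coding genes (a PhyloSift/AMPHORA-style panel, PMPROK
identifiers) and reported, per gene: the amino-acid alignment length, the
average pairwise percent identity, the average Robinson-Foulds distance
among its ML bootstrap replicates, and the number of rapid-bootstrap
replicates at convergence. Those printed values are inputs for desk-scale
analyses here — e.g. the alignment-length vs. bootstrap-RF correlation and
the expected 4419-column supermatrix — without requiring the original
841-genome alignments.
"""

from __future__ import annotations

import pandas as pd

# columns: gene_id, gene_name, product, length, avg_pct_identity, avg_rf, bootstrap_reps
_MARKER_GENE_ROWS = [
    ("PMPROK00003", "rplN", "50S ribosomal protein L14", 118, 39, 1124.18, 500),
    ("PMPROK00015", "rpsC", "30S ribosomal protein S3", 180, 46, 947.92, 400),
    ("PMPROK00019", "rpsE", "30S ribosomal protein S5", 155, 47, 1026.01, 500),
    ("PMPROK00020", "rplF", "50S ribosomal protein L6", 168, 49, 1039.08, 450),
    ("PMPROK00025", "rpsS", "30S ribosomal protein S19", 91, 50, 1194.08, 550),
    ("PMPROK00028", "rpsB", "30S ribosomal protein S2", 226, 51, 903.61, 450),
    ("PMPROK00029", "rplK", "50S ribosomal protein L11", 141, 51, 1112.34, 450),
    ("PMPROK00034", "rplD", "50S ribosomal protein L4", 196, 52, 947.99, 450),
    ("PMPROK00041", "rpsQ", "30S ribosomal protein S17", 78, 52, 1222.31, 450),
    ("PMPROK00048", "rplB", "50S ribosomal protein L2", 208, 52, 1015.17, 500),
    ("PMPROK00051", "rpsI", "30S ribosomal protein S9", 128, 53, 1098.84, 450),
    ("PMPROK00053", "rplE", "50S ribosomal protein L5", 176, 53, 1027.25, 500),
    ("PMPROK00054", "rpsG", "30S ribosomal protein S7", 156, 54, 1011.56, 450),
    ("PMPROK00060", "lepA", "GTP-binding protein LepA", 598, 56, 666.34, 300),
    ("PMPROK00064", "infB", "translation initiation factor IF-2", 533, 56, 701.37, 300),
    ("PMPROK00068", "rpsK", "30S ribosomal protein S11", 113, 58, 1149.50, 500),
    ("PMPROK00071", "rplP", "50S ribosomal protein L16", 133, 58, 1070.93, 450),
    ("PMPROK00074", "rpsH", "30S ribosomal protein S8", 125, 59, 1083.00, 450),
    ("PMPROK00075", "rplC", "50S ribosomal protein L3", 202, 60, 950.51, 400),
    ("PMPROK00081", "rpsM", "30S ribosomal protein S13", 118, 61, 1129.42, 450),
    ("PMPROK00087", "pheS", "phenylalanyl-tRNA synthetase, alpha subunit", 219, 61, 920.66, 450),
    ("PMPROK00092", "rplO", "50S ribosomal protein L15", 138, 62, 1128.83, 400),
    ("PMPROK00093", "rpsJ", "30S ribosomal protein S10", 101, 65, 1094.34, 400),
    ("PMPROK00094", "rpsL", "30S ribosomal protein S12", 118, 74, 1164.01, 450),
]

#: Published total phylogenetic diversity (sum of branch lengths) of the tree
#: of all Greengenes 16S rRNA sequences.
GREENGENES_16S_TOTAL_PD = 1766.27

#: Published total branch length of the comparable 16S tree of the study's
#: 841-genome subsample (bacteria + archaea).
SUBSAMPLE_841_16S_PD = 69.91


def marker_gene_stats() -> pd.DataFrame:
    """The published per-gene statistics of the 24-gene marker panel."""
    return pd.DataFrame(
        _MARKER_GENE_ROWS,
        columns=[
            "gene_id",
            "gene_name",
            "product",
            "length",
            "avg_pct_identity",
            "avg_rf",
            "bootstrap_reps",
        ],
    )


def pd_coverage_percent(
    pd_subset: float = SUBSAMPLE_841_16S_PD,
    pd_total: float = GREENGENES_16S_TOTAL_PD,
) -> float:
    """Phylogenetic diversity of a subsample as a percentage of a reference
    total (defaults: the published 16S PD totals above)."""
    if pd_total <= 0:
        raise ValueError("total PD must be positive")
    return 100.0 * pd_subset / pd_total
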