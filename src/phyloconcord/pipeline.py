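"""Pipeline orchestration: taxon filtering -> greedy PD selection ->
marker selection -> supermatrix assembly -> concordance tree -> comparison
reports, with a JSON manifest recording parameters, input checksums, stage
counts and every output file.

The stage order encodes the study design: taxa are dereplicated on the
guide tree *first*, then the marker set is chosen as the genes complete for
the selected taxa (allowlisted taxa are unioned in afterwards and exempted
from the completeness requirement; their missing genes are gap-filled).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import concordance as conc
from . import marker_matrix as mm
from . import supermatrix as sm
from . import treecompare as tc
from .pd_selection import greedy_max_pd
from .treeio import (
    TaxonUniverse,
    parse_newick,
    restrict_to_taxa,
    write_newick,
)

log = logging.getLogger("phyloconcord")


class PipelineError(Exception):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run. Threshold defaults are the
    study's constants: at least 18 of 38 markers per genome, a PD stopping
    increment of 0.02 substitutions/site, at most 6 missing taxa per gene."""

    guide_tree: str
    presence_matrix: str
    alignments_dir: str
    samples_dir: str
    outdir: str
    min_markers: int = 18
    pd_stop_increment: float = 0.02
    max_taxa: Optional[int] = None
    missing_ceiling: int = 6
    cf_floor: float = 0.0
    consensus_threshold: float = 0.5
    allowlist: list[str] = field(default_factory=list)
    reference_tree: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_markers < 0:
            raise PipelineError("config: min_markers must be nonnegative")
        if self.pd_stop_increment < 0:
            raise PipelineError("config: pd_stop_increment must be nonnegative")
        if not 0 <= self.cf_floor < 1:
            raise PipelineError("config: cf_floor must be in [0, 1)")
        if not 0.5 <= self.consensus_threshold <= 1:
            raise PipelineError("config: consensus_threshold must be in [0.5, 1]")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in fixed order and return the manifest dict
    (also written to ``<outdir>/manifest.json``). Any stage error aborts
    with the stage name and cause."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": asdict(config),
        "seed": config.seed,
        "stage_order": [
            "filter_taxa",
            "pd_selection",
            "marker_selection",
            "supermatrix",
            "concordance",
            "compare",
        ],
        "inputs": {},
        "outputs": [],
        "counts": {},
        "warnings": [],
        "completed_stages": [],
    }

    def record_input(path: str | Path) -> None:
        p = Path(path)
        manifest["inputs"][str(p)] = _sha256(p)

    def emit(path: Path, text: str) -> None:
        path.write_text(text)
        manifest["outputs"].append(str(path))

    def fail(stage: str, exc: Exception) -> PipelineError:
        manifest["warnings"].append(f"aborted in stage {stage}: {exc}")
        _write_manifest(outdir, manifest)
        return PipelineError(f"stage {stage}: {exc}")

    # ---------------------------------------------------------- filter_taxa
    stage = "filter_taxa"
    try:
        record_input(config.presence_matrix)
        matrix = mm.load_presence_matrix(Path(config.presence_matrix).read_text())
        filtered = mm.filter_taxa_by_marker_count(matrix, config.min_markers)
    except Exception as exc:
        raise fail(stage, exc) from exc
    manifest["counts"]["taxa_input"] = len(matrix.taxa)
    manifest["counts"]["taxa_after_marker_filter"] = len(filtered.taxa)
    log.info("%s: kept %d/%d taxa", stage, len(filtered.taxa), len(matrix.taxa))
    manifest["completed_stages"].append(stage)

    # ----------------------------------------------------------- pd_selection
    stage = "pd_selection"
    try:
        record_input(config.guide_tree)
        guide = parse_newick(Path(config.guide_tree).read_text())
        usable = sorted(set(filtered.taxa) & set(guide.leaf_labels()))
        if len(usable) < 4:
            raise PipelineError("fewer than 4 filtered taxa present in guide tree")
        guide_sub = restrict_to_taxa(guide, usable)
        ranking = greedy_max_pd(
            guide_sub,
            stop_increment=config.pd_stop_increment,
            max_taxa=config.max_taxa,
        )
        pd_selected = ranking.selected_taxa
        final_taxa = sorted(set(pd_selected) | (set(config.allowlist) & set(matrix.taxa)))
        emit(outdir / "pd_ranking.tsv", ranking.to_tsv())
        emit(outdir / "selected_taxa.txt", "\n".join(final_taxa) + "\n")
    except Exception as exc:
        raise fail(stage, exc) from exc
    manifest["counts"]["taxa_selected_pd"] = len(pd_selected)
    manifest["counts"]["taxa_final"] = len(final_taxa)
    log.info("%s: selected %d taxa (PD) + allowlist -> %d", stage,
             len(pd_selected), len(final_taxa))
    manifest["completed_stages"].append(stage)

    # ------------------------------------------------------- marker_selection
    stage = "marker_selection"
    try:
        genes = mm.complete_marker_set(filtered, pd_selected)
        if not genes:
            raise PipelineError("no gene is complete for the PD-selected taxa")
        counts = mm.per_gene_missing_counts(matrix, final_taxa)
        flagged = mm.flag_excess_missing(
            {g: counts[g] for g in genes}, ceiling=config.missing_ceiling
        )
        if flagged:
            manifest["warnings"].append(
                f"genes over missing ceiling {config.missing_ceiling}: {flagged}"
            )
        emit(
            outdir / "marker_selection.tsv",
            mm.selection_report(counts, genes, ceiling=config.missing_ceiling),
        )
    except Exception as exc:
        raise fail(stage, exc) from exc
    manifest["counts"]["genes_input"] = len(matrix.genes)
    manifest["counts"]["genes_selected"] = len(genes)
    log.info("%s: selected %d/%d genes", stage, len(genes), len(matrix.genes))
    manifest["completed_stages"].append(stage)

    # ------------------------------------------------------------ supermatrix
    stage = "supermatrix"
    try:
        universe = TaxonUniverse(tuple(final_taxa))
        alignments = []
        for gene in genes:
            path = Path(config.alignments_dir) / f"{gene}.fasta"
            record_input(path)
            aln = sm.read_fasta_alignment(path.read_text(), gene)
            subset = {
                t: s for t, s in aln.sequences.items() if t in universe.label_set
            }
            alignments.append(sm.Alignment(gene, subset))
        matrix_out = sm.concatenate(alignments, universe)
        emit(outdir / "supermatrix.fasta", matrix_out.to_fasta())
        emit(outdir / "supermatrix.phy", matrix_out.to_phylip())
        emit(outdir / "partitions.txt", matrix_out.partition_file())
        emit(
            outdir / "gene_stats.tsv",
            sm.per_gene_stats_tsv(alignments, seed=config.seed),
        )
    except Exception as exc:
        raise fail(stage, exc) from exc
    manifest["counts"]["supermatrix_columns"] = matrix_out.length
    manifest["counts"]["supermatrix_partitions"] = len(matrix_out.partitions)
    log.info("%s: %d columns, %d partitions", stage, matrix_out.length,
             len(matrix_out.partitions))
    manifest["completed_stages"].append(stage)

    # ------------------------------------------------------------ concordance
    stage = "concordance"
    try:
        samples: list[conc.TreeSample] = []
        for gene in genes:
            path = Path(config.samples_dir) / f"{gene}.trees"
            record_input(path)
            raw = conc.read_tree_sample(path.read_text(), gene)
            keep = sorted(set(final_taxa) & raw.universe.label_set)
            if len(keep) < 4:
                raise PipelineError(
                    f"gene {gene}: fewer than 4 selected taxa in its sample"
                )
            restricted = [restrict_to_taxa(t, keep) for t in raw.trees]
            samples.append(conc.TreeSample(gene, restricted))
        tables = [conc.split_frequencies(s) for s in samples]
        cf = conc.concordance_factors(tables)
        pct = conc.primary_concordance_tree(cf, cf_floor=config.cf_floor)
        emit(outdir / "concordance_factors.tsv", cf.to_tsv())
        emit(outdir / "concordance_tree.nwk", write_newick(pct) + "\n")
    except Exception as exc:
        raise fail(stage, exc) from exc
    n_accepted = len(
        [n for n in pct.internal_nodes(exclude_root=True)]
    )
    manifest["counts"]["cf_splits_tabulated"] = len(cf.factors)
    manifest["counts"]["splits_accepted"] = n_accepted
    log.info("%s: %d splits tabulated, %d accepted", stage, len(cf.factors),
             n_accepted)
    manifest["completed_stages"].append(stage)

    # ---------------------------------------------------------------- compare
    stage = "compare"
    try:
        rows = []
        for aln, sample in zip(alignments, samples):
            avg_rf = tc.mean_pairwise_rf(sample, seed=config.seed)
            rows.append((aln.gene, aln.length, avg_rf))
        tsv = "gene\tlength\tavg_rf\n" + "".join(
            f"{g}\t{l}\t{r:.4f}\n" for g, l, r in rows
        )
        emit(outdir / "replicate_rf.tsv", tsv)
        if len(rows) >= 3:
            try:
                r, p = tc.length_rf_correlation([(l, rf) for _, l, rf in rows])
                manifest["counts"]["length_rf_pearson_r"] = r
                manifest["counts"]["length_rf_pearson_p"] = p
            except tc.CompareError as exc:
                manifest["warnings"].append(f"length-RF correlation skipped: {exc}")
        try:
            hist = tc.support_histogram(pct, bin_width=0.1)
            emit(outdir / "cf_histogram.tsv", tc.histogram_tsv(hist))
        except tc.CompareError as exc:
            manifest["warnings"].append(f"CF histogram skipped: {exc}")
        if config.reference_tree:
            record_input(config.reference_tree)
            ref = parse_newick(Path(config.reference_tree).read_text())
            result = tc.rf_distance(pct, ref, prune_to_shared=True)
            manifest["counts"]["rf_vs_reference"] = result.raw
            log.info("compare: RF vs reference = %d", result.raw)
    except Exception as exc:
        raise fail(stage, exc) from exc
    manifest["completed_stages"].append(stage)

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
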