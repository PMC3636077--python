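# Methods

## Problem and scope

phyloconcord rebuilds, as a tested library, the analysis chain used to
construct a reference phylogeny from many bacterial and archaeal genomes
with a panel of single-copy marker genes:

1. **Taxon dereplication** by greedy maximum phylogenetic diversity (PD) on
   a guide tree;
2. **Marker selection** that eliminates missing data, via maximal-biclique
   reasoning on the gene-presence matrix;
3. **Supermatrix assembly**: a concatenated amino-acid alignment
   partitioned by gene;
4. **Concordance supertree**: per-gene split frequencies from replicate
   tree samples, concordance factors (CFs), and a greedily assembled
   primary concordance tree;
5. **Tree comparison**: Robinson–Foulds (RF) distances, majority-rule
   consensus, support histograms, and the alignment-length vs.
   replicate-variance correlation.

Tree *inference* (ML searches, bootstrap generation, HMM alignment) is out
of scope; inferred trees and alignments are consumed as inputs.

## Tree model and split algebra

Trees are stored rooted as written in Newick, but all comparisons are
unrooted: every statistic is defined on nontrivial bipartitions (splits),
the two-way partitions of the taxon set induced by internal edges, which
matches PHYLIP `treedist` semantics. A fully resolved unrooted tree on
*n* leaves has *n* − 3 nontrivial splits; a bifurcating root's two child
edges induce the same split and are counted once.

Splits are canonicalized to the side **not** containing the
lexicographically smallest taxon label, giving deterministic equality and
hashing. Two splits are compatible iff one of their four side
intersections is empty; a pairwise-compatible split set is laminar after
canonicalization and is assembled into its unique tree bottom-up
(`tree_from_splits`), with unused resolution appearing as polytomies.

Absent branch lengths are recorded as absent, never as zero; PD
computations refuse such trees outright, because silently zeroed edges
corrupt PD rankings.

## Greedy maximum-PD selection

PD of a leaf subset is the total branch length of the minimal unrooted
subtree spanning it (the root junction is traversed but a root edge is
never counted, since guide trees are arbitrarily rooted). Selection starts
from the globally farthest leaf pair — located by a double sweep from the
lexicographically smallest leaf, with ties broken to the smallest label —
and repeatedly appends the leaf with the largest PD increment (ties again
lexicographic). With farthest-pair initialization the greedy prefix of any
size attains the global PD maximum for that size (Steel's optimality
result), and increments are non-increasing after the initial pair; both
properties are tested against exhaustive subset enumeration.

The stopping rule is strict: selection halts when the best available
increment falls *below* the threshold, and the triggering taxon is
excluded. The pipeline default of 0.02 substitutions/site (2 substitutions
per 100 sites) is the study-design value.

## Biclique marker selection

The detection matrix is boolean taxa × genes. A maximal biclique is a
taxon set and gene set whose cross-product is fully detected and to which
no taxon or gene can be added (two-sided maximality). Enumeration uses the
bijection between maximal bicliques and closed gene sets with nonempty
support: a depth-first search over the gene side with LCM-style prefix
pruning, taxon sets as bitmasks. It is verified against an exhaustive
enumeration over all taxon subsets on every 0/1 matrix up to 4×4 and on
random 5×5 matrices. The pipeline's actual selection step is the simpler
`complete_marker_set` (the column-wise AND over the PD-selected taxa),
applied after PD selection — matching the stage order of the study design.

Taxa on an explicit allowlist are unioned in after PD selection and are
exempt from the completeness requirement; their missing genes are
gap-filled. A validator flags any selected gene missing in more than a
configurable number of final taxa (default ceiling 6).

`filter_taxa_by_marker_count` raises when no taxon passes, rather than
returning an empty matrix: a zero-row matrix violates the container's
invariants and every downstream stage would fail less legibly.

## Supermatrix

Concatenation is over an explicit taxon universe; a taxon absent from a
gene is gap-filled with `-` across that gene's range. Partition
coordinates are 0-based half-open internally and written 1-based inclusive
in RAxML-style partition files. Average percent identity is the mean over
unordered sequence pairs of matches divided by mutually ungapped columns;
a flag switches the denominator to the full alignment length (columns
gapped in either sequence then count as mismatches) — the published
per-gene table does not state which convention it used, so both are
provided and neither is asserted as *the* published one. Above 10,000
pairs a seeded uniform pair sample is used.

## Concordance factors and the primary concordance tree

Each gene contributes a `TreeSample` (bootstrap replicates or posterior
draws) whose trees all share one leaf set. Per-gene split frequencies are
exact sample fractions; the CF of a split is its mean frequency across
genes, with replicates weighted equally within a gene and genes equally
across genes. This is the independence-limit ("sample-wide") estimator:
the hierarchical Dirichlet-process machinery of full Bayesian concordance
analysis is deliberately not modelled. On data with many taxa and weak
per-gene signal the prior's concentration parameter has been observed to
leave the concordance-tree topology essentially unchanged, and the
topology is what this pipeline consumes.

Primary concordance tree assembly: sort splits by CF descending; accept a
split iff its CF is at least `cf_floor` and it is compatible with every
already-accepted split. Within a group of equal-CF splits, any candidate
that conflicts with another candidate of the same group is rejected
(conflicts with candidates already excluded by higher-ranked splits do not
count); evidence ties therefore surface as polytomies, never as
hash-order-dependent resolutions. The default `cf_floor` is 0.0 because
published concordance trees retain very low-CF splits.

With a single gene and `cf_floor` 0.5 the primary concordance tree equals
the majority-rule consensus of that gene's sample, except in the measure-
zero case of a split at frequency exactly 0.5 (the consensus's strict `>`
excludes it, the floor's `≥` keeps it). Tests avoid exact ties by using
odd sample sizes or verified seeds.

## Tree comparison

RF is the size of the symmetric difference of nontrivial split sets;
polytomies simply contribute fewer splits. Normalizations (percent of the
two trees' combined split count, or of a caller-supplied reference count)
are exposed but no single convention is hard-coded. Mean pairwise RF over
a replicate sample uses all pairs up to 10,000, then a seeded sample.
Majority-rule consensus keeps splits with frequency strictly above the
threshold (strict consensus at threshold 1.0), guaranteeing compatibility.
The length-vs-RF correlation is an ordinary Pearson r with a two-sided p
(scipy).

## Synthetic data generator

The generator defines the conditions under which the pipeline is tested:

- **Species tree**: Yule topology (uniform random leaf splitting) with
  i.i.d. exponential branch lengths, mean 0.1 substitutions/site — the
  simplest standard null with strictly positive lengths for PD. Labels
  `t0001…`.
- **Gene trees**: each equals the species tree with probability 1 − p,
  else the species tree after a fixed number of random NNI moves. NNI is
  implemented as a child-swap on the unrooted (trifurcating-root)
  representation: swap a random child of the lower edge endpoint with a
  random sibling subtree. Each effective move changes exactly one split
  (RF 2). The parent-side subtree is not used as a swap partner, so the
  neighborhood is a subset of the full NNI neighborhood; for controllable
  discordance this is sufficient and keeps the move local and cheap.
  NNI perturbation rather than coalescent simulation is a deliberate
  choice: the concordance method is agnostic to the biological cause of
  discordance, and NNI gives direct control over RF magnitude.
- **Replicate samples**: each replicate is the gene tree perturbed by
  K ~ Poisson(c / gene_length) NNI moves. The 1/length scaling reproduces
  the published length-variance relationship qualitatively; it does not
  model bootstrap resampling theory.
- **Presence matrix**: i.i.d. Bernoulli missingness.
- **Alignments**: root sequence uniform over the 20 amino acids; along
  each edge every site substitutes to a uniformly chosen different residue
  with probability 1 − exp(−branch length). This is a Jukes–Cantor-style
  toy process, adequate for exercising identity statistics, not a
  realistic protein model.

Default gene count (24), gene lengths (the published panel's alignment
lengths, summing to 4419 columns) and replicate count (500) mirror the
study. Determinism: a master `SeedSequence` spawns per-gene and
per-replicate streams; identical configs produce byte-identical files.

What passing synthetic tests does **not** show: real marker genes violate
every simplification above (non-Yule trees, correlated missingness,
rate heterogeneity, genuinely conflicting histories rather than NNI
neighborhoods), so recovery results here validate the *machinery*, not the
biological adequacy of any inference.

## Pipeline

`run_pipeline` executes, in fixed order: taxon filtering (default: at
least 18 of the panel's markers) → greedy PD selection (default stop
0.02) → allowlist union → complete-marker selection (missing ceiling 6) →
supermatrix assembly → concordance tree (cf_floor 0.0) → comparison
reports. The manifest records parameters, SHA-256 checksums of every
input, per-stage counts and all outputs; it contains no timestamps, so
identical config and seed reproduce it byte-for-byte. Any stage error
aborts with the stage name; the partial manifest is still written with the
abort recorded.

## Problem sizes and numerical choices

Desk-scale checks run at 50 taxa × 24 genes × 500 replicates per gene
(recovery), 20 seeds for expectation-level monotonicity claims, 200 random
tree pairs for the RF oracle, and every 0/1 matrix up to 4×4 plus 100
random 5×5 matrices for the biclique oracle — sizes chosen so the whole
suite completes in a few minutes on one core while still exercising each
combinatorial path exhaustively where exhaustion is feasible. Floating
point: PD and CF comparisons in tests use absolute tolerances ~1e-9;
branch lengths are written with full repr precision so round-trips are
exact. The published full-scale results (multi-hundred-split trees,
average CF ≈ 0.36, per-gene bootstrap RF averages) require the original
841-genome alignments and ~10³ bootstrap replicates per gene and are not
reproduced here; the deposited-tree benchmark hooks (leaf counts, the
318 RF distance, the 800-taxon PD selection) activate when those files are
placed under `data/supplementary/`.

## Known limitations

- The CF estimator ignores between-gene dependence and provides no
  credibility intervals; no population/species-tree estimate is produced.
- The NNI move set is a restricted neighborhood (see above).
- `greedy_max_pd` recomputes distances from the growing subtree each step
  (O(k·n)); fine for thousands of leaves, not optimized for millions.
- Nexus support is read-only and limited to the trees block.
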