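# Methods

## Overview

`melliseq` implements a graph-based single-cell transcriptomics workflow
for whole-organism samples profiled at two developmental stages, plus a
synthetic UMI-count generator with planted ground truth used to validate
every stage by recovery rather than by execution alone.  This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic benchmark does and does not establish about real
data.

## Quality control and normalization

Cells are kept when total UMI count > `qc.min_umi` (default 700) **and**
mitochondrial UMI fraction < `qc.max_mito` (default 0.10); both bounds are
exclusive, so a cell at exactly 700 UMIs or exactly 10% mitochondrial
content is removed.  Genes are kept when detected (count > 0) in at least
`qc.min_cells_per_gene` cells (default 4, i.e. genes in ≤ 3 cells are
dropped).  Cells are filtered before genes; re-running the gene filter on
the reduced cell set can only remove further genes and then stabilizes.
Mitochondrial genes are identified by a configurable regular expression
and/or explicit ID list — there is no default pattern, because insect
mitochondrial gene names do not follow the vertebrate `MT-` convention and
silently matching nothing (or everything) would corrupt the QC silently.

Normalization is ln(1 + count/total × 10⁴) in float64.  The scale factor
(`norm.scale_factor`) is the droplet-convention default; values are exact
zeros wherever counts are zero, and the transform is monotone and
scale-invariant within a cell.

## Variable genes

The default statistic is the binned standardized dispersion: means and
variance-to-mean dispersions are computed on de-logged expression, log
transformed, genes are binned into 20 equal-width bins of log mean, and
dispersions are z-scored within each bin (a bin holding a single gene
z-scores that gene against mean 0 and its own dispersion).  Genes with
normalized dispersion > `hvg.disp_cutoff` (0.5) and mean log expression in
(`hvg.mean_low`, `hvg.mean_high`) = (0.0125, 3) are selected.  This
matches what the classical single-cell toolchains actually compute when a
"standard deviation" cutoff is quoted; a literal plain-standard-deviation
mode (`hvg.method: sd`) is exposed for comparison.  The implementation
delegates to scanpy's Seurat-flavoured routine; the test suite checks its
output against an independent re-derivation of the statistic.

## Covariate regression and scaling

Per gene, ordinary least squares of log expression on an intercept plus
library size and mitochondrial fraction; all genes are solved in one
`lstsq` call against the shared design matrix.  Residuals are standardized
to unit variance (ddof = 1) and clipped to ±10 so single outlier cells
cannot dominate the PCA.  Zero-variance covariates are dropped with a
warning; genes whose residuals are constant become all-zero rows rather
than NaNs.

## PCA and JackStraw

Scores are the cells' coordinates on the top right singular directions of
the scaled cells × genes matrix, computed exactly through the smaller Gram
matrix (no re-centering — rows are already centered gene-wise, which also
caps the usable components at min(n_cells − 1, n_genes)).  Component signs
are fixed so each PC's largest-magnitude gene loading is positive, making
runs reproducible across orderings.

JackStraw significance: in each of `jackstraw.n_reps` (100) replicates a
random `jackstraw.prop` (1%) of gene columns is permuted across cells, the
PCA is recomputed, and the permuted genes' squared loadings are pooled
into a per-PC null.  Each PC's p-value is a one-sided proportion test: the
number of observed squared loadings exceeding the null's 95th percentile
is tested against the 5% null rate (upper-tail binomial).  A rank-based
whole-distribution comparison was considered and rejected: when only a
small subset of genes carries a component, the remaining genes load
*below* the null on that PC and a rank statistic loses power, while the
exceedance proportion remains sensitive.  On pure-noise matrices ~8% of
PCs are selected at α = 0.05 (measured over 20 seeds); a planted
20-gene factor is detected in every seed.

## Cell network and Markov clustering

Pearson correlation between cells' significant-PC profiles defines
similarity; each cell nominates its `cellnet.k` = 20 most similar cells
subject to r ≥ `cellnet.r_min` = 0.77, and an undirected edge exists when
either endpoint nominates the other (union symmetrization).  Ties at the
k-th neighbour break by node order, so construction is deterministic.
Nodes of degree < 3 are removed in a single, non-iterated pass before
clustering.

MCL runs on the weighted adjacency with one self-loop per node, weighted
by the node's maximum incident edge weight (the standard regularization;
isolated nodes get weight 1).  The column-stochastic matrix is iterated —
expansion (power 2), inflation (entrywise power 1.6), renormalization,
pruning of entries < 10⁻⁵ — until the largest entrywise change is below
10⁻⁶ or 200 iterations elapse (non-convergence returns the current state
with a warning).  Clusters are the attractor systems of the converged
matrix; attractor rows sharing members are unioned, and nodes in different
connected components can never share a cluster.  Very high inflation
legitimately collapses toward singletons (the identity matrix is an MCL
fixed point), so "sharper granularity with higher inflation" holds only in
the practical range.

Clusters smaller than `merge.min_size` = 10 are merged, smallest first,
into the neighbouring cluster with the highest summed connecting edge
weight; sizes are re-evaluated after every merge, and small clusters with
no external edges are kept.  Final cluster IDs are contiguous from 1 by
descending size (ties by smallest member name).

## Pseudobulk with artifact filters

For each cell cluster, three zeroing rules silence genes whose in-cluster
evidence is too thin to average: fewer than `pseudobulk.min_cells` = 3
expressing cells, maximum expression < `pseudobulk.min_max` = 0.5, or
detection below `pseudobulk.min_frac` = 5% of the cluster.  "Expressed"
means strictly positive log-normalized value, and the rules are evaluated
on the unfiltered submatrix.  Expression is then capped per gene at the
cluster's 95th percentile (linear interpolation between order statistics,
zeros included; the convention is configurable), damping single-cell
spikes.  Means are finally taken separately per stage within each cluster,
so a mixed-stage cluster yields one column per stage ("stage-
differentiated clusters").  Filters and the cap are computed on the
cluster's pooled cells by default — the stage split enters only at the
averaging step — with a per-stage evaluation mode exposed
(`pseudobulk.per_stage_filters`).  Zeroing before averaging can only lower
column means; this inequality is property-tested.

## Gene coexpression network

Genes with maximum pseudobulk expression > `gcn.min_max` = 0.2 enter the
network; construction reuses the cell-graph machinery with `gcn.k` = 4 and
`gcn.r_min` = 0.7 over the stage-cluster columns.  Louvain community
detection (igraph's multilevel implementation, seeded through Python's
`random` module) optimizes weighted modularity with resolution
`gcn.resolution` = 0.65 — Graphia's "granularity" setting is mapped
to the Louvain resolution parameter as-is, the simplest faithful reading
of an undocumented mapping.  Isolated genes become singleton communities.
The reported modularity is recomputed directly from the returned
assignment, and the test suite cross-checks the two-triangle toy case
against an exhaustive search over all 203 partitions.

## Markers and over-representation

One-vs-rest differential expression per cell cluster (or per
cluster-stage group): genes pass a pre-filter — detected in ≥ 10% of cells
on at least one side and |log₂ fold change| ≥ 0.25, with fold change
computed on de-logged expression with unit pseudocount — then the
two-sided Wilcoxon rank-sum test compares the cluster against all other
cells.  The exact null distribution is enumerated when both groups have
≤ 25 tie-free observations; otherwise the normal approximation with tie
and continuity correction is used (the two agree within 0.02 for group
sizes 8–25, verified over 200 random draws).  P-values are Bonferroni
adjusted over the genes tested within each cluster.

Over-representation of a gene cluster in annotated sets is the upper-tail
hypergeometric probability of the observed overlap, Benjamini–Hochberg
adjusted across sets.  Gene sets are read from GMT; an optional two-column
homolog table translates gene IDs into the annotation's namespace before
intersection, which is how a non-model organism can borrow, e.g., fly
annotation.

## Synthetic data model

Counts follow a gamma-Poisson (negative binomial) model:

    count[c, g] ~ NB(mean = s_c · b_g · f_marker · f_module · f_program,
                     dispersion = 0.5)

* `s_c` — per-cell size factor, log-normal with σ = 0.35, mean 1.
* `b_g` — per-gene baseline, log-normal with log-mean −0.5 and log-sd 1.2,
  giving a median library of ~2,500 UMIs over 2,000 genes so that normal
  cells clear the 700-UMI QC bound with realistic headroom.
* **Markers** — 10 planted cell types (3 specific to stage 1, 5 to stage
  2, 2 shared; ~400 cells per stage) each with 20 disjoint marker genes at
  8-fold elevated mean.
* **Mitochondrial genes** — 10 genes whose baselines are scaled to an
  expected 5% of the library, matching honey bee droplet data; their names
  (`mt-…`) feed the QC mitochondrial pattern.
* **Planted modules** — 4 disjoint modules of 30 genes.  Each module is
  active in a random half of the cell types (mean ratio 4 between active
  and inactive types, symmetric on the log scale) and carries per-cell
  log-normal activity jitter (σ = 0.5), so module genes covary across
  cells and across cell-type aggregates.  The subset-of-types design keeps
  the ground truth identifiable: a module whose activity concentrates on a
  single type is statistically indistinguishable from that type's marker
  set, and no clustering method could (or should) separate them.
* **Background programs** — every remaining gene belongs to one of 8 broad
  coexpression programs with log-normal per-type activity (σ = 0.6) and
  the same per-cell jitter.  Whole-organism transcriptomes have
  essentially no "free" genes — organ-level expression programs span most
  of the genome — and this layer is what makes the coexpression graph
  behave realistically: with only ~12 pseudobulk columns, any two
  independent gene profiles exceed r = 0.7 with probability ≈ 0.006, so
  structureless background genes would attach to planted modules through
  chance correlations alone.  Giving background genes strong partners of
  their own makes each gene's nearest neighbours its genuine program.

Dropout arises naturally from low negative-binomial means; no explicit
zero-inflation is added, which matches the motivation for the pseudobulk
zeroing rules (false zeros from sampling, not from a separate censoring
process).  Fixed seeds give bit-identical output; all draws come from one
`numpy` Generator in a fixed order.

QC-outlier fixtures (`generate_qc_outliers`) append cells violating
exactly one rule each: multinomial cells downsampled to ≤ 700 total UMIs
with normal mitochondrial content, and cells with ~30% mitochondrial mass
at a normal library size.

### What the synthetic benchmark shows — and does not

Recovery results on these conditions (20 seeds, default spec): median
Adjusted Rand Index between MCL cell clusters and planted types ≈ 0.96;
stage-specific types are recovered as single-stage clusters; median
best-match Jaccard between Louvain gene clusters and planted modules
≈ 0.86–0.89.  These establish that the implementation correctly recovers
the structure its own generative model plants at realistic noise levels.
They do not establish performance on real tissue: the generator has no
doublets, no ambient RNA, no batch effects (the emulated study design is
single-batch), no continuous differentiation trajectories, and far fewer
cell types than a real pupa — and with ~12 pseudobulk columns the gene
network operates near the identifiability limit that a real 80-column
dataset does not face.

## Pipeline mechanics

The run directory holds every intermediate artifact in plain formats
(Matrix Market bundles, TSV graphs and tables, one HDF5 AnnData for the
normalized matrix) plus a JSON manifest of per-stage counts and a log.
Each stage reads only on-disk artifacts of earlier stages, so any stage
can be re-run on an existing directory and reproduces its outputs
byte-identically.  One global seed is fanned out to per-stage child seeds
(generator, JackStraw, Louvain) through `numpy.random.SeedSequence`, so
stages are independently reproducible and a full re-run with the same
config is byte-identical.  Configs are validated strictly — unknown keys
are rejected — and the resolved config is echoed into the run directory.

Evaluation utilities (`melliseq.evaluate`) score a run against ground
truth with a fixed 20-PC projection rather than JackStraw selection; this
keeps multi-seed recovery studies fast, and JackStraw calibration is
assessed separately on purpose-built matrices.

## Known limitations

* MCL is dense-ish at desk scale (sparse matrices with pruning); very
  large graphs (≫ 10⁴ nodes) would need a blocked implementation.
* The Wilcoxon exact path enumerates only tie-free small groups; heavily
  tied small samples fall back to the corrected normal approximation.
* The "granularity → resolution" identity mapping for Louvain is a
  convention, not a derived equivalence.
* Pseudobulk columns inherit whatever errors the cell clustering made;
  there is no uncertainty propagation from cluster assignments into the
  gene network.
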