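# Methods

## Scope and data model

The pipeline starts from three inputs: a directed TF→target interaction
table (TSV or SIF) whose per-TF target sets define *regulons*; a gene ×
sample matrix of raw integer counts with per-sample metadata (`subset` ∈
{HE, nonHE, CD43pos}, `genotype` ∈ {WT, KO}, `dox`, `replicate`); and,
optionally, a gene→GO-CC annotation table with a term→supercategory map.
Gene identifiers are upper-cased symbols throughout; TFs are ordinary genes
and may appear in the count matrix. Self-edges are dropped at load time and
duplicate edges collapse.

## Normalization and differential expression

Size factors are median-of-ratios over reference genes (nonzero in every
sample), rescaled so their geometric mean is 1. DE testing is a per-gene
Welch two-sample t-test on log2(normalized count + pseudocount 1.0),
two-sided, with Welch–Satterthwaite degrees of freedom, followed by BH-FDR
across genes. This choice is deliberately transparent and dependency-light
rather than a dispersion-shrinking NB GLM: the package's guarantees are
about calibration and recovery of the downstream regulon statistics, not
about squeezing maximal per-gene power, and a moderated test could be
swapped in behind the same `DEResult` contract. Numerical guards: a floor
of 1e-8 on the squared standard error; genes with zero variance in both
groups and equal means get t = 0, p = 1; genes with all-zero counts across
both groups are dropped before testing and reported as `untested` (they are
excluded from the enrichment universe). Directions: `up` iff q ≤ 0.05 and
log2FC ≥ 1, `down` symmetric, else `nc`; both thresholds configurable.
Under the global-null simulation the observed fraction of genes at
q ≤ 0.05 is far below 0.05 — with n = 3 per group the Welch test on log-NB
counts is mildly conservative, and its p-values are only approximately
uniform (the test suite checks the median Kolmogorov–Smirnov uniformity
p over ten null seeds rather than demanding every seed pass).

## Regulon scoring, signs, and selection

All set-overlap statistics share one hypergeometric core. For a regulon
with m members inside the tested universe of N genes: enrichment p against
the up set (K = |up|) is the upper tail P(X ≥ k_up); analogously for the
down set; depletion is the lower tail P(X ≤ k_up + k_down) against the
combined DE set. The smallest of the three tails sets the dominant
direction (ties break toward the larger overlap count, then toward up).
BH runs across regulons within one contrast — never across contrasts —
on the dominant-direction p. The signed score is −log10(q) for up-dominant
regulons and +log10(q) (a negative number) for down-dominant or depleted
ones, so node color in the exported network reads as "direction of the
regulon members' change". Regulons with fewer than 3 members in the
universe are skipped with a logged reason.

Selection ("functionally relevant") is the conjunction q ≤ 0.05, dominant
overlap ≥ 3 genes, odds ratio ≥ 2, and an enrichment (not depletion)
dominant tail. This rule is this package's own operational definition —
published data-driven selection procedures vary and are often
under-specified — and every constant is a config knob. The universe is the
set of genes tested in the contrast, not all annotated genes: scoring
against never-measured genes inflates enrichment.

The network for a contrast contains the selected TFs plus anchor genes
(default {GATA2}; a missing anchor is kept, unannotated, with a warning)
and every database edge between included nodes. Node attributes: the TF's
own log2FC, its U/NC/D size category (|log2FC| ≥ 0.585, i.e. 1.5-fold,
splits U/D from NC), the signed score, and the selected flag.

## GO category analysis

Categories are scored with the identical hypergeometric core against the
combined DE set over a universe of tested genes carrying ≥ 1 CC annotation
(standard over-representation practice). The smaller of the enrichment and
depletion tails is reported with matching sign after BH across categories.
The category graph keeps categories at q ≤ 0.05 (display filter,
configurable) and joins every pair sharing ≥ 1 universe gene with an edge
weighted by the shared-gene count. Supercategories are an explicit,
user-editable term→class map; the shipped default maps plasma-membrane /
cell-surface / extracellular-matrix terms to `cell_surface` and
cytoskeletal terms to `cytoskeleton`, everything else to `other`. The GO
DAG is *not* traversed: annotations are taken as given, so results depend
on the annotation table's own propagation state.

## Synthetic data generator

The generator emulates the statistical structure of a knockout RNA-seq
study, not its biology. Counts are negative binomial with variance
μ + αμ² (dispersion α), per-gene baselines log-normal around
`baseline_mean` (default median 100–200 counts, log-SD 1), and per-sample
library factors log-uniform in `library_size_range` (default 0.7–1.4).
Differential signal is regulon-structured: an *active regulon* applies a
log2 fold change to a seeded random `fraction_responsive` of its targets
(and, by default, to the TF's own mRNA) in the group-B samples of a named
contrast; `GroundTruth` records exactly the perturbed genes with their
log2FCs and the active (TF, direction) pairs. Everything is driven by one
`numpy` Generator seed: same config and seed give bitwise-identical
matrices.

Interaction databases are generated with regulon sizes from a truncated
negative binomial (shape 5) around `mean_regulon_size`, minimum 3 —
heavy-tailed like curated resources. Target sharing uses a common pool of
`mean_regulon_size` targets sampled per slot with probability
`regulon_overlap`; `overlap = 1.0` is the documented degenerate case where
all regulons share one identical target set. Every one of the `n_targets`
database targets ends up in at least one regulon (leftovers are assigned to
a random TF), so `n_targets` is the database's coverage of the
transcriptome — an important realism knob: if the database covers only a
small fraction of tested genes, DE genes concentrate inside it and *all*
regulons score as enriched against the full universe.

Three canned studies set the conditions used by the tests and the
acceptance script:

- `null_study`: 2,000 genes, 100 TFs (regulons ~20), n = 3/group, no
  active regulons — type-I-error / FDR calibration.
- `recovery_study`: 2,000 genes, 100 TFs (regulons ~50), n = 4/group,
  k fully responsive regulons at log2FC 2 — selection sensitivity and
  false-selection rate.
- `default_study`: 16,000 genes with the database covering 12,000
  (150 TFs, regulons ~80, overlap 0.05), three subsets × WT/KO at
  n = 3/group, 15/16/26 active regulons per contrast at log2FC ±3 with 80%
  responsive targets, dispersion 0.05. These effect sizes are calibrated so
  the *detected* DE sets land in the several-hundred-to-~1,700-gene range
  typical of such studies (smallest in the endothelial subsets, largest in
  CD43⁺ blood).

What the simulations do not model — and what passing tests therefore do
not demonstrate about real data: batch effects, correlated noise between
genes, isoform structure, varying per-gene dispersion, signed
(activation/repression) edge semantics, and database errors (false or
missing edges). In particular, real interaction databases have biased,
incomplete coverage, so false-selection rates on real data will exceed the
simulated ones.

A note on per-gene power: with n = 4 per group the Welch test has ~6
degrees of freedom and its BH-adjusted critical t nearly equals the
noncentrality of a 4-fold change at typical NB noise (sd of log2 counts
≈ 0.5), so per-gene sensitivity at FDR 0.05 is only ~0.2 under the
recovery conditions. The regulon-level statistic aggregates over ~50
targets and recovers the planted TFs essentially perfectly; that
aggregation gain is the method's point.

## Reporting

Marker z-score panels standardize each gene's normalized expression across
samples: (x − row mean) / row sample SD with ddof = 1 (the common heatmap
convention); constant rows become all-zero and are flagged, and panel genes
absent from the matrix are listed, never silently dropped. Shipped default
panels: HE = {RHAG, GFI1, RUNX1, NTS, BMPER}, nonHE = {SOX17, COL15A1,
CAV1, SCG5, EMCN}. Networks and category graphs export to GraphML (full
attributes; NaN-valued attributes are omitted per node), SIF (topology
only, orphan nodes on their own line), and node/edge TSVs. The pipeline
runner validates config keys loudly (unknown keys name themselves in the
error), writes a manifest with versions, seed, config hash and per-stage
row counts, and is deterministic: same config and seed give byte-identical
tables. Problem sizes in the test-suite simulations (2,000-gene calibration
and recovery runs, 10–20 seeds; one 16,000-gene full study in the
acceptance script) were chosen to make the statistical checks stable while
keeping a full run in the order of seconds.
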