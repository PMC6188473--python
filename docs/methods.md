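# Methods

This note documents the statistical procedures `crosscell` implements,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Coordinates and units

All interval types — gene spans, transcripts, peaks, conservation runs,
SNPs — use BED-style 0-based half-open coordinates in memory and on
disk. The single place an inclusive window definition is converted to
this convention is the promoter window (below). Gene length means
genomic span including UTRs; FPKM and TPM are computed over these
whole-gene lengths, deliberately, because nuclear RNA-seq covers
introns and UTR-containing spans better than exon-only models.

## Specificity Index

Inputs are per-sample FPKM values, log10-transformed and floored at 0
(so a long gene with near-zero expression cannot look "specifically
depleted" everywhere), with genes under 1 kb removed (extremely short
genes have unstable FPKM). Per cell type the floored values are
summarized as mean and standard deviation across replicates (sample sd,
ddof = 1; a single replicate yields sd = 0).

For target cell type A, gene g, and each other cell type B, the
difference mean(g,A) − mean(g,B) is ranked across genes in descending
order (rank 1 = most enriched; ties receive average ranks). SI(g,A) is
the mean of g's ranks over all B, and the specificity rank is the
ascending rank of SI (again average ties). Ranking the log-space
difference is the ratio ranking of the classic index applied to floored
log10(FPKM), and is division-safe at the floor.

Replicate uncertainty propagates by resampling: each iteration draws
one value per (gene, cell type) from Normal(mean, sd), re-floors
negative draws at 0 (sampled values stay in the support of the inputs),
recomputes specificity ranks, and the final table averages the
*specificity rank* — not the SI value — over iterations (default 1000).
With all sd = 0 the draws equal the means exactly, so the resampled
table collapses to the deterministic one; this is an exact identity,
used as a test invariant. One seeded generator drives all iterations in
a fixed order, so results are reproducible and independent of any
execution interleaving.

Two open points are resolved as follows and exposed in code rather than
hidden: ranks are computed over *all retained genes* (not only
"expressed" ones), and negative draws are floored (the alternative —
keeping negative draws — changes ranks only for genes tied at the
floor).

Implementation note: average-rank computation is a single argsort plus
vectorized tie-group averaging along the contiguous axis; on the
2000-gene × 1000-iteration arrays this is roughly an order of magnitude
faster than generic ranking routines and exactly equal to them (a test
asserts equality).

## Ortholog harmonization

The transcript-level ortholog table carries one row per orthologous
transcript tuple with a 0/1 confidence flag per species pair. Filters
run in this order, each recorded in an audit log:

1. any confidence = 0 → row dropped;
2. exact duplicate rows dropped;
3. strict 1:1 at the transcript level: a transcript annotated as
   orthologous to more than one transcript in another species removes
   *every* row it participates in, on both sides;
4. per gene, the longest transcript becomes the gene annotation; rows
   collapse to gene tuples, and any gene participating in more than one
   distinct tuple is removed with all its tuples (gene ids must be
   unique per species in the universe — transcript-level 1:1 does not
   by itself imply this);
5. tuples are dropped when the cross-species whole-gene length ratio
   (max/min) exceeds 2 — two-fold annotation-length changes would
   masquerade as expression changes — or when any species' gene span is
   under 1 kb (small RNAs).

Boundary semantics are strict readings of the defining wording: ratio
exactly 2 and length exactly 1000 bp are retained. The survivor set is
tested for exact equality against an independently written row-by-row
oracle on hundreds of random tables, and harmonization is idempotent.

## Differential expression

The engine is a documented stand-in for a DESeq2-style analysis, not a
re-implementation: no dispersion shrinkage, no independent filtering,
no outlier handling. The downstream cascades are engine-agnostic and
accept external DE tables with the same columns.

Per gene: counts ~ NB(μ, α) with log link and offset log s_j, where s_j
are median-of-ratios size factors (reference = per-gene geometric mean
over samples, genes containing zeros excluded from the reference).
Dispersion is method-of-moments on size-factor-normalized counts
pooled within the cells of the categorical covariates,
Var(q) ≈ μ·mean(1/s) + αμ², clipped to [1e-8, 10]. The clip bounds
stabilize Wald standard errors at very small and very large empirical
variances. Coefficients come from vectorized IRLS across all genes
simultaneously (shared design matrix, per-gene weights); the Wald
statistic on the contrast coefficient is referred to a t distribution
with (samples − parameters) degrees of freedom. The t reference is a
small-sample choice: with the dispersion estimated rather than known, a
normal reference is anticonservative at 8–16 replicates, and the t
reference brings the null rejection rate to nominal (measured 0.050 at
p < 0.05 on the homogeneous generator; the acceptance script recomputes
this). Continuous covariates (age in years, post-mortem delay in
hours) enter in raw units. All-zero genes report NA p-values and are
excluded from the Benjamini–Hochberg correction, which otherwise runs
over all tested genes.

When testing a continuous covariate the within-group dispersion pool
includes the covariate's own signal, inflating α for true covariate
genes — a conservative bias of the stand-in worth knowing about when
interpreting covariate scans.

## Species-enrichment cascade

Within each cell type, a gene is called enriched in species S iff
padj < α₁ and log2FC ≥ 2 toward S and baseMean > 400 and mean
log2(FPKM) > 4 in S. α₁ defaults to 1e-5 (the printed "10e-5" literally
equals 1e-4; the stringent reading is the default and the value is
configurable). The pan-species exclusion then removes genes that
differ between species in *all* cell types. Three pan-species modes are
implemented because the defining sentence underdetermines the model:

- `combined` (default): adjusted p from the all-samples species
  contrast (cell type as additive covariate), and the fold condition
  (|log2FC| > 1, consistent sign) in every cell type's own DE table.
- `intersection`: padj and fold both required per cell type. Fragile
  exactly when per-cell-type replication is thin — a genuine
  pan-species gene occasionally misses the stringent padj in one cell
  type and escapes exclusion.
- `blocked`: thresholds on the pooled contrast only. A genuine
  single-cell-type 8-fold gene dilutes to |log2FC| ≈ 3/C there, which
  for C = 3 sits exactly at the fold cutoff, so this mode misclassifies
  cell-type-specific genes as pan-species.

`combined` reads the defining sentence literally (one adjusted p; fold
in all cell types) and is robust on both sides; the recovery rates the
acceptance script reports are computed under it.

Housekeeping genes — the conservation reference — are well expressed in
both species (baseMean > 400, mean log2 FPKM > 4 per species over all
samples) with no evidence of a species difference at raw p > 0.2 (raw,
not adjusted: the set deliberately excludes anything with even weak
evidence).

## Partition-resampling null

For a size-k donor subgroup in an n-donor cohort, every one of the
C(n, k) subsets is contrasted against its complement with the NB engine
and the count of genes at padj < 0.01 recorded. Size factors are
estimated once from the full matrix (they do not depend on labels);
dispersions are re-estimated per partition from that partition's
grouping, as a label-aware analysis would. The full 560-partition scan
at 2000 genes runs in seconds thanks to the vectorized IRLS.

## Single-nucleus validation

Filters run gene-first, then cells, once (no iteration): genes detected
in fewer than 3 cells are dropped, then cells detecting fewer than 300
or more than 5000 genes. Boundaries are strict readings: exactly 3
cells, exactly 300 or 5000 genes are retained. Normalization is global
scaling ln(1 + count/cell_total × 10⁴); natural log follows the
convention of the single-cell toolchain this emulates and the base is
configurable. Detection proportion is the fraction of a cluster's cells
strictly above the threshold (default 1.0 on the normalized scale; a
TPM-based mode exists because published comparisons mix the two
conventions). Gene-set distribution comparisons use ECDFs with the
two-sample Kolmogorov–Smirnov test — the underlying comparison is of
unpaired per-gene metric distributions, for which KS is the standard
nonparametric choice. Depth curves downsample reads *without
replacement* (multivariate hypergeometric — exact for read subsampling
at a fixed depth, unlike binomial thinning), recompute TPM over
whole-gene lengths, and count genes with log2(TPM+1) > 1.1,
equivalently TPM > 2^1.1 − 1 ≈ 1.1435.

## Peaks and conservation

The promoter window is 1 kb upstream to 100 bp downstream of the TSS,
strand-aware; internally [tss−1000, tss+101) on plus strand, mirrored
on minus, clipped at the contig start (width 1101 bp). The TSS is that
of the whole-gene span of the chosen longest-transcript annotation.
Assignment: promoter if ≥1 bp overlap with any window (nearest TSS
breaks ties, then lexicographic gene id), else gene body if overlapping
a gene span (largest overlap, then nearest TSS, then id), else other;
the three categories are mutually exclusive and exhaustive. Unknown
contigs warn and fall to "other" rather than erroring, since peak files
routinely contain scaffolds absent from gene models.

Conservation tracks are run-length encoded per-base scores in [0, 1];
bases not covered by any run score 0, the common convention for missing
PhastCons values (recorded in output metadata). Per-peak conservation
is the arithmetic per-base mean; metagene profiles rescale each peak to
[0, 1], assign base i of an L-base peak to bin ⌊i·n_bins/L⌋, average
per-bin within peak and then across peaks. Group comparisons use the
Welch unequal-variance t-test, one-sided by default with medians
reported; two zero-variance groups with equal means return p = 0.5 by
convention (no evidence either way). Accessibility signal over regions
is FPKM computed from a supplied per-base coverage track (read-level
input is out of scope), log2 with pseudocount 1. The differential-peak
filter retains |fold| strictly greater than 2 and consumes externally
estimated fold changes. SNPs are 1-bp 0-based intervals; containment is
half-open.

## Synthetic data: what it emulates, and what it does not

Bulk counts are gamma-Poisson (negative binomial) with per-gene
dispersion α ~ lognormal(ln 0.04, 0.3) clipped to [1e-6, 0.5], sample
size factors uniform on [0.7, 1.4], and mean
rate_g × length_kb × depth × s_j × 2^(planted effects) — so FPKM-like
units recover rate_g independent of gene length. The default design
mirrors the profiled studies: 2 species × 3 cell types × 8 replicates,
2000 genes, with 20 markers and 50 species-enriched genes per cell
type, 40 pan-species and 200 housekeeping genes, and the planted
species effect at 8-fold (log2 = 3, comfortably above the 4-fold call
threshold so that recovery tests measure method error, not threshold
boundary effects). Planted-class genes are restricted to 3–20 kb so
the baseMean/FPKM expression gates measure calling error rather than
gene-length artifacts; class rates are set so planted genes clear those
gates by construction (e.g. housekeeping rate ~lognormal(ln 40, 0.15)).
Gene models have log-uniform lengths on [200 bp, 50 kb] — guaranteeing
genes below the 1 kb filter — with 1–4 transcripts whose longest equals
the gene span.

The partition cohort generator produces a single-cell-type, 16-donor
matrix, homogeneous by default, optionally planting a fold change on a
chosen donor subset. The single-nucleus generator (6000 genes — above
the 5000 detected-gene bound so over-detection violators exist — 3
clusters × 100 cells, lognormal library sizes, per-gene-per-cell
Bernoulli dropout at 0.3) engineers its filter violators exactly: the
planted low/high cells and rare genes are, by construction, precisely
the entities the filters remove, which is what makes the filter tests
exact rather than statistical. Peak/conservation fixtures place a
500 bp promoter peak inside each expressed gene's promoter window and
draw per-run scores around a class mean, with species-enriched genes
lowered by the configured contrast.

Not emulated: batch effects, GC/length biases within a species,
read-level errors, doublets, ambient RNA, realistic genome sequence,
or inter-gene correlation. Passing recovery tests therefore
demonstrates correctness of the procedures under the stated noise
model, not robustness to artifacts the model omits.

## Determinism and problem sizes

Every generator and every stochastic stage takes an explicit seed; the
pipeline fans a single config seed into named per-stage uses, and
reruns are byte-identical (tested on output checksums). The test suite
and the acceptance script size their simulations to study scale where
the measured property needs it (2000 genes, 8–16 replicates, 560
partitions, 1000 SI iterations) and to smaller instances where the
check is an exact oracle equality, where instance size only adds
runtime, not information.

## Known limitations

- The DE stand-in's moment dispersions are noisier than shrunken
  estimates at 2–4 replicates; the t reference compensates on average
  but per-gene standard errors remain rough at the smallest designs.
- SI p-values (permutation significance of the index) are not
  implemented; the ranking and its resampling stability are.
- Peak calling, differential-accessibility estimation, motif discovery
  and GO enrichment are consumed as inputs or out of scope entirely.
- The harmonizer assumes the ortholog table's transcripts resolve in
  the supplied gene models and fails loudly otherwise.
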