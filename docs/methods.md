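# Methods

This note documents the models, algorithms, defaults and numerical choices
in `tsskit`, and what the synthetic data used by the test suite does and
does not emulate.

## Coordinates and data model

All genomic coordinates are 1-based and closed on both ends (GTF
convention); BED input/output converts to and from 0-based half-open at the
boundary. Transcript coordinates run 1..L along the spliced transcript in
5'→3' orientation, so transcript position 1 is the annotated TSS. The atomic
evidence unit is a *mapped TSS record*: (chromosome, position, count,
strand[, cell barcode]), the tabulated 5' ends of reads. Tables of these
records are the interchange format between alignment extraction and
clustering; extraction from BAM honors CB/UB tags (one count per UMI per
position and cell) and skips unmapped/secondary/supplementary alignments.

## TSS cluster prediction

Per-sample clustering is plain distance ("distclu"-style) chaining:
positions supported by at least `min_pos_count` reads (default 3) on the
same chromosome and strand are chained while consecutive kept positions are
at most `max_gap` bp apart (default 20); chains with total count below
`min_cluster_count` (default 5) are discarded. The dominant TSS of a cluster
is its highest-count position; ties break toward the 5' end in transcript
orientation (most upstream), a documented convention rather than a
principled choice. The defaults are in the range conventional CAGE
clustering tools use; all are exposed in the CLI and config.

Clusters are assigned to the same-strand gene whose span, extended upstream
by a promoter window W = 1,000 bp, contains the cluster's reference point
(dominant position for on-site data, count-weighted center for near-site);
ties between overlapping genes break to the gene with the nearest annotated
transcript start. W matches the 1,000 bp horizon of the near-site
adjustment; unassigned clusters are excluded from usage computations.

## Cross-sample merging (disjoin)

Cluster calls on different samples overlap imperfectly. Pooled intervals are
partitioned at every breakpoint (each input start, and each input end + 1)
into the minimal set of disjoint intervals whose union equals the input
union — disjoin semantics, computed per chromosome and strand; '+' and '−'
clusters never merge. The implementation is a sorted-breakpoint sweep with
binary-searched coverage counts; the test suite checks it against a
brute-force per-position enumeration on random interval sets.

## Near-site adjustment

In single-end 5' libraries the observed Read-2 5' end sits 3' of the genuine
TSS by roughly the cDNA fragment length. The adjustment procedure:

1. **Intronic exclusion.** Near-site clusters whose centers classify as
   intronic indicate transcripts missing from the annotation; the genuine
   TSS cannot be located, so they are excluded. Intergenic centers are kept
   (the rule excludes introns specifically).
2. **Learning.** For every gene with exactly one annotated TSS, the smallest
   distance between any of its near-site cluster centers and that TSS is
   computed *in transcript coordinates* (falling back to genomic distance
   when a center is not exonic on any transcript). Distances above 1,000 bp
   are discarded as likely novel TSSs. The adjustment distance is the mean
   of the per-gene distances weighted by the supporting read counts. The
   1,000 bp filter is applied in transcript coordinates for consistency with
   the intron-aware shift (the choice is unobservable for single-exon genes
   and second-order otherwise).
3. **Shifting.** Each cluster center is projected into transcript
   coordinates of a transcript of its gene containing it (preferring the
   transcript with the most 5' start, which maximizes room to shift),
   moved toward the 5' end by the adjustment distance, clamped at transcript
   position 1, and projected back to the genome. The adjusted cluster keeps
   its original width centered on the new position; width transformation
   under splicing is deliberately not modeled. Centers not exonic in any
   transcript fall back to a genomic-coordinate shift with a warning.

A cluster "center" is the read-count-weighted mean position rounded to the
nearest integer.

In the full pipeline, near-site samples are merged (disjoin) in the
*observed* near-site coordinate space and the unified windows are then
adjusted as a unit. This keeps the counting windows disjoint and preserves
an exact 1:1 mapping between each output (adjusted) cluster and the window
its reads are counted in; adjusting before merging would break that mapping
whenever disjoin splits an adjusted interval.

Not modeled: strand-invasion artifact removal (extra templated G at the 5'
end) and probabilistic fragment-length models; both are known limitations.

## Quantification and usage

For each sample, entry (t, c) of the cluster × cell matrix is the total UMI
count of records from cell c whose position lies inside cluster t (closed
interval, strand-matched). For near-site data the counting windows are the
original near-site intervals while the output rows are the adjusted
clusters. Matrices are stored sparsely and written as MatrixMarket triplets.
Usage of cluster t on a gene is θ_t = x_t / Σ_t x_t, undefined (NaN) when
the gene total is zero. Cell quality control is assumed upstream (filtered
barcodes in, filtered barcodes out).

## Differential usage: binomial GLMM

For one cluster, conditional on the gene totals,

    x_ij ~ Binomial(y_ij, θ_j),  logit(θ_j) = β0 + z_j'β + φ_j,
    φ_j ~ N(0, σ²)

with z_j the K−1 condition dummies (baseline condition all-zeros) plus any
sample-level covariates. Conditioning on y removes differential gene
expression as a confounder. The marginal likelihood integrates φ_j out with
a **Laplace approximation**: the per-sample posterior mode is found by a
damped Newton iteration (the integrand is strictly concave in φ_j, so this
always converges), and the marginal log-likelihood is

    Σ_j [ b_j(φ̂_j) − φ̂_j²/(2σ²) − ½ log(1 + σ² y_j p̂_j (1 − p̂_j)) ]

which is continuous down to σ² = 0, where it reduces to the ordinary
binomial GLM log-likelihood. The outer maximization runs L-BFGS-B over
(β, log σ) with |β| ≤ 30 and log σ ∈ [−6, 3]; the coefficient bound keeps
complete-separation fits finite. Relative function tolerance 1e-10, at most
200 iterations; non-convergence is reported (`converged=False`, p missing),
never silently mapped to p = 1.

**Cell level equals pseudo-bulk.** Within a sample, cells share θ_j, and a
product of Binomial(y_i, θ) pmfs equals the Binomial(Σy_i, θ) pmf of the
sum times a combinatorial factor that does not involve θ. The cell-level
likelihood therefore depends on parameters only through per-sample totals:
the cell-level fit runs on those sufficient statistics (reporting the
cell-level log-likelihood with the per-cell constants added back), and
cell-level and pseudo-bulk LRT p-values agree to machine precision. This is
the exact form of the observed near-identity of the two fits.

**Testing.** The condition effect is tested by a likelihood-ratio χ² with
K−1 df, the null model dropping the condition dummies but keeping covariates
and the random intercept. σ² is a nuisance present under both hypotheses, so
no boundary correction applies to the β test even when σ̂² → 0. Cells with
y_ij = 0 carry no likelihood information and are dropped. The χ² reference
is asymptotic in the number of *samples*: with very few donors per group
(≈5) the test is visibly anti-conservative at the raw 0.05 level (≈0.10 in
our Monte-Carlo checks), a standard property of LRTs with estimated variance
components; at 10 donors per group it is within Monte-Carlo error of
nominal. p-values are Benjamini–Hochberg adjusted across clusters
(missing values excluded from the number of tests).

Before testing, genes are filtered: detection (fraction of cells with a
positive gene total, pooling the compared groups) must be ≥ 10% in *every*
sample (inclusive boundary), and — since usage is only informative with
alternatives — genes with a single cluster are dropped.

**Comparators** (for benchmarking, not recommended for inference):
two-sided Wilcoxon rank-sum on per-cell usage or on per-sample pseudo-bulk
usage; and a distribution-distance permutation test that scores the mean
between-group minus mean within-group Wasserstein-1 distance between
per-sample usage distributions, with p = (1 + #{permuted ≥ observed}) /
(1 + n_perm) over random relabelings (default n_perm = 2,000). Note the
permutation p-value is resolution-limited by the number of distinct label
splits: with 3 samples per group only 10 splits exist, so p < 0.05 is
unattainable regardless of effect size.

## Simulation design

Two conditions, J samples each, I cells per sample, two TSS clusters per
gene. Gene totals are independent negative-binomial counts per cell; per-gene
means are drawn from LogNormal(0, 1) truncated to [0.2, 50] UMI/cell
(emulating a detection-filtered pool of well-expressed genes) and
dispersions from LogNormal(0, 0.5); a configurable fraction of genes
(default 0.2) receives a condition-2 fold change 2^N(0,1) to emulate
confounding differential expression. Moment-fitting the NB pool to a user
count matrix is supported. Gene–gene dependence is deliberately omitted:
every DU test examined operates marginally per gene, so copula structure
does not enter the likelihoods being compared.

Expected usage of cluster 1 in sample j, condition k is a baseline plus a
sample offset, clipped to [0, 1]:

* null genes: a ~ U(0.1, 0.9) shared by both conditions,
  τ ~ (1−π) U(−0.1, 0.1) + (π/2) U(c1, c2) + (π/2) U(−c2, −c1);
* alternative genes: a1 ~ U(0.1, 0.4), a2 = a1 + d with d ~ U(0.1, 0.5),
  τ ~ (1−π) U(−0.1, 0.1) + π U(c1, c2) — the outlier component is one-sided
  positive in *both* conditions, followed literally as specified; a
  symmetric variant is available behind `symmetric_alt_outliers`.

π ∈ {0.1, ..., 0.4} is the donor-outlier frequency and (c1, c2) the outlier
deviation band ((0.1, 0.2) small, (0.2, 0.3) large). Per cell, usage
γ ~ Beta(α_jk, 5) with α_jk = 5 μ_jk/(1 − μ_jk) so E[γ] = μ_jk (μ ∈ {0,1}
degenerates to a point mass), and the cluster-1 count is Binomial(y, γ),
cluster 2 the complement. The Beta stage adds within-sample cell-level
usage dispersion beyond binomial noise.

The benchmark applies each method to every gene's first cluster, BH-adjusts
across genes jointly, and reports type-I error (fraction of null genes
rejected) and power (fraction of alternatives) at adjusted p < 0.05; method
failures count as non-rejections and are tallied. The default problem sizes
used by the test suite and the acceptance script — J up to 10 per group,
I = 100 cells, 500 + 500 genes — are a reduced version of a full benchmark
grid (J up to 25, I up to 500, 1,000 + 1,000 genes), chosen as a desk-scale
working set; the full grid is one YAML file away.

## Evaluation metrics

* **Signed distance**: annotated − predicted on '+', predicted − annotated
  on '−', so positive always means the prediction lies 5' of the annotation.
  Distance distributions are computed on genes with exactly one annotated
  TSS, retain |d| ≤ 500 bp by default, and report mean and sample (n−1) sd.
* **Precision/recall/F1**: per gene, precision is the fraction of predicted
  clusters whose interval overlaps an annotated TSS of the same gene; recall
  the fraction of annotated TSSs contained in a predicted cluster of the
  gene. Sample-level P and R are unweighted means over genes (a gene with no
  predictions contributes recall 0 but no precision term; genes absent from
  the annotation are excluded), and F1 = 2PR/(P+R) with the 0/0 → 0
  convention.
* **Category summaries**: each cluster's reference point is classified as
  5'-most exon / other exon / intron / intergenic against same-strand gene
  models only (a position overlapping just an opposite-strand gene is
  intergenic), and both cluster fractions and read-mass fractions are
  reported.

## Synthetic fixtures: what they do and do not show

The fixture generator builds non-overlapping genes (1–3 exons, mixed
strands, 1–2 true TSSs each) and draws reads with Gaussian positional jitter
(on-site) or |N(mean, sd)| transcript-space displacement projected through
the exon chain (near-site). This exercises every coordinate-handling path —
strand geometry, intron-aware projection, disjoin, per-cell counting — with
exact known truth. It does *not* emulate: mapping errors and multimappers,
strand-invasion artifacts, empirical (non-Gaussian) fragment-length
distributions, overlapping or nested genes, ambient RNA or doublets.
Passing tests therefore certify the algorithms and their contracts, not
performance on any particular real library.

## Reproducibility

Every stochastic component takes an explicit seed (CLI `--seed`, scenario
`seed`); fixed seeds give bit-identical tables, matrices and benchmark
results. The pipeline writes a manifest recording package version,
parameters, seeds and per-stage tallies (records read, clusters excluded,
reads outside clusters), and skips a completed run whose config hash is
unchanged.
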