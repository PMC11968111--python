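# tsskit

Transcription start site (TSS) analysis for 5' single-cell RNA-seq:
per-sample TSS cluster prediction, cross-sample merging, per-cell
quantification, and differential TSS usage (DU) testing with a binomial
generalized linear mixed model.

## Who this is for

5' scRNA-seq libraries place a read end at (or near) the transcription start
of each captured transcript, so they can resolve *which* promoter a gene
uses, per cell, across donors and conditions. `tsskit` is for analysts who
have such data — either **on-site** (paired-end; Read 1's 5' end maps
exactly at the genuine TSS) or **near-site** (single-end; only Read 2
carries cDNA, its 5' end lies a roughly predictable distance 3' of the TSS)
— and want to ask whether the relative usage of a TSS cluster differs
between cell types or patient groups while respecting donor-level
variability.

## The model

For one TSS cluster at a time, let x be its read (UMI) count and y the total
count over all clusters of the same gene. Usage is θ = x / Σx. The DU test
assumes, for cell i in sample j,

    x_ij ~ Binomial(y_ij, θ_j)
    logit(θ_j) = β0 + z_j'β + φ_j,   φ_j ~ N(0, σ²)

where z_j codes the biological condition of sample j and φ_j is a per-sample
random intercept. The condition effect β is tested with a likelihood-ratio
χ² test (K−1 df) of the full against the null model; p-values are
Benjamini–Hochberg adjusted across clusters. The model can be fit per cell
or on per-sample aggregated (pseudo-bulk) counts; because binomials sharing
θ_j aggregate exactly, the two fits give identical p-values (see
`docs/methods.md`). Conditioning on the gene total makes the test robust to
differential gene *expression*, which confounds count-based tests.

For near-site data, clusters of Read-2 5' ends are shifted toward the
genuine TSS by a learned **adjustment distance**: the read-weighted mean
transcript-space gap between near-site cluster centers and annotated TSSs of
single-TSS genes (gaps > 1,000 bp discarded), applied in transcript
coordinates so introns are skipped.

## Worked example

Everything below runs on synthetic data generated by the package itself —
no downloads. Generate two on-site samples with a known annotation, cluster,
merge, quantify and evaluate:

```bash
tsskit fixtures --preset onsite --out fx --seed 7 --n-samples 2
tsskit cluster --table fx/sample1.mapped_tss.tsv --table fx/sample2.mapped_tss.tsv \
               --gtf fx/annotation.gtf --out cl
tsskit merge --clusters cl/sample1.clusters.bed --clusters cl/sample2.clusters.bed \
             --out unified.bed
tsskit quantify --table fx/sample1.mapped_tss.tsv --clusters unified.bed \
                --gtf fx/annotation.gtf --sample-id sample1 --out mat1
tsskit evaluate --clusters cl/sample1.clusters.bed --annot-tss fx/tss.bed \
                --gtf fx/annotation.gtf --out report.tsv
```

which prints

```
onsite fixture (2 samples) written to fx
sample1: 26 clusters -> cl/sample1.clusters.bed
sample2: 26 clusters -> cl/sample2.clusters.bed
51 unified clusters -> unified.bed
sample1: 1366 nonzeros over 51 clusters x 50 cells
P=1.000 R=1.000 F1=1.000 -> report.tsv
```

The 26 per-sample clusters are the synthetic genome's true TSSs (20 genes,
some with two start sites); after pooling and disjoin-merging they become 51
unified, non-overlapping clusters comparable across the two samples; the
quantification step writes a sparse 51 × 50 cluster-by-cell UMI matrix
(MatrixMarket triplet). Precision/recall/F1 of 1.0 means every predicted
cluster overlaps an annotated TSS of its gene and every annotated TSS is
covered — expected here since the fixture jitters read ends by only ~2 bp.

The simulation benchmark measures DU-test operating characteristics on data
with known truth (two clusters per gene; usage shifts d ~ U(0.1, 0.5) for
alternative genes; donor outliers at frequency π):

```bash
printf 'J: 5\nI: 100\nn_null: 100\nn_alt: 100\n' > sc.yaml
tsskit benchmark --methods glmm_bulk,wilcoxon_bulk --seed 3 --scenario sc.yaml --out bench.tsv
```

```
 J   I  pi  c1  c2  seed        method  type1_error  power  n_failed
 5 100 0.1 0.1 0.2     3     glmm_bulk         0.05   0.89         0
 5 100 0.1 0.1 0.2     3 wilcoxon_bulk         0.02   0.73         0
```

`type1_error` is the fraction of null genes (no usage difference) rejected
at BH-adjusted p < 0.05, `power` the fraction of alternative genes detected:
the pseudo-bulk GLMM controls the error rate while clearly out-powering the
rank test at 5 donors per group.

The same functionality is available as a library
(`tsskit.fit_du_bulk`, `tsskit.cluster_tss`, `tsskit.simulate_dataset`, ...);
see the docstrings and `docs/methods.md`.

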