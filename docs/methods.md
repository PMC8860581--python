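# Methods

`epicohort` implements an integrative workflow for discovering co-regulated
gene cohorts in a knockout study that combines bulk RNA-seq over a tissue x
developmental-stage grid with histone-mark ChIP-seq. The motivating system
is PRC2 inactivation (*Eed* conditional knockout) in the developing mouse
CNS, sampled along the anterior–posterior axis (forebrain, midbrain,
hindbrain, spinal cord) across four embryonic stages, with H3K27me3 as the
repressive mark; everything is parameterised, so any two-condition design
with the same shape fits.

The workflow has three stages: (i) differential expression between knockout
and wild type under a fixed contrast plan; (ii) stratification of genes by
expression response crossed with repressive-mark status; (iii) embedding of
per-gene multi-omic profiles with an MMD-regularized variational
autoencoder and extraction of gene cohorts from the tails of each latent
dimension.

## Peak-to-gene assignment

Internal coordinates are 0-based half-open everywhere; NarrowPeak and BED
are native, GTF is converted on read. Peaks are kept only when their
adjusted P-value is below 0.05 (NarrowPeak column 9 read as −log10 q; a
missing value, −1, fails the filter). A peak is assigned to a gene when its
interval intersects the gene's strand-oriented window. Three window presets
exist because marks warrant different rules:

* `promoter_body` (default): 2.5 kb upstream of the TSS through 500 bp past
  the gene end;
* `tss_symmetric`: TSS ± 2.5 kb, used for the marked/unmarked call in the
  stratified analysis;
* `gene_body`: gene body plus 500 bp past the end — the default override
  for H3K36me3, whose signal covers transcribed regions.

Among multiple assigned peaks the one with the greatest signal is kept;
equal signals break ties by smallest start coordinate so results are
deterministic. Genes with no assignment carry signal 0 and width 0.
Chromatin-state segments are assigned when they overlap the TSS ± 10 bp;
with several overlaps the first in file order wins, and uncovered genes are
labelled `NS`.

## Normalization and differential expression

Genes are filtered unless they have ≥ 10 counts in at least half (ceiling)
of the samples. Between-sample scaling uses the trimmed mean of M-values:
the reference is the sample whose upper-quartile/library-size ratio is
closest to the mean of that ratio; per sample, gene-wise log-ratios are
doubly trimmed (30% on M, 5% on A, trimming by sorted position with ties
broken on the other coordinate so the result is invariant to gene order)
and averaged with inverse asymptotic-variance weights; factors are rescaled
to product 1. Expression values are log2(TMM-scaled CPM + 1); the
"expressed" threshold (0.5) applies on the linear TMM-CPM scale.

The contrast plan contains 12 knockout-vs-wild-type comparisons: four
per-tissue contrasts over the three later stages (the earliest stage is
omitted because the repressive mark is largely absent before it) with stage
as batch factor, and eight per-stage contrasts within the anterior (FB, MB)
and posterior (HB, SC) tissue groups with tissue as batch factor.

The built-in DE engine is a deliberately transparent approximation of the
standard NB-GLM Wald workflow. Per gene, an NB2 log-linear model
(condition + batch, log effective-library-size offset) is fitted by IRLS.
Dispersion is estimated in two steps: a per-gene moment estimate solves the
Pearson statistic = residual df by bisection (the statistic is monotone in
the dispersion); the shrinkage centre is a common dispersion matching the
*total* Pearson statistic over all genes to its pooled df — the per-gene
median is biased low by zero-truncation of individual estimates, which
measurably inflates type-I error at 3v3. Each gene's dispersion is shrunk
50% toward that centre (configurable) and floored at 1e−8. The condition
coefficient is Wald-tested against the normal reference and BH-adjusted
within each contrast (significance: padj ≤ 0.05). There is no posterior
fold-change shrinkage and no outlier filtering; result tables from an
external engine can be imported instead.

Measured calibration at the 3v3 settings used in the tests (μ = 100,
dispersion 0.1, 2000 genes): type-I error ≈ 0.06–0.07, p-values uniform by
KS, power > 0.95 for a planted log2FC of 2.

## Stratified labelling

Each gene gets one of six exclusive categories: response ∈ {unaffected,
partly_affected, consistently_affected} × mark ∈ {marked, unmarked}.
Response uses eight designated contrasts (default: the four per-tissue plus
the four anterior-temporal ones; the alternative reading — anterior plus
posterior temporal — is available via `stratification_set`): a gene is
expressed when its mean TMM-CPM over all WT samples or all KO samples
exceeds 0.5 (pooled across tissue and stage); partly affected when
expressed and significant in ≥ 1 of the eight; consistently affected when
additionally |log2FC| > 1 in ≥ 3 of the eight. Marked means a positive
H3K27me3 signal within TSS ± 2.5 kb in FB, MB or HB at the reference stage
(E16.5). The ectopic survey instead uses per-(tissue, stage) group means:
silent (< 0.5) in every WT group and ≥ 0.5 in at least one KO group.

## Profiles and scaling

The embedded genes (default: the consistently affected set) each get a
97-feature profile under the default design: 64 expression features (one
per sample, ordered WT then KO, anterior→posterior, stage, replicate), 21
mark features — log2(signal + 1) over 3 brain tissues × 7 ChIP stages
(E10.5–E16.5); the +1 makes absent peaks exactly 0 — and the 12 contrast
log2 fold changes in plan order. Every column is min-max scaled to [0, 1]
over the embedded gene set (training-set scaling semantics; scaling per
column rather than per block is a documented choice); constant columns map
to 0 and the parameters are kept for the inverse transform. Block sizes
follow the design, so non-default grids produce the corresponding counts.

## The MMD-VAE

The embedding model is an InfoVAE-style autoencoder trained on numpy arrays
with hand-written backpropagation (the network is small enough —
~10² features, ~10³ genes — that this trains in seconds per run on one CPU
core and keeps every step inspectable). Encoder: dense 64 (selu) → 32
(relu) → linear heads for the posterior mean and log-variance of D latent
dimensions (default D = 3). Sampling uses the reparameterization
z = μ + ε·exp(logvar/2). Decoder mirrors the encoder with selu on the
output layer. The per-batch loss is

    MSE(x, x̂) + λ · MMD²(z_batch, prior_batch),   λ = 1,

with the biased V-statistic of squared maximum mean discrepancy under a
Gaussian kernel k(a,b) = exp(−‖a−b‖²/2σ²); the prior batch is drawn from
N(0, I_D) at the training batch size. The kernel bandwidth is unspecified
in the protocol; σ² = D by default (single kernel, so the estimator remains
hand-checkable against the closed form). Optimisation is Adam (β₁ = 0.9,
β₂ = 0.999) at learning rate 0.01 with the classic per-step decay
lr_t = lr/(1 + 0.01·t) (a weight-decay interpretation is available behind
`decay_mode`), 250 epochs, batch size 50, on an 85% training split with the
remainder used for per-epoch validation loss; model selection is simply the
final epoch.

Numerical choices: the log-variance head's bias is initialised at −4 and
log-variances are clipped to [−10, 3]. With a zero init the
reparameterization noise starts at SD 1 — the full scale of the min-max
scaled data — and training reliably collapses to a constant decoder; a
small initial posterior spread is the standard remedy and the clip keeps
the gradient of the clipped region at zero. Weights use Glorot-uniform
init. The split, initialisation, batch order, reparameterization noise and
prior draws all flow from one seeded generator, so training is bit-for-bit
reproducible; inference (`encode`) returns posterior means and is
deterministic.

## Cohorts and downstream statistics

For each latent dimension, the low/high cohorts are genes below/above the
dimension's mean ∓/± 1.25 empirical SDs (2·D cohorts; computing SD
empirically rather than assuming the prior's unit scale is safer for
held-out genes, and both modes are exposed). Cohorts whose members
extensively overlap the union of the other cohorts are pruned iteratively
(drop the cohort with the largest Jaccard-vs-union while it exceeds 0.5 — a
documented default, the original criterion being qualitative). Latent
dimensions are characterised by Spearman correlation against per-gene
summary features, and pairwise latent correlations are reported as a
diagnostic.

Enrichment statistics: two-sided Fisher exact tests for category enrichment
(sample odds ratio ad/bc, optional Haldane correction for display),
one-sided hypergeometric over-representation against user-supplied GMT gene
sets, BH adjustment at α = 0.1, and Mann–Whitney U comparisons (exact null
when the smaller group has ≤ 8 observations and no ties, otherwise the
tie-corrected normal approximation) with Bonferroni correction and the
conventional star bins (NS > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥ *** > 0.0001 ≥
****).

The embedder benchmark scores labelled gene sets with a one-vs-rest
silhouette (per label: that label's genes against all other labelled genes,
Euclidean distance, mean over the label's members). Stochastic embedders
are evaluated over 20 seeded runs at D ∈ {3, 6}; a deterministic PCA
embedder and a seeded random-projection baseline ship built in, and
external methods (tSNE/UMAP/PHATE) plug in through the same
`fit(x, d, seed)` signature without being dependencies.

## Synthetic study conditions

The generator emulates the full design — 2 genotypes × 4 tissues × 4 stages
× 2 replicates = 64 RNA-seq samples — with negative-binomial counts
(Var = μ + αμ²) and six planted archetypes on a single synthetic chromosome
(genes tiled every 20 kb with 5 kb bodies on alternating strands, so strand
handling is always exercised). Default conditions: 150 genes per affected
archetype plus 750 background (1500 genes; background is half the
transcriptome so that the majority-unchanged assumption behind TMM holds),
baseline mean 100 with 0.5 log2 SD across genes, dispersion 0.05, an
anterior–posterior gradient of ±1.5 log2 per tissue step (posterior genes
rising, anterior falling), a stage slope of ±0.75 log2 (development rising,
proliferation falling), knockout effects of +2.5 (posterior, development),
−2.0 (anterior, proliferation) and +2.0 (immune) log2 units, uniform depth
factors in [0.7, 1.3], and lognormal peak signals (log-mean 3, log-SD 0.5)
for the marked archetypes (posterior, anterior, development) in every cell
of the 3-tissue × 7-stage ChIP grid, always intersecting TSS ± 2.5 kb.
ChromHMM-style segments mark bivalent promoters at marked TSSs, enhancer
states at unmarked affected genes, and leave half the background
unannotated. An optional flag doubles a quarter of the genes in one sample
to inject a pure composition shift for normalization tests.

What the generator does *not* emulate: gene-length effects, GC or mappability
bias, overlapping genes, correlated neighbouring genes, partial knockout
penetrance, mark spreading over domains, or replicate-level batch effects.
Passing tests therefore demonstrate that the machinery recovers structure
it is designed to detect under its own statistical assumptions — not
performance on real libraries.

Measured end-to-end behaviour under these conditions (problem sizes chosen
to keep a full run in seconds–minutes on one core): the 750 consistently
affected genes are embedded at D = 3; tail extraction recovers the five
planted archetypes with mean best-match Jaccard ≈ 0.6 across 5 seeds
(five archetypes compete for six tails, and one archetype is occasionally
split or absorbed — the same qualitative behaviour as pruning-worthy
overlapping cohorts in real data).

## Known limitations

* The DE engine approximates but does not replicate any specific external
  implementation (no fold-change shrinkage, no outlier handling); imported
  tables are first-class inputs for parity-critical work.
* The Wald test's small-sample type-I error sits near the top of its
  nominal band at 3 vs 3 replicates; with so few replicates an exact test
  does not exist for estimated dispersions, and users should treat padj
  near the threshold accordingly.
* The silhouette protocol requires uniquely labelled genes and at least two
  genes per label.
* Latent-tail cohorts are non-exclusive by construction; interpretation of
  a dimension requires the correlation table, not the cohort alone.
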