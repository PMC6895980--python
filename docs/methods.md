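# Methods

## Study design being modeled

The pipeline reproduces the analysis pattern of a two-group multi-omics
study of gonadotroph nonfunctioning pituitary adenomas: genome-wide CpG
methylation (Infinium-style β values in [0,1]) and gene-level RNA read
counts measured on the same 32 tumor and 5 normal pituitary samples, with a
larger independent cohort (83 tumors + 5 normals) for targeted validation.
All statistics are two-group comparisons or within-tumor correlations; no
covariates, batch terms, or cell-composition corrections are modeled.

## Differential methylation

Probes are removed when they lie on chrX/chrY, carry SNP-proximity or
multi-mapping flags, or (when a detection-p matrix is supplied) have any
detection p > 0.01. Testing uses M-values, M = log2(β′/(1−β′)) with β′
clipped to [ε, 1−ε], ε = 10⁻⁶ — the logit scale has near-constant variance
where β does not — via a per-probe two-sided Welch t-test and
Benjamini–Hochberg adjustment. The effect screen stays on the β scale,
where Δβ = mean β(tumor) − mean β(normal) is directly interpretable: a DMP
requires |Δβ| > 0.2 (exclusive) and adjusted p ≤ 0.005. The published
protocol this mirrors prints the FDR threshold as "adjusted p > 0.005";
that is read as a ceiling — the opposite reading would select the *least*
significant probes. The moderated (empirical-Bayes) test used by array
pipelines is an extension point; the plain Welch test is self-contained and
desk-verifiable, and the acceptance suite scores recovery rather than
agreement with any particular shrinkage estimator.

Degenerate probes (zero variance in both groups) get p = 1 when the group
means agree and the smallest positive double otherwise. DMP calls may be
restricted to gene-annotated probes (default), since the downstream
analysis concerns gene-associated CpGs.

## Differential expression

Genes are kept when they have ≥ 5 raw reads in ≥ ⌈n/2⌉ samples; the ceiling
is the stricter reading of "at least half" for odd n. Size factors are
median-of-ratios: for each gene with nonzero counts in every sample, the
ratio of each sample's count to the gene's geometric mean; a sample's
factor is the median ratio, and factors are rescaled to geometric mean 1.
Fold change is the ratio of group means of normalized counts with a
pseudocount of 0.5 in numerator and denominator (two all-zero groups give
FC = 1).

The test is a deliberately simple two-group negative-binomial Wald test:
counts are modeled as NB with variance μ + φμ², φ estimated per gene by
method of moments within each group (var(q) ≈ μ·mean(1/s) + φμ² on
normalized counts q), pooled across groups with df weights and floored at
10⁻⁸. The statistic is the log difference of (pseudocounted) group means
over its delta-method standard error, referred to a t distribution with
n − 2 df rather than the normal — at five normal samples the estimated
dispersion makes the normal reference anti-conservative, and the t
reference brings the null type-I error at α = 0.05 to ≈ 0.05–0.06 (measured
in the test suite on 2000 null genes). There is no shrinkage, no outlier
(Cook's) filtering, and no GLM machinery; those belong to production DE
tools, and the point here is a calibrated, transparent stand-in whose null
behavior is itself under test. DEGs require adjusted p < 0.05 and FC > 2 or
FC < 0.5.

## Integration

For each called DMP and each gene it is annotated to (present in the
filtered expression set), Spearman's ρ is computed between the probe's β
values and the gene's normalized counts across the tumor samples only —
the within-tumor cohort is the default because the scientific question is
whether methylation tracks expression among tumors, and the validation-arm
design correlates within the tumor group as well; an all-samples mode
exists. Mid-ranks break ties, p comes from the two-sided t-approximation
with n − 2 df, and constant vectors are skipped (counted in the log).
Emission uses unadjusted p < 0.05, matching the screen this mirrors; a BH
option exists but is off by default.

A probe annotated to one gene under several region labels contributes one
pair, classified by the most promoter-proximal label (priority TSS200 >
TSS1500 > 5′UTR > 1stExon > Body > 3′UTR). Region labels collapse to
promoter = {TSS1500, TSS200, 5′UTR, 1stExon} and body = {Body, 3′UTR};
contexts collapse to island, shelf–shore (any shore or shelf), and open
sea. The body:promoter ratio is reported per correlation sign with a 1-df
chi-square test (no continuity correction) on the 2×2 sign × region table.

Correlated pairs whose probe is a DMP and whose gene is a DEG are
classified by the triple (methylation direction, correlation sign,
expression direction). The expected expression direction is *down* for
(hyper, negative) and (hypo, positive), *up* otherwise; a pair is
concordant when the observed direction matches. The 8 possible triples
split 4/4 and the classification is invariant under the double flip
(hyper↔hypo together with up↔down).

Percentages in reports are rounded half-up to one decimal, matching the
table conventions of the studies this emulates.

## Enrichment

Over-representation only: for each gene set (intersected with the
universe), the hypergeometric upper tail P(overlap ≥ observed) at fixed
margins, BH across sets, significance at adjusted p < 0.05. The universe is
the expression-filtered gene list, not the genome: genes that could never
have entered the query must not inflate significance. Gene symbols match
case-insensitively everywhere (annotation, counts, GMT).

## Validation statistics

Mann–Whitney U is exact (full null enumeration inside scipy) when
n_x·n_y ≤ 400 and the data are tie-free, otherwise normal approximation
with tie correction. Fisher's exact test sums tables with probability ≤
observed at fixed margins. qPCR relative expression is 2^−ΔCT against a
single reference gene. The CpG-panel report takes per-sample
percent-methylation (rescaled from 0–100 to [0,1] on entry) and relative
expression tables and reuses the same Spearman screen per named (CpG,
gene) pair.

## Synthetic cohorts

The generator plants known signal so every stage can be scored:

* **Methylation.** Null probes draw a per-probe baseline mean from
  Beta(0.8, 0.8) (the bimodal shape typical of array β distributions);
  per-sample β values are Beta-distributed around the probe mean with
  concentration 150, i.e. within-group β-sd ≈ 0.04 at β = 0.5 — the scale
  of array replicate scatter in reasonably homogeneous tissue. Planted
  DMPs (5% of probes; 85% hypermethylated) get baselines leaving room for
  the full additive effect (Δβ = 0.35) so mean clipping is never needed;
  the clipped flag in the truth table marks the <1% of null probes whose
  extreme baseline means were clamped away from 0/1.
* **Expression.** Gene base means are log-normal (log2 mean 7, sd 1.5);
  per-sample depth factors are log-normal (sd 0.3, geometric mean 1) and
  recoverable by median-of-ratios; counts are NB with shared dispersion
  0.2 (variance μ + 0.2μ²). Planted DEGs (5% of genes, 4-fold) and coupled
  genes have their base mean floored at 50 so the planted effect is
  observable above the count filter — validated genes in such studies are
  expressed genes.
* **Coupling.** 11% of planted DMPs are coupled to a dedicated gene (70%
  negative). Within tumor samples only, the gene's log2 mean is shifted by
  sign × strength × slope × (β − mean β) with strength 0.8 and slope 25
  log2-units per unit β, putting coupled-pair |ρ| in the 0.4–0.9 range the
  emulated study reports for its significant pairs; strength 0 disables
  coupling exactly. Coupling acts only in tumors because the correlation
  cohort is tumors-only. Each coupled gene is also a DEG whose direction
  is the concordant one with probability 0.85, so the quadrant stage sees
  both concordant and discordant pairs.
* **Annotation.** Region and context labels are drawn from configurable
  mixes (defaults: promoter-class ≈ 42%, body-class ≈ 58%; open sea 50%,
  island 16%, shores/shelves 34%); 5% of probes are intergenic, 2% on sex
  chromosomes, 1% each SNP-flagged and multi-mapping. Planted DMPs avoid
  filtered and intergenic probes.
* **Reproducibility.** All draws come from named substreams spawned in a
  fixed order from one seed, so identical configs are bit-identical and
  enlarging the probe panel does not reshuffle gene-level draws.

What the generator does *not* emulate: detection p-values, batch and
chip effects, cell-type composition, probe cross-hybridization beyond a
boolean flag, correlated probes within regions (each probe is
independent), per-gene dispersion, and library-preparation artifacts.
Passing the recovery suite therefore shows the pipeline recovers clean
planted signal at realistic noise scales and sample sizes — not that it is
robust to the technical structure of real array/sequencing data.

## Problem sizes and defaults

Test and acceptance runs use 2000 probes × 2000 genes with the 32+5
design; the oracle-equivalence suites use 200 random small instances per
primitive; the null-coupling check uses 200 coupled pairs. These sizes give
stable rates (binomial 99% bands on calibration checks) while keeping the
whole suite in seconds.

| parameter | default | meaning |
|---|---|---|
| min_abs_delta_beta | 0.2 | DMP effect floor on \|Δβ\| |
| max_adj_p (DMP) | 0.005 | BH ceiling for DMP calls |
| detection_p_max | 0.01 | probe QC detection-p ceiling |
| min_fc | 2.0 | DEG fold-change threshold (and 1/2 reciprocal) |
| max_adj_p (DEG) | 0.05 | BH ceiling for DEG calls |
| min_reads / min_sample_frac | 5 / 0.5 | low-expression filter |
| alpha (integration) | 0.05 | unadjusted Spearman screen level |
| effect_delta_beta | 0.35 | planted methylation effect |
| deg_fold_change | 4.0 | planted expression effect |
| coupling_strength | 0.8 | scales the β→log-expression slope |
| nb_dispersion | 0.2 | NB dispersion φ |

## Known limitations

The DMP and DEG tests are transparent stand-ins, not re-implementations of
moderated array or GLM-based count pipelines; on real data they will be
less powerful (no variance shrinkage) and less robust (no outlier
handling). The correlation screen is marginal per pair (no multiplicity
control by default, matching the emulated protocol). Region/context
stratification trusts the annotation as given; no genome coordinates are
used beyond the chromosome name. Multi-gene probes contribute one record
per gene, which double-counts probes in gene-pair tallies — the convention
is stated in the composition report's documentation.
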