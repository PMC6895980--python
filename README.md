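# methexpr

Integration of genome-wide CpG methylation with gene expression in a
tumor/normal design, modeled on studies of gonadotroph nonfunctioning
pituitary adenomas (NFPAs): 450K-style β-value arrays on one side, gene-level
RNA read counts on the other, and the question of which differentially
methylated CpGs actually track the expression of their genes.

The package is aimed at method developers and analysts who want a
self-contained, fully tested re-implementation of this integration workflow
that runs end-to-end on synthetic cohorts with planted ground truth — every
stage can be scored for sensitivity and calibration because the generator
knows which probes, genes, and couplings are real.

## What it computes

Given a β matrix (probes × samples, β ∈ [0,1]), a count matrix (genes ×
samples), an HM450-style probe annotation, and a two-group sample sheet:

1. **DMP calling** — probe QC (sex chromosomes, SNP/multi-mapping flags,
   detection p), per-probe Welch t-test on M-values
   (M = log2(β/(1−β))), BH adjustment, and the effect screen on the β scale:
   a DMP has |Δβ| > 0.2 and adjusted p ≤ 0.005, where
   Δβ = mean β(tumor) − mean β(normal). Calls are stratified by direction,
   promoter vs gene body (TSS1500/TSS200/5′UTR/1stExon vs Body/3′UTR), and
   CpG context (island / shelf–shore / open sea).
2. **DEG calling** — low-expression filter (≥5 reads in ≥half the samples),
   median-of-ratios size factors, fold change FC = mean(tumor)/mean(normal)
   on normalized counts, a two-group negative-binomial Wald test with pooled
   method-of-moments dispersion, BH; a DEG has adjusted p < 0.05 and FC > 2
   or FC < 0.5.
3. **Integration** — for each DMP–gene pair, Spearman ρ between β and
   normalized expression across tumor samples; pairs with p < 0.05 are
   eQTM-style records carrying sign, region class, and context class, with a
   body:promoter ratio per sign (χ² test) and narrative summaries.
4. **Concordance quadrants** — correlated pairs that are also DEGs are
   classified by (methylation direction × correlation sign × expression
   direction); a pair is *concordant* when the expression change matches the
   methylation-based prediction (e.g. hypermethylated + negative ρ →
   downregulated).
5. **Enrichment** — hypergeometric over-representation of the correlated
   gene list against GMT collections, with the expression-filtered gene set
   as the universe.
6. **Validation statistics** — Mann–Whitney U (exact when feasible),
   Fisher's exact test, 2^−ΔCT relative expression, and per-CpG Spearman
   panels for targeted validation cohorts.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (32 tumors + 5 normals, 2000 probes/genes, 100 planted DMPs of which
85 hypermethylated, 100 planted 4-fold DEGs, 11 signed couplings):

```
$ python analysis/01_simulate.py
$ python analysis/02_call_dmps.py
77 probes removed by QC filters; 1923 tested
98 DMPs called (|delta beta| > 0.2, FDR <= 0.005)
  hypermethylated: 83 (84.7%)
  hypomethylated:  15 (15.3%)
$ python analysis/03_call_degs.py
1998 of 2000 genes pass the low-expression filter
101 DEGs called (FC > 2.0 or < 0.5, FDR < 0.05): 56 up, 45 down
$ python analysis/04_integrate.py
14 of 98 DMPs correlate with their gene at p < 0.05 (14.3% of tested), covering 14 genes
  negative: 6 (median rho -0.662); positive: 8
8 correlated DMP-DEG pairs; 8 concordant (8 genes, 8 CpGs)
```

Reading: of the 100 planted DMPs, 98 are recovered at the published-style
thresholds with the planted 85/15 hyper/hypo split; the correlation screen
finds the planted couplings (plus the expected ~5% background at α = 0.05),
and every correlated DMP–DEG pair lands in the concordance quadrant its
planted coupling predicts. `analysis/05_enrichment.py` flags only the
DEG-biased synthetic gene sets, and `analysis/06_validation_panel.py`
reproduces a Table-2-style validation report on an independent 83-tumor
cohort (all panel ρ < 0, p < 0.01). Tables land under `results/`; the large
simulated matrices go to `scratch/`.

The same stages are available as a CLI (`methexpr simulate|dmp|deg|
integrate|enrich|validate|run`), with `methexpr run --config config.yaml`
driving the whole pipeline from one YAML file and writing a run manifest.

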