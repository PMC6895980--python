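"""Correlate DMP methylation with gene expression; classify concordance.

The core integration step: for every called DMP annotated to a gene in the
filtered expression set, Spearman-correlate beta with normalized counts
across the tumor samples, keep pairs at p < 0.05, stratify them by
promoter/body and CpG context (body:promoter ratio per correlation sign,
chi-square), overlap with the DEG list, and classify each DMP-DEG pair as
concordant or discordant with the methylation-based prediction.
"""

import json
from pathlib import Path

import pandas as pd

from methexpr import (
    DegThresholds,
    DmpThresholds,
    IntegrationParams,
    correlate_dmps,
    estimate_size_factors,
    filter_low_expression,
    filter_probes,
    integration_summary,
    overlap_with_degs,
    ratio_test,
    read_annotation,
    read_beta_matrix,
    read_counts_matrix,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    meth = read_beta_matrix(COHORT / "beta.tsv", COHORT / "samples.csv")
    expr = read_counts_matrix(COHORT / "counts.tsv", COHORT / "samples.csv")
    annotation = read_annotation(COHORT / "annotation.tsv")
    dmps = pd.read_csv(RESULTS / "dmps.tsv", sep="\t")
    degs = pd.read_csv(RESULTS / "degs.tsv", sep="\t")

    filtered = filter_probes(meth, annotation, DmpThresholds())
    expr_f = estimate_size_factors(filter_low_expression(expr, DegThresholds()))
    params = IntegrationParams()

    corr = correlate_dmps(dmps, filtered, expr_f, annotation, params)
    corr.to_csv(RESULTS / "corr.tsv", sep="\t", index=False)
    quadrants = overlap_with_degs(corr, dmps, degs)
    quadrants.to_csv(RESULTS / "quadrants.tsv", sep="\t", index=False)

    summary = integration_summary(corr, quadrants, n_tested_dmps=len(dmps))
    if {"negative", "positive"} <= set(corr["sign"]):
        rn, rp, chi_p = ratio_test(corr)
        summary["body_promoter_ratio_negative"] = round(rn, 2)
        summary["body_promoter_ratio_positive"] = round(rp, 2)
        summary["ratio_chi2_p"] = chi_p
    with open(RESULTS / "integration_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    print(f"{summary['n_significant_dmps']} of {len(dmps)} DMPs correlate with their "
          f"gene at p < {params.alpha} ({summary.get('pct_significant')}% of tested), "
          f"covering {summary['n_genes']} genes")
    print(f"  negative: {summary['n_negative']} (median rho "
          f"{summary['median_rho_negative']:.3f}); positive: {summary['n_positive']}")
    print(f"{summary['n_pairs']} correlated DMP-DEG pairs; "
          f"{summary['n_concordant_pairs']} concordant "
          f"({summary['n_concordant_genes']} genes, {summary['n_concordant_cpgs']} CpGs)")
    if "ratio_chi2_p" in summary:
        print(f"body:promoter ratio {summary['body_promoter_ratio_negative']} (negative) vs "
              f"{summary['body_promoter_ratio_positive']} (positive), "
              f"chi-square p = {summary['ratio_chi2_p']:.3g}")


if __name__ == "__main__":
    main()
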