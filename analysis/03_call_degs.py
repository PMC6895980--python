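"""Call differentially expressed genes on the simulated cohort.

Applies the low-expression filter (>= 5 reads in >= half the samples),
median-of-ratios normalization, the two-group NB Wald test, and the
FC > 2 or < 0.5 at FDR < 0.05 thresholds.
"""

from pathlib import Path

from methexpr import (
    DegThresholds,
    call_degs,
    estimate_size_factors,
    filter_low_expression,
    read_counts_matrix,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    expr = read_counts_matrix(COHORT / "counts.tsv", COHORT / "samples.csv")
    thresholds = DegThresholds()

    filtered = filter_low_expression(expr, thresholds)
    filtered = estimate_size_factors(filtered)
    degs = call_degs(filtered, thresholds)
    RESULTS.mkdir(exist_ok=True)
    degs.to_csv(RESULTS / "degs.tsv", sep="\t", index=False)
    filtered.size_factors.to_csv(RESULTS / "size_factors.tsv", sep="\t")

    n_up = int((degs["direction"] == "up").sum())
    print(f"{len(filtered.gene_ids)} of {len(expr.gene_ids)} genes pass the "
          f"low-expression filter")
    print(f"size factors span {filtered.size_factors.min():.2f}-"
          f"{filtered.size_factors.max():.2f}")
    print(f"{len(degs)} DEGs called (FC > {thresholds.min_fc} or < "
          f"{1 / thresholds.min_fc:.1f}, FDR < {thresholds.max_adj_p}): "
          f"{n_up} up, {len(degs) - n_up} down")


if __name__ == "__main__":
    main()
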