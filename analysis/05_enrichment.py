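"""Over-representation of methylation-correlated genes in gene sets.

The query is the list of genes whose expression correlates with a DMP; the
universe is every gene that survived the expression filter.  Half of the
synthetic collection's sets were built DEG-biased, so enrichment should
flag (some of) those and none of the uniform-random sets.
"""

from pathlib import Path

import pandas as pd

from methexpr import (
    DegThresholds,
    enrich,
    filter_low_expression,
    read_counts_matrix,
    read_gmt,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    corr = pd.read_csv(RESULTS / "corr.tsv", sep="\t")
    expr = read_counts_matrix(COHORT / "counts.tsv", COHORT / "samples.csv")
    universe = [str(g) for g in filter_low_expression(expr, DegThresholds()).gene_ids]
    collection = read_gmt(COHORT / "gene_sets.gmt")

    query = sorted(set(corr["gene"]))
    records = enrich(query, collection, universe)
    records.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)

    n_sig = int(records["significant"].sum())
    print(f"query: {len(query)} correlated genes; universe: {len(universe)} genes; "
          f"{len(collection)} sets tested")
    print(f"{n_sig} sets significant at adjusted p < 0.05")
    for row in records.head(5).itertuples(index=False):
        print(f"  {row.set_name}: overlap {row.n_overlap}/{row.n_set}, "
              f"p = {row.p:.3g}, adj p = {row.adj_p:.3g}")


if __name__ == "__main__":
    main()
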