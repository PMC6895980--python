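"""Local over-representation analysis of gene lists against GMT collections.

For each gene set, the overlap with the query list is tested with the
hypergeometric upper tail (one-sided Fisher) against a stated gene
universe; p-values are BH-adjusted across sets.  The universe should be
the set of genes that could have entered the query — here, the genes
surviving the expression filter — not the whole genome.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .core_data import DataError, GeneSetCollection

SIGNIFICANCE_ALPHA = 0.05


def enrich(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each set.

    Gene symbols are matched case-insensitively.  Each set is intersected
    with the universe before testing; the p-value is P(overlap >= observed)
    at fixed margins.  Records are BH-adjusted and sorted by p, with
    ``significant`` flagging adjusted p < 0.05.

    Returns columns: set_name, n_set, n_query, n_overlap, overlap_genes,
    p, adj_p, significant.
    """
    universe_set = {g.upper() for g in universe}
    query = {g.upper() for g in query_genes}
    if not universe_set:
        raise DataError("empty universe")
    if not query:
        raise DataError("empty query gene list")
    stray = query - universe_set
    if stray:
        raise DataError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )

    M = len(universe_set)
    n = len(query)
    rows = []
    for name, genes in collection.items():
        in_universe = {g.upper() for g in genes} & universe_set
        K = len(in_universe)
        overlap = sorted(in_universe & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, K, n, k, ";".join(overlap), min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_name", "n_set", "n_query", "n_overlap", "overlap_genes", "p"]
    )
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] < SIGNIFICANCE_ALPHA
    return out.sort_values(["p", "set_name"], ignore_index=True)
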