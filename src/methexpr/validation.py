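"""Validation-arm statistics: targeted methylation / qPCR panels.

Group comparisons use the two-sided Mann–Whitney U test (exact null when
feasible), proportions use Fisher's exact test, qPCR relative expression
uses the 2^-dCT method against a single reference gene, and per-CpG
methylation–expression correlations reuse the Spearman screen on a small
named panel of (CpG, gene) pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataError
from .integration import spearman

#: exact Mann–Whitney null is enumerated when n_x * n_y is at most this
EXACT_MW_LIMIT = 400


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when n_x * n_y <= 400 and the data are
    tie-free; otherwise the normal approximation with tie correction.
    Returns (U statistic for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) * len(y) <= EXACT_MW_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test on a nonnegative-integer 2x2 table.

    The two-sided p sums, at fixed margins, all tables whose hypergeometric
    probability does not exceed the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be nonnegative integers")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """qPCR relative expression by the 2^-dCT method (dCT = target - reference)."""
    return float(2.0 ** -(float(ct_target) - float(ct_reference)))


def validate_cpg_panel(
    meth_table: pd.DataFrame,
    expr_table: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-pair Spearman correlation for a targeted validation panel.

    ``meth_table`` holds per-sample methylation fractions (CpGs x samples,
    values in [0, 1]; percent scales 0–100 are rescaled on entry) and
    ``expr_table`` per-sample relative expression (genes x samples).  Both
    must cover the same samples.  Each (cpg_id, gene) pair yields one row
    with its rho and p.

    Returns columns: cpg_id, gene, rho, p, n.
    """
    meth_table = meth_table.copy()
    if (meth_table.to_numpy() > 1).any():
        meth_table = meth_table / 100.0
    if (meth_table.to_numpy() < 0).any() or (meth_table.to_numpy() > 1).any():
        raise DataError("methylation values must lie in [0, 1] (or 0-100 percent)")
    missing = [s for s in meth_table.columns if s not in expr_table.columns]
    missing += [s for s in expr_table.columns if s not in meth_table.columns]
    if missing:
        raise DataError(f"sample sets differ between tables: {sorted(set(missing))}")
    samples = list(meth_table.columns)
    rows = []
    for cpg_id, gene in pairs:
        if cpg_id not in meth_table.index:
            raise DataError(f"unknown CpG in panel: {cpg_id}")
        if gene not in expr_table.index:
            raise DataError(f"unknown gene in panel: {gene}")
        x = meth_table.loc[cpg_id, samples].to_numpy(dtype=float)
        y = expr_table.loc[gene, samples].to_numpy(dtype=float)
        rho, p = spearman(x, y)
        rows.append((cpg_id, gene, rho, p, len(samples)))
    return pd.DataFrame(rows, columns=["cpg_id", "gene", "rho", "p", "n"])
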