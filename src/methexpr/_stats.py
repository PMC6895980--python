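"""Small shared statistical helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns adjusted p-values (monotone in the raw p, capped at 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    return multipletests(p, method="fdr_bh")[1]


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` (table convention)."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100 * count / total).quantize(q, rounding=ROUND_HALF_UP))
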