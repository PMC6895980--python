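"""Differential expression on gene-level read counts.

Low-expression filtering, median-of-ratios size factors, fold change on
normalized counts, and a per-gene two-group negative-binomial Wald test
with a pooled method-of-moments dispersion estimate.  A differentially
expressed gene (DEG) is one with adjusted p below threshold and fold
change above ``min_fc`` or below ``1/min_fc``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .core_data import DataError, ExpressionSet

DIR_UP = "up"
DIR_DOWN = "down"

#: pseudocount added to group means in fold change and Wald logs
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DegThresholds:
    """Thresholds defining a DEG call.

    ``max_adj_p``: BH-adjusted p ceiling (exclusive).
    ``min_fc``: fold-change floor; genes pass with FC > min_fc or < 1/min_fc.
    ``min_reads`` in at least ``min_sample_frac`` of samples defines the
    low-expression filter on raw counts.
    """

    max_adj_p: float = 0.05
    min_fc: float = 2.0
    min_reads: int = 5
    min_sample_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.min_fc <= 1:
            raise ValueError("min_fc must exceed 1")
        if self.min_reads < 0:
            raise ValueError("min_reads must be nonnegative")


def filter_low_expression(
    expr: ExpressionSet, thresholds: DegThresholds = DegThresholds()
) -> ExpressionSet:
    """Keep genes with >= min_reads raw counts in >= ceil(frac * n) samples."""
    n_needed = math.ceil(thresholds.min_sample_frac * expr.counts.shape[1])
    ok = (expr.counts >= thresholds.min_reads).sum(axis=1) >= n_needed
    return ExpressionSet(expr.counts[ok], expr.samples, expr.size_factors)


def estimate_size_factors(expr: ExpressionSet) -> ExpressionSet:
    """Median-of-ratios per-sample depth factors (attached to a copy).

    For each gene with nonzero counts in every sample, compute the ratio of
    each sample's count to the gene's geometric mean; the sample's factor is
    the median ratio.  Factors are rescaled to geometric mean 1, so exact
    scalar-multiple columns recover their multiples up to a common constant.
    """
    counts = expr.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise DataError("no gene has nonzero counts in all samples")
    sub = counts[all_pos]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    sf = pd.Series(factors, index=expr.counts.columns, name="size_factor")
    return ExpressionSet(expr.counts, expr.samples, sf)


def fold_change(expr: ExpressionSet, pseudocount: float = PSEUDOCOUNT) -> pd.Series:
    """Per-gene tumor/normal ratio of mean normalized counts.

    A pseudocount keeps the ratio finite when a group mean is zero; two
    all-zero groups give FC = 1.
    """
    norm = expr.normalized()
    tumor, normal = expr.samples.tumor_ids, expr.samples.normal_ids
    if not tumor or not normal:
        raise DataError("fold_change requires both tumor and normal samples")
    mt = norm[tumor].mean(axis=1)
    mn = norm[normal].mean(axis=1)
    return (mt + pseudocount) / (mn + pseudocount)


def _group_moments(norm: np.ndarray, inv_sf: np.ndarray):
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    mean_inv_sf = inv_sf.mean()
    return mean, var, mean_inv_sf


def deg_test(expr: ExpressionSet) -> pd.DataFrame:
    """Per-gene two-group negative-binomial Wald test.

    Model: counts ~ NB with mean sf_j * q_group and variance mu + phi mu^2.
    The dispersion phi is a method-of-moments estimate pooled across the two
    groups (df-weighted, floored at 1e-8).  The Wald statistic is the log
    difference of group means over its delta-method standard error; the
    two-sided p uses a t reference with n - 2 degrees of freedom to account
    for the estimated dispersion.  All-zero genes get p = 1.

    Returns columns ``stat``, ``p``, ``mean_tumor``, ``mean_normal``
    (normalized-scale group means), indexed by gene.
    """
    expr.samples.require_two_groups()
    norm = expr.normalized()
    sf = expr.size_factors.to_numpy()
    tumor, normal = expr.samples.tumor_ids, expr.samples.normal_ids
    idx_t = [expr.counts.columns.get_loc(s) for s in tumor]
    idx_n = [expr.counts.columns.get_loc(s) for s in normal]
    xt = norm.iloc[:, idx_t].to_numpy()
    xn = norm.iloc[:, idx_n].to_numpy()
    inv_t, inv_n = 1.0 / sf[idx_t], 1.0 / sf[idx_n]
    nt, nn = len(idx_t), len(idx_n)

    mu_t, var_t, minv_t = _group_moments(xt, inv_t)
    mu_n, var_n, minv_n = _group_moments(xn, inv_n)

    # method-of-moments dispersion per group: var(q) ~ mu*mean(1/sf) + phi*mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_t = (var_t - mu_t * minv_t) / mu_t**2
        phi_n = (var_n - mu_n * minv_n) / mu_n**2
    phi_t = np.where(np.isfinite(phi_t), phi_t, 0.0)
    phi_n = np.where(np.isfinite(phi_n), phi_n, 0.0)
    phi = ((nt - 1) * phi_t + (nn - 1) * phi_n) / (nt + nn - 2)
    phi = np.maximum(phi, 1e-8)

    mu_t_s = mu_t + PSEUDOCOUNT
    mu_n_s = mu_n + PSEUDOCOUNT
    # var of the group mean of normalized counts, then delta method for log
    var_mean_t = (mu_t_s * minv_t + phi * mu_t_s**2) / nt
    var_mean_n = (mu_n_s * minv_n + phi * mu_n_s**2) / nn
    se = np.sqrt(var_mean_t / mu_t_s**2 + var_mean_n / mu_n_s**2)
    stat = (np.log(mu_t_s) - np.log(mu_n_s)) / se
    df = nt + nn - 2
    p = 2 * stats.t.sf(np.abs(stat), df)

    all_zero = (mu_t == 0) & (mu_n == 0)
    stat[all_zero] = 0.0
    p[all_zero] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"stat": stat, "p": p, "mean_tumor": mu_t, "mean_normal": mu_n},
        index=expr.gene_ids,
    )


def call_degs(
    expr: ExpressionSet, thresholds: DegThresholds = DegThresholds()
) -> pd.DataFrame:
    """Call differentially expressed genes.

    BH-adjusts the Wald p over all tested genes, then emits genes with
    adjusted p < ``max_adj_p`` and FC > ``min_fc`` or FC < 1/``min_fc``.

    Returns columns: gene, fold_change, mean_tumor, mean_normal, stat, p,
    adj_p, direction.
    """
    fc = fold_change(expr)
    test = deg_test(expr)
    adj = bh_adjust(test["p"].to_numpy())
    out = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "fold_change": fc.to_numpy(),
            "mean_tumor": test["mean_tumor"].to_numpy(),
            "mean_normal": test["mean_normal"].to_numpy(),
            "stat": test["stat"].to_numpy(),
            "p": test["p"].to_numpy(),
            "adj_p": adj,
        }
    )
    keep = (out["adj_p"] < thresholds.max_adj_p) & (
        (out["fold_change"] > thresholds.min_fc)
        | (out["fold_change"] < 1.0 / thresholds.min_fc)
    )
    out = out[keep].reset_index(drop=True)
    out["direction"] = np.where(out["fold_change"] > 1, DIR_UP, DIR_DOWN)
    return out.sort_values("gene", ignore_index=True)
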