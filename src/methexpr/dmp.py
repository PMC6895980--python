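"""Differential methylation: probe filtering, M-values, delta-beta, DMP calls.

The two-group comparison (tumor vs normal pituitary) tests per-probe
M-values with a Welch t-test and adjusts with Benjamini–Hochberg; the
effect-size screen stays on the beta scale, where a differentially
methylated position (DMP) is a probe with |delta beta| above threshold and
adjusted p at or below the FDR ceiling.  Delta beta is the mean tumor beta
minus the mean normal beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, percent
from .core_data import (
    SEX_CHROMS,
    DataError,
    MethylationSet,
    ProbeAnnotation,
)

logger = logging.getLogger(__name__)

DIR_HYPER = "hyper"
DIR_HYPO = "hypo"

# gene-region labels collapsed to promoter vs gene body
PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
BODY_REGIONS = frozenset({"Body", "3UTR"})

# CpG-context labels collapsed to three strata
CONTEXT_CLASS = {
    "Island": "island",
    "N_Shore": "shelf_shore",
    "S_Shore": "shelf_shore",
    "N_Shelf": "shelf_shore",
    "S_Shelf": "shelf_shore",
    "OpenSea": "open_sea",
}


@dataclass(frozen=True)
class DmpThresholds:
    """Thresholds defining a DMP call.

    ``min_abs_delta_beta``: effect-size floor on |delta beta| (exclusive).
    ``max_adj_p``: BH-adjusted p ceiling (inclusive).
    ``detection_p_max``: per-value detection p ceiling for probe QC.
    """

    min_abs_delta_beta: float = 0.2
    max_adj_p: float = 0.005
    detection_p_max: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.min_abs_delta_beta:
            raise ValueError("min_abs_delta_beta must be positive")
        if self.max_adj_p <= 0 or self.detection_p_max <= 0:
            raise ValueError("p-value thresholds must be positive")


def filter_probes(
    meth: MethylationSet,
    annotation: ProbeAnnotation,
    thresholds: DmpThresholds = DmpThresholds(),
) -> MethylationSet:
    """Remove probes unsuitable for the tumor/normal comparison.

    Discards probes on sex chromosomes, probes flagged as SNP-proximal or
    multi-mapping, and (when a detection matrix is present) probes with any
    detection p above ``detection_p_max``.  Probe order is preserved.
    """
    missing = meth.probe_ids.difference(annotation.probe_ids)
    if len(missing):
        raise DataError(f"probe missing from annotation: {missing[0]}")
    info = annotation.probes.loc[meth.probe_ids]
    keep = (
        ~info["chrom"].isin(SEX_CHROMS)
        & ~info["snp_flag"]
        & ~info["multimap_flag"]
    )
    if meth.detection_p is not None:
        keep &= (meth.detection_p <= thresholds.detection_p_max).all(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_probes: removed %d of %d probes", removed, len(keep))
    return meth.subset_probes(meth.probe_ids[keep.to_numpy()])


def m_values(meth: MethylationSet, epsilon: float = 1e-6) -> pd.DataFrame:
    """Logit2 transform M = log2(beta / (1 - beta)), beta clipped to [eps, 1-eps]."""
    b = meth.beta.clip(lower=epsilon, upper=1 - epsilon)
    return np.log2(b / (1 - b))


def delta_beta(meth: MethylationSet) -> pd.Series:
    """Per-probe mean tumor beta minus mean normal beta."""
    tumor, normal = meth.samples.tumor_ids, meth.samples.normal_ids
    if not tumor or not normal:
        raise DataError("delta_beta requires both tumor and normal samples")
    return meth.beta[tumor].mean(axis=1) - meth.beta[normal].mean(axis=1)


def dmp_test(meth: MethylationSet) -> pd.DataFrame:
    """Per-probe two-sided Welch t-test on M-values.

    Returns a DataFrame with columns ``stat`` and ``p`` indexed by probe.
    Probes constant in both groups get stat 0 and p 1 when the constants
    match; a nonzero mean difference with zero variance in both groups is
    reported at the smallest positive double (the evidence is unbounded).
    """
    meth.samples.require_two_groups()
    m = m_values(meth)
    mt = m[meth.samples.tumor_ids].to_numpy()
    mn = m[meth.samples.normal_ids].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(mt, mn, axis=1, equal_var=False)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: scipy yields nan
    degenerate = np.isnan(stat)
    if degenerate.any():
        equal_means = np.isclose(mt.mean(axis=1), mn.mean(axis=1))
        stat[degenerate & equal_means] = 0.0
        p[degenerate & equal_means] = 1.0
        stat[degenerate & ~equal_means] = np.inf
        p[degenerate & ~equal_means] = np.finfo(float).tiny
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"stat": stat, "p": p}, index=meth.probe_ids)


def call_dmps(
    meth: MethylationSet,
    annotation: ProbeAnnotation,
    thresholds: DmpThresholds = DmpThresholds(),
    restrict_to_annotated: bool = True,
) -> pd.DataFrame:
    """Call differentially methylated positions.

    BH-adjusts the Welch p over all tested probes, then emits probes with
    |delta beta| > ``min_abs_delta_beta`` and adjusted p <= ``max_adj_p``
    (the FDR ceiling).  With ``restrict_to_annotated`` the emitted set is
    limited to probes annotated to at least one gene, mirroring an analysis
    of gene-associated CpGs.

    Returns columns: probe_id, delta_beta, stat, p, adj_p, direction.
    """
    db = delta_beta(meth)
    test = dmp_test(meth)
    adj = bh_adjust(test["p"].to_numpy())
    out = pd.DataFrame(
        {
            "probe_id": meth.probe_ids,
            "delta_beta": db.to_numpy(),
            "stat": test["stat"].to_numpy(),
            "p": test["p"].to_numpy(),
            "adj_p": adj,
        }
    )
    keep = (out["delta_beta"].abs() > thresholds.min_abs_delta_beta) & (
        out["adj_p"] <= thresholds.max_adj_p
    )
    if restrict_to_annotated:
        annotated = set(annotation.gene_map["probe_id"])
        keep &= out["probe_id"].isin(annotated)
    out = out[keep].reset_index(drop=True)
    out["direction"] = np.where(out["delta_beta"] > 0, DIR_HYPER, DIR_HYPO)
    return out.sort_values("probe_id", ignore_index=True)


def composition_report(records: pd.DataFrame, annotation: ProbeAnnotation) -> pd.DataFrame:
    """Stratify DMPs by direction, promoter/body region, and CpG context.

    Direction and CpG-context tallies count each probe once; region tallies
    count one per annotated (gene, region) pair, since a probe may sit in
    the promoter of one gene and the body of another.  Percentages are
    rounded half-up to one decimal.

    Returns columns: stratum, category, count, percent.
    """
    if records.empty:
        raise DataError("composition_report requires a non-empty DMP table")
    rows: list[tuple[str, str, int]] = []

    by_dir = records["direction"].value_counts()
    for cat in (DIR_HYPER, DIR_HYPO):
        rows.append(("direction", cat, int(by_dir.get(cat, 0))))

    ctx = annotation.probes.loc[records["probe_id"], "cpg_context"].map(CONTEXT_CLASS)
    by_ctx = ctx.value_counts()
    for cat in ("island", "shelf_shore", "open_sea"):
        rows.append(("context", cat, int(by_ctx.get(cat, 0))))

    pairs = annotation.gene_map[annotation.gene_map["probe_id"].isin(set(records["probe_id"]))]
    region_class = pairs["region"].map(
        lambda r: "promoter" if r in PROMOTER_REGIONS else "body"
    )
    by_reg = region_class.value_counts()
    for cat in ("promoter", "body"):
        rows.append(("region", cat, int(by_reg.get(cat, 0))))

    out = pd.DataFrame(rows, columns=["stratum", "category", "count"])
    totals = out.groupby("stratum")["count"].transform("sum")
    out["percent"] = [
        percent(c, t) for c, t in zip(out["count"], totals)
    ]
    return out
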