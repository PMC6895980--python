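"""Methylation–expression integration: the core of the pipeline.

For every DMP annotated to a gene present in the expression matrix, the
probe's beta values are correlated (Spearman) with the gene's normalized
counts across tumor samples, producing eQTM-style records.  Significant
pairs are stratified by promoter/body location and CpG context, overlapped
with the DEG list, and classified into concordance quadrants: a pair is
concordant when the tumor/normal expression direction matches the
prediction from the methylation direction combined with the correlation
sign (e.g. hypermethylated + negative correlation -> downregulated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import percent
from .core_data import DataError, ExpressionSet, MethylationSet, ProbeAnnotation
from .dmp import CONTEXT_CLASS, DIR_HYPER, DIR_HYPO
from .expression import DIR_DOWN, DIR_UP

logger = logging.getLogger(__name__)

SIGN_NEG = "negative"
SIGN_POS = "positive"

COHORT_TUMOR_ONLY = "tumor_only"
COHORT_ALL = "all_samples"

#: promoter-proximal priority used when a probe maps to one gene under
#: several region labels
REGION_PRIORITY = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR")


@dataclass(frozen=True)
class IntegrationParams:
    """Settings for the correlation screen.

    ``alpha`` is the unadjusted significance level of the per-pair Spearman
    test.  ``cohort`` selects the samples the correlation runs over; the
    default uses tumor samples only, since the question is whether
    methylation tracks expression within tumors.  ``adjust`` switches the
    screen to BH-adjusted p-values.
    """

    alpha: float = 0.05
    cohort: str = COHORT_TUMOR_ONLY
    adjust: bool = False
    promoter_regions: frozenset = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
    body_regions: frozenset = frozenset({"Body", "3UTR"})

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.cohort not in (COHORT_TUMOR_ONLY, COHORT_ALL):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.promoter_regions & self.body_regions:
            raise ValueError("promoter and body region sets must be disjoint")


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive mid-ranks.  Constant input is an error: rank correlation is
    undefined there, and callers skip such pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("spearman undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _preferred_region(regions: pd.Series) -> str:
    order = {r: i for i, r in enumerate(REGION_PRIORITY)}
    return min(regions, key=lambda r: order[r])


def correlate_dmps(
    dmps: pd.DataFrame,
    meth: MethylationSet,
    expr: ExpressionSet,
    annotation: ProbeAnnotation,
    params: IntegrationParams = IntegrationParams(),
) -> pd.DataFrame:
    """Correlate each DMP's methylation with its annotated genes' expression.

    One record per (probe, gene) pair whose gene is present in the filtered
    expression set; a pair mapping under several region labels is collapsed
    to the most promoter-proximal one.  Pairs with constant methylation or
    expression across the cohort are skipped (counted in the log).  Emitted
    records satisfy p < alpha (or BH-adjusted p < alpha when ``adjust``).

    Returns columns: probe_id, gene, rho, p, sign, region_class,
    context_class.
    """
    if params.cohort == COHORT_TUMOR_ONLY:
        cohort = meth.samples.tumor_ids
    else:
        cohort = meth.samples.sample_ids
    missing = [s for s in cohort if s not in expr.counts.columns]
    if missing:
        raise DataError(f"cohort samples missing from expression set: {missing}")

    norm = expr.normalized()
    beta = meth.beta[cohort]
    norm = norm[cohort]
    gene_index = set(expr.gene_ids)

    pairs = annotation.gene_map[
        annotation.gene_map["probe_id"].isin(set(dmps["probe_id"]))
    ]
    pairs = (
        pairs.groupby(["probe_id", "gene"], sort=True)["region"]
        .agg(_preferred_region)
        .reset_index()
    )

    n_skipped_absent = 0
    n_skipped_constant = 0
    rows = []
    for probe_id, gene, region in pairs.itertuples(index=False):
        if gene not in gene_index:
            n_skipped_absent += 1
            continue
        x = beta.loc[probe_id].to_numpy()
        y = norm.loc[gene].to_numpy()
        try:
            rho, p = spearman(x, y)
        except DataError:
            n_skipped_constant += 1
            continue
        region_class = "promoter" if region in params.promoter_regions else "body"
        context_class = CONTEXT_CLASS[annotation.probes.at[probe_id, "cpg_context"]]
        rows.append((probe_id, gene, rho, p, region_class, context_class))
    if n_skipped_absent or n_skipped_constant:
        logger.info(
            "correlate_dmps: skipped %d pairs with gene absent from expression, "
            "%d with constant values",
            n_skipped_absent,
            n_skipped_constant,
        )
    out = pd.DataFrame(
        rows, columns=["probe_id", "gene", "rho", "p", "region_class", "context_class"]
    )
    if out.empty:
        out["sign"] = pd.Series(dtype=str)
        return out
    if params.adjust:
        from ._stats import bh_adjust

        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out = out[out["adj_p"] < params.alpha].reset_index(drop=True)
    else:
        out = out[out["p"] < params.alpha].reset_index(drop=True)
    out["sign"] = np.where(out["rho"] < 0, SIGN_NEG, SIGN_POS)
    cols = ["probe_id", "gene", "rho", "p", "sign", "region_class", "context_class"]
    if "adj_p" in out.columns:
        cols.append("adj_p")
    return out[cols].sort_values(["probe_id", "gene"], ignore_index=True)


def ratio_test(corr_records: pd.DataFrame) -> tuple[float, float, float]:
    """Body:promoter ratio per correlation sign, with a chi-square test.

    Returns ``(ratio_negative, ratio_positive, chi2_p)`` where each ratio is
    the count of body CpGs over promoter CpGs among records of that sign,
    and the p-value is a 1-df chi-square (no continuity correction) on the
    2x2 sign-by-region table.  A zero promoter count yields ``inf``.
    """
    signs = set(corr_records["sign"])
    if signs != {SIGN_NEG, SIGN_POS}:
        raise DataError("ratio_test requires records of both correlation signs")
    table = pd.crosstab(corr_records["sign"], corr_records["region_class"])
    for col in ("body", "promoter"):
        if col not in table.columns:
            table[col] = 0

    def ratio(sign: str) -> float:
        body = table.at[sign, "body"]
        prom = table.at[sign, "promoter"]
        return float("inf") if prom == 0 else body / prom

    obs = table[["body", "promoter"]].to_numpy()
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return ratio(SIGN_NEG), ratio(SIGN_POS), float(p)


def classify_quadrant(meth_direction: str, corr_sign: str, expr_direction: str) -> bool:
    """Is the observed expression direction the one methylation predicts?

    A negative correlation predicts that hypermethylation lowers expression
    (and hypomethylation raises it); a positive correlation predicts the
    reverse.  Concordant pairs are those whose tumor/normal expression
    change matches that prediction.
    """
    if meth_direction not in (DIR_HYPER, DIR_HYPO):
        raise ValueError(f"bad methylation direction {meth_direction!r}")
    if corr_sign not in (SIGN_NEG, SIGN_POS):
        raise ValueError(f"bad correlation sign {corr_sign!r}")
    if expr_direction not in (DIR_UP, DIR_DOWN):
        raise ValueError(f"bad expression direction {expr_direction!r}")
    if (meth_direction == DIR_HYPER) == (corr_sign == SIGN_NEG):
        expected = DIR_DOWN
    else:
        expected = DIR_UP
    return expr_direction == expected


def overlap_with_degs(
    corr_records: pd.DataFrame, dmps: pd.DataFrame, degs: pd.DataFrame
) -> pd.DataFrame:
    """Join correlated pairs with the DMP and DEG tables.

    Keeps (probe, gene) pairs whose probe is a called DMP and whose gene is
    a called DEG; each surviving pair becomes one quadrant record carrying
    the methylation direction, correlation sign, expression direction, and
    the concordance flag.

    Returns columns: probe_id, gene, meth_direction, corr_sign,
    expr_direction, concordant.
    """
    cols = ["probe_id", "gene", "meth_direction", "corr_sign", "expr_direction", "concordant"]
    if corr_records.empty or dmps.empty or degs.empty:
        return pd.DataFrame(columns=cols)
    merged = corr_records.merge(
        dmps[["probe_id", "direction"]].rename(columns={"direction": "meth_direction"}),
        on="probe_id",
        how="inner",
    ).merge(
        degs[["gene", "direction"]].rename(columns={"direction": "expr_direction"}),
        on="gene",
        how="inner",
    )
    merged = merged.rename(columns={"sign": "corr_sign"})
    merged["concordant"] = [
        classify_quadrant(m, c, e)
        for m, c, e in zip(
            merged["meth_direction"], merged["corr_sign"], merged["expr_direction"]
        )
    ]
    return merged[cols].sort_values(["probe_id", "gene"], ignore_index=True)


def integration_summary(
    corr_records: pd.DataFrame,
    quadrants: pd.DataFrame,
    n_tested_dmps: int | None = None,
) -> dict:
    """Narrative counts for the integration stage.

    Includes the number and percentage (one decimal) of significantly
    correlated DMPs among all tested, the negative/positive split with
    median rho per sign, per-quadrant pair counts, and the concordant CpG
    and gene tallies.  Internal identities (negative + positive = total,
    quadrant counts sum to pair count) hold by construction.
    """
    n_sig = int(corr_records["probe_id"].nunique()) if len(corr_records) else 0
    n_neg = int((corr_records["sign"] == SIGN_NEG).sum()) if len(corr_records) else 0
    n_pos = int((corr_records["sign"] == SIGN_POS).sum()) if len(corr_records) else 0
    summary: dict = {
        "n_significant_dmps": n_sig,
        "n_records": int(len(corr_records)),
        "n_genes": int(corr_records["gene"].nunique()) if len(corr_records) else 0,
        "n_negative": n_neg,
        "n_positive": n_pos,
        "median_rho_negative": float(
            corr_records.loc[corr_records["sign"] == SIGN_NEG, "rho"].median()
        )
        if n_neg
        else float("nan"),
        "median_rho_positive": float(
            corr_records.loc[corr_records["sign"] == SIGN_POS, "rho"].median()
        )
        if n_pos
        else float("nan"),
    }
    if n_tested_dmps is not None:
        summary["n_tested_dmps"] = int(n_tested_dmps)
        summary["pct_significant"] = percent(n_sig, n_tested_dmps) if n_tested_dmps else 0.0

    quad_counts: dict[str, int] = {}
    for meth_dir in (DIR_HYPER, DIR_HYPO):
        for sign in (SIGN_NEG, SIGN_POS):
            key = f"quadrant_{meth_dir}_{sign}"
            if len(quadrants):
                quad_counts[key] = int(
                    (
                        (quadrants["meth_direction"] == meth_dir)
                        & (quadrants["corr_sign"] == sign)
                    ).sum()
                )
            else:
                quad_counts[key] = 0
    summary.update(quad_counts)
    summary["n_pairs"] = int(len(quadrants))
    if len(quadrants):
        conc = quadrants[quadrants["concordant"]]
        summary["n_concordant_cpgs"] = int(conc["probe_id"].nunique())
        summary["n_concordant_genes"] = int(conc["gene"].nunique())
        summary["n_concordant_pairs"] = int(len(conc))
    else:
        summary["n_concordant_cpgs"] = 0
        summary["n_concordant_genes"] = 0
        summary["n_concordant_pairs"] = 0
    return summary
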