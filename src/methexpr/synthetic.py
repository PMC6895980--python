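"""Synthetic paired methylation/expression cohorts with planted ground truth.

The generator emulates a two-group epigenome/transcriptome study of
gonadotroph nonfunctioning pituitary adenomas: 32 tumors and 5 normal
pituitary samples profiled for ~half a million CpG probes (here a few
thousand) and genome-wide read counts.  It plants

* differentially methylated probes (DMPs) whose group means differ by a
  configured delta beta, ~85% hypermethylated in tumors;
* differentially expressed genes (DEGs) with a configured fold change;
* signed couplings between a subset of DMPs and their annotated genes:
  within tumor samples, the gene's log mean expression is a linear (hence
  monotone) function of that sample's beta at the coupled probe, with the
  configured sign (mostly negative) and strength.

Every probe/gene is labelled in a truth table so downstream calls can be
scored for sensitivity and direction agreement.

Randomness is organized as named substreams spawned in a fixed order from
the single seed (annotation, methylation, expression, coupling, noise), so
enlarging the probe panel does not reshuffle the gene draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    GeneSetCollection,
    MethylationSet,
    ExpressionSet,
    ProbeAnnotation,
    SampleSheet,
    write_annotation,
    write_beta_matrix,
    write_counts_matrix,
    write_gmt,
    write_sample_sheet,
)
from .integration import classify_quadrant
from .dmp import DIR_HYPER, DIR_HYPO
from .expression import DIR_DOWN, DIR_UP

# Proportions of probe-to-gene region labels and CpG-context classes,
# roughly matching the HM450 array's gene-annotated design: promoter-class
# labels (TSS1500/TSS200/5UTR/1stExon) and body-class (Body/3UTR) in
# comparable amounts, half of probes in open sea.
DEFAULT_REGION_MIX = {
    "TSS1500": 0.14,
    "TSS200": 0.10,
    "5UTR": 0.12,
    "1stExon": 0.06,
    "Body": 0.48,
    "3UTR": 0.10,
}
DEFAULT_CONTEXT_MIX = {
    "Island": 0.16,
    "N_Shore": 0.11,
    "S_Shore": 0.10,
    "N_Shelf": 0.07,
    "S_Shelf": 0.06,
    "OpenSea": 0.50,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    The defaults mirror the emulated study: 32 tumors vs 5 normals; 85% of
    planted DMPs hypermethylated with delta beta 0.35; 11% of DMPs coupled
    to their gene's expression, 70% of couplings negative; DEGs at 4-fold;
    NB counts with dispersion 0.2.  ``coupling_strength`` in (0, 1] scales
    the within-tumor beta->log-expression slope; 0 disables coupling.
    """

    n_probes: int = 2000
    n_genes: int = 2000
    n_tumor: int = 32
    n_normal: int = 5
    frac_dmp: float = 0.05
    frac_hyper_among_dmp: float = 0.85
    frac_coupled_among_dmp: float = 0.11
    frac_negative_among_coupled: float = 0.70
    effect_delta_beta: float = 0.35
    coupling_strength: float = 0.8
    nb_dispersion: float = 0.2
    frac_deg: float = 0.05
    deg_fold_change: float = 4.0
    frac_concordant_coupling: float = 0.85
    beta_concentration: float = 150.0
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.5
    depth_log_sd: float = 0.3
    frac_intergenic: float = 0.05
    frac_sex_chrom: float = 0.02
    frac_snp_flag: float = 0.01
    frac_multimap_flag: float = 0.01
    coupling_slope: float = 25.0
    region_mix: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    context_mix: dict = field(default_factory=lambda: dict(DEFAULT_CONTEXT_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_dmp",
            "frac_hyper_among_dmp",
            "frac_coupled_among_dmp",
            "frac_negative_among_coupled",
            "frac_deg",
            "frac_concordant_coupling",
            "frac_intergenic",
            "frac_sex_chrom",
            "frac_snp_flag",
            "frac_multimap_flag",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.n_tumor + self.n_normal < 4:
            raise ValueError("need at least 4 samples in total")
        if self.frac_dmp > 0 and self.frac_dmp * self.n_probes < 1:
            raise ValueError("frac_dmp * n_probes < 1: nothing to plant")


@dataclass
class SimulatedDataset:
    meth: MethylationSet
    expr: ExpressionSet
    annotation: ProbeAnnotation
    truth_probes: pd.DataFrame
    truth_genes: pd.DataFrame
    true_size_factors: pd.Series


def _sample_beta(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    a = np.clip(mean, 1e-3, 1 - 1e-3) * conc
    b = conc - a
    return rng.beta(a, b)


def simulate(config: SimConfig) -> SimulatedDataset:
    """Generate a paired cohort; bit-identical for a fixed config."""
    base = np.random.SeedSequence(config.seed)
    # fixed spawn order: annotation, methylation, expression, coupling
    ss_annot, ss_meth, ss_expr, ss_couple = base.spawn(4)
    rng_annot = np.random.default_rng(ss_annot)
    rng_meth = np.random.default_rng(ss_meth)
    rng_expr = np.random.default_rng(ss_expr)
    rng_couple = np.random.default_rng(ss_couple)

    n_p, n_g = config.n_probes, config.n_genes
    probe_ids = np.array([f"cg{i:08d}" for i in range(n_p)])
    gene_ids = np.array([f"GENE{i:05d}" for i in range(n_g)])
    tumor_ids = [f"T{i:03d}" for i in range(config.n_tumor)]
    normal_ids = [f"N{i:03d}" for i in range(config.n_normal)]
    samples = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": tumor_ids + normal_ids,
                "group": ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
            }
        )
    )

    # --- annotation -------------------------------------------------------
    chroms = np.array([f"chr{c}" for c in list(range(1, 23))])
    chrom = chroms[rng_annot.integers(0, len(chroms), n_p)]
    sex = rng_annot.random(n_p) < config.frac_sex_chrom
    chrom[sex] = rng_annot.choice(["chrX", "chrY"], size=int(sex.sum()))
    pos = rng_annot.integers(10_000, 100_000_000, n_p)
    snp_flag = rng_annot.random(n_p) < config.frac_snp_flag
    multimap_flag = rng_annot.random(n_p) < config.frac_multimap_flag
    intergenic = rng_annot.random(n_p) < config.frac_intergenic
    gene_of_probe = rng_annot.integers(0, n_g, n_p)
    region_labels = np.array(list(config.region_mix))
    region_p = np.array(list(config.region_mix.values()), dtype=float)
    region = rng_annot.choice(region_labels, size=n_p, p=region_p / region_p.sum())
    context_labels = np.array(list(config.context_mix))
    context_p = np.array(list(config.context_mix.values()), dtype=float)
    context = rng_annot.choice(context_labels, size=n_p, p=context_p / context_p.sum())

    # --- choose planted probes/genes -------------------------------------
    clean = ~(sex | snp_flag | multimap_flag | intergenic)
    n_dmp = int(round(config.frac_dmp * n_p))
    clean_idx = np.flatnonzero(clean)
    dmp_idx = rng_meth.choice(clean_idx, size=min(n_dmp, len(clean_idx)), replace=False)
    is_dmp = np.zeros(n_p, dtype=bool)
    is_dmp[dmp_idx] = True
    hyper = rng_meth.random(len(dmp_idx)) < config.frac_hyper_among_dmp

    n_coupled = int(round(config.frac_coupled_among_dmp * len(dmp_idx)))
    coupled_order = rng_couple.permutation(len(dmp_idx))[:n_coupled]
    coupled_probe_idx = dmp_idx[coupled_order]
    # coupled probes get distinct dedicated genes so pairs are unambiguous
    coupled_genes = rng_couple.choice(n_g, size=n_coupled, replace=False)
    gene_of_probe[coupled_probe_idx] = coupled_genes
    neg_sign = rng_couple.random(n_coupled) < config.frac_negative_among_coupled

    # --- methylation matrix ----------------------------------------------
    baseline = rng_meth.beta(0.8, 0.8, n_p)
    # planted probes get baselines that leave room for the full effect
    base_hyper = rng_meth.uniform(0.10, 1 - config.effect_delta_beta - 0.05, len(dmp_idx))
    base_hypo = rng_meth.uniform(config.effect_delta_beta + 0.05, 0.90, len(dmp_idx))
    baseline[dmp_idx] = np.where(hyper, base_hyper, base_hypo)
    tumor_mean = baseline.copy()
    effect = np.where(hyper, config.effect_delta_beta, -config.effect_delta_beta)
    tumor_mean[dmp_idx] = baseline[dmp_idx] + effect
    clipped = (tumor_mean < 0.001) | (tumor_mean > 0.999)
    tumor_mean = np.clip(tumor_mean, 0.001, 0.999)

    beta_t = _sample_beta(
        rng_meth,
        np.repeat(tumor_mean[:, None], config.n_tumor, axis=1),
        config.beta_concentration,
    )
    beta_n = _sample_beta(
        rng_meth,
        np.repeat(baseline[:, None], config.n_normal, axis=1),
        config.beta_concentration,
    )
    beta = pd.DataFrame(
        np.hstack([beta_t, beta_n]),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=tumor_ids + normal_ids,
    )
    meth = MethylationSet(beta, samples)

    # --- expression matrix ------------------------------------------------
    base_mean = 2.0 ** rng_expr.normal(config.base_log2_mean, config.base_log2_sd, n_g)
    sf = np.exp(rng_expr.normal(0.0, config.depth_log_sd, config.n_tumor + config.n_normal))
    sf = sf / np.exp(np.mean(np.log(sf)))

    # DEG planting: coupled genes are DEGs whose direction is concordant
    # with (meth direction, coupling sign) most of the time; extra DEGs are
    # drawn from the remaining genes with a 50/50 direction split.
    is_deg = np.zeros(n_g, dtype=bool)
    deg_dir_up = np.zeros(n_g, dtype=bool)
    hyper_of_coupled = hyper[coupled_order]
    for j in range(n_coupled):
        g = coupled_genes[j]
        is_deg[g] = True
        meth_dir = DIR_HYPER if hyper_of_coupled[j] else DIR_HYPO
        sign = "negative" if neg_sign[j] else "positive"
        expected_up = not classify_quadrant(meth_dir, sign, DIR_DOWN)
        concordant = rng_expr.random() < config.frac_concordant_coupling
        deg_dir_up[g] = expected_up if concordant else not expected_up
    n_deg_total = int(round(config.frac_deg * n_g))
    n_extra = max(0, n_deg_total - n_coupled)
    pool = np.flatnonzero(~is_deg)
    extra = rng_expr.choice(pool, size=min(n_extra, len(pool)), replace=False)
    is_deg[extra] = True
    deg_dir_up[extra] = rng_expr.random(len(extra)) < 0.5

    # planted genes get a floor on their base expression so effects are
    # observable above the low-count filter
    planted_genes = np.flatnonzero(is_deg)
    base_mean[planted_genes] = np.maximum(base_mean[planted_genes], 50.0)

    log2fc = np.zeros(n_g)
    log2fc[is_deg & deg_dir_up] = np.log2(config.deg_fold_change)
    log2fc[is_deg & ~deg_dir_up] = -np.log2(config.deg_fold_change)

    # per-sample expected mean: group effect in tumors + beta coupling
    mu = np.repeat(base_mean[:, None], config.n_tumor + config.n_normal, axis=1)
    mu[:, : config.n_tumor] *= 2.0 ** log2fc[:, None]
    for j in range(n_coupled):
        g = coupled_genes[j]
        p_idx = coupled_probe_idx[j]
        b = beta_t[p_idx]
        centered = b - b.mean()
        slope = config.coupling_strength * config.coupling_slope
        sgn = -1.0 if neg_sign[j] else 1.0
        mu[g, : config.n_tumor] *= 2.0 ** (sgn * slope * centered)
    mu = mu * sf[None, :]

    phi = config.nb_dispersion
    if phi > 0:
        r = 1.0 / phi
        counts = rng_expr.negative_binomial(r, r / (r + mu))
    else:
        counts = rng_expr.poisson(mu)
    expr = ExpressionSet(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=tumor_ids + normal_ids),
        samples,
    )

    # --- annotation container --------------------------------------------
    genes_field = np.where(intergenic, "", gene_ids[gene_of_probe])
    probes_df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "cpg_context": context,
            "snp_flag": snp_flag,
            "multimap_flag": multimap_flag,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    mask = genes_field != ""
    gene_map = pd.DataFrame(
        {
            "probe_id": probe_ids[mask],
            "gene": genes_field[mask],
            "region": region[mask],
        }
    ).reset_index(drop=True)
    annotation = ProbeAnnotation(probes_df, gene_map)

    # --- truth tables ------------------------------------------------------
    coupled_gene_col = np.array([""] * n_p, dtype=object)
    coupling_sign_col = np.array([""] * n_p, dtype=object)
    coupled_gene_col[coupled_probe_idx] = gene_ids[coupled_genes]
    coupling_sign_col[coupled_probe_idx] = np.where(neg_sign, "negative", "positive")
    true_dir = np.array([""] * n_p, dtype=object)
    true_dir[dmp_idx] = np.where(hyper, DIR_HYPER, DIR_HYPO)
    truth_probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "is_dmp": is_dmp,
            "true_direction": true_dir,
            "coupled_gene": coupled_gene_col,
            "coupling_sign": coupling_sign_col,
            "clipped": clipped,
        }
    )
    truth_genes = pd.DataFrame(
        {
            "gene": gene_ids,
            "is_deg": is_deg,
            "true_direction": np.where(is_deg, np.where(deg_dir_up, DIR_UP, DIR_DOWN), ""),
            "true_log2_fc": log2fc,
        }
    )
    true_sf = pd.Series(sf, index=tumor_ids + normal_ids, name="size_factor")
    return SimulatedDataset(meth, expr, annotation, truth_probes, truth_genes, true_sf)


def make_gene_sets(
    dataset: SimulatedDataset,
    n_sets: int = 20,
    set_size: int = 40,
    seed: int = 0,
    frac_from_deg: float = 0.5,
) -> GeneSetCollection:
    """Random gene sets over the simulated genes, half of them DEG-biased.

    Sets named ``SET_DEGBIASED_*`` draw ``frac_from_deg`` of their members
    from planted DEGs (so enrichment has signal to find); ``SET_RANDOM_*``
    sets are uniform draws.
    """
    rng = np.random.default_rng(seed)
    genes = dataset.truth_genes["gene"].to_numpy()
    deg_genes = dataset.truth_genes.loc[dataset.truth_genes["is_deg"], "gene"].to_numpy()
    sets: dict[str, frozenset[str]] = {}
    for i in range(n_sets):
        biased = i < n_sets // 2 and len(deg_genes)
        if biased:
            n_deg = min(int(round(frac_from_deg * set_size)), len(deg_genes))
            part1 = rng.choice(deg_genes, size=n_deg, replace=False)
            part2 = rng.choice(genes, size=set_size - n_deg, replace=False)
            members = frozenset(part1) | frozenset(part2)
            name = f"SET_DEGBIASED_{i:02d}"
        else:
            members = frozenset(rng.choice(genes, size=set_size, replace=False))
            name = f"SET_RANDOM_{i:02d}"
        sets[name] = members
    return GeneSetCollection(sets)


def write_fixture(dataset: SimulatedDataset, outdir: str | Path, force: bool = False) -> dict:
    """Write the dataset in the pipeline's plain-text formats.

    Emits beta.tsv, counts.tsv, samples.csv, annotation.tsv, plus the two
    truth tables.  Refuses a non-empty directory unless ``force``.
    Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    paths = {
        "beta": outdir / "beta.tsv",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.csv",
        "annotation": outdir / "annotation.tsv",
        "truth_probes": outdir / "truth_probes.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
    }
    write_beta_matrix(dataset.meth, paths["beta"])
    write_counts_matrix(dataset.expr, paths["counts"])
    write_sample_sheet(dataset.meth.samples, paths["samples"])
    write_annotation(dataset.annotation, paths["annotation"])
    dataset.truth_probes.to_csv(paths["truth_probes"], sep="\t", index=False)
    dataset.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
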