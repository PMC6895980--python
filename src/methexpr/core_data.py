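"""Domain containers and plain-text I/O for the methylation–expression pipeline.

All matrices travel as tab-delimited text (features in rows, samples in
columns).  The probe annotation emulates the HumanMethylation450 manifest
dialect: per-probe semicolon-separated parallel lists of gene symbols and
gene-region labels, a CpG-context class, and SNP / multi-mapping flags.
Gene sets use the standard GMT format.

Containers are thin dataclasses around :class:`pandas.DataFrame`; validation
happens at construction so downstream stages can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

GROUP_TUMOR = "tumor"
GROUP_NORMAL = "normal"
GROUPS = (GROUP_TUMOR, GROUP_NORMAL)

REGION_LABELS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
CONTEXT_LABELS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


class DataError(ValueError):
    """Raised when an input file or container violates the format contract."""


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-group assignment (two-group tumor/normal design).

    Parameters
    ----------
    table:
        DataFrame with columns ``sample_id`` and ``group`` (values
        ``"tumor"`` / ``"normal"``).  Sample ids must be unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sample_id", "group"} - set(self.table.columns)
        if missing:
            raise DataError(f"sample sheet missing columns: {sorted(missing)}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise DataError(f"duplicate sample ids: {dups}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise DataError(f"unknown group labels: {sorted(bad)} (expected {GROUPS})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def tumor_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["group"] == GROUP_TUMOR, "sample_id"])

    @property
    def normal_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["group"] == GROUP_NORMAL, "sample_id"])

    def require_two_groups(self, min_per_group: int = 2) -> None:
        """Raise unless both groups are present with at least ``min_per_group``."""
        nt, nn = len(self.tumor_ids), len(self.normal_ids)
        if nt < min_per_group or nn < min_per_group:
            raise DataError(
                f"two-group operation needs >= {min_per_group} samples per group, "
                f"got tumor={nt}, normal={nn}"
            )

    def __len__(self) -> int:
        return len(self.table)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str)
    return SampleSheet(df[["sample_id", "group"]])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe-level genomic annotation plus the expanded probe->gene map.

    ``probes`` is indexed by probe id with columns ``chrom``, ``pos``,
    ``cpg_context``, ``snp_flag``, ``multimap_flag``.  ``gene_map`` holds one
    row per (probe, gene, region) triple; intergenic probes have no rows
    there.  Gene symbols are stored uppercased so that matching against count
    matrices and GMT files is case-insensitive.
    """

    probes: pd.DataFrame
    gene_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.probes.index.duplicated().any():
            dups = sorted(self.probes.index[self.probes.index.duplicated()].unique())
            raise DataError(f"duplicate probe ids in annotation: {dups[:5]}")
        bad_ctx = set(self.probes["cpg_context"]) - set(CONTEXT_LABELS)
        if bad_ctx:
            raise DataError(f"unknown CpG context labels: {sorted(bad_ctx)}")
        if len(self.gene_map):
            bad_reg = set(self.gene_map["region"]) - set(REGION_LABELS)
            if bad_reg:
                raise DataError(f"unknown region labels: {sorted(bad_reg)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    def genes_for(self, probe_id: str) -> list[tuple[str, str]]:
        """(gene, region) pairs annotated to a probe (empty if intergenic)."""
        sub = self.gene_map[self.gene_map["probe_id"] == probe_id]
        return list(zip(sub["gene"], sub["region"]))

    def subset(self, probe_ids: Iterable[str]) -> "ProbeAnnotation":
        ids = pd.Index(probe_ids)
        return ProbeAnnotation(
            self.probes.loc[ids],
            self.gene_map[self.gene_map["probe_id"].isin(set(ids))].reset_index(drop=True),
        )


def _parse_bool(series: pd.Series, col: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    vals = series.astype(str).str.strip().str.lower().map(mapping)
    if vals.isna().any():
        bad = series[vals.isna()].iloc[0]
        raise DataError(f"non-boolean value {bad!r} in column {col}")
    return vals.astype(bool)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read the manifest-dialect annotation TSV.

    The ``genes`` and ``regions`` columns carry semicolon-separated parallel
    lists; they are expanded into one (probe, gene, region) row each, with
    exact duplicate triples collapsed.  Unequal list lengths are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "chrom", "pos", "genes", "regions",
                "cpg_context", "snp_flag", "multimap_flag"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"annotation missing columns: {sorted(missing)}")

    probes = pd.DataFrame(
        {
            "chrom": df["chrom"].values,
            "pos": pd.to_numeric(df["pos"]).astype(int).values,
            "cpg_context": df["cpg_context"].values,
            "snp_flag": _parse_bool(df["snp_flag"], "snp_flag").values,
            "multimap_flag": _parse_bool(df["multimap_flag"], "multimap_flag").values,
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )

    rows: list[tuple[str, str, str]] = []
    for probe_id, genes_field, regions_field in zip(df["probe_id"], df["genes"], df["regions"]):
        genes = [g for g in genes_field.split(";") if g] if genes_field else []
        regions = [r for r in regions_field.split(";") if r] if regions_field else []
        if len(genes) != len(regions):
            raise DataError(
                f"probe {probe_id}: gene list ({len(genes)}) and region list "
                f"({len(regions)}) have unequal lengths"
            )
        for g, r in zip(genes, regions):
            rows.append((probe_id, g.upper(), r))
    gene_map = pd.DataFrame(rows, columns=["probe_id", "gene", "region"])
    gene_map = gene_map.drop_duplicates(ignore_index=True)
    return ProbeAnnotation(probes, gene_map)


def write_annotation(annot: ProbeAnnotation, path: str | Path) -> None:
    grouped = annot.gene_map.groupby("probe_id")
    genes = grouped["gene"].agg(";".join) if len(annot.gene_map) else pd.Series(dtype=str)
    regions = grouped["region"].agg(";".join) if len(annot.gene_map) else pd.Series(dtype=str)
    out = annot.probes.copy()
    out.insert(2, "genes", genes.reindex(out.index, fill_value=""))
    out.insert(3, "regions", regions.reindex(out.index, fill_value=""))
    out.to_csv(path, sep="\t", index=True, index_label="probe_id")


# ---------------------------------------------------------------------------
# Methylation / expression containers
# ---------------------------------------------------------------------------

@dataclass
class MethylationSet:
    """Beta-value matrix (probes x samples) with its sample sheet.

    Beta values are methylation fractions in [0, 1].  An optional detection
    p-value matrix of the same shape supports probe-level quality filtering.
    """

    beta: pd.DataFrame
    samples: SampleSheet
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.beta.columns) != self.samples.sample_ids:
            sheet = set(self.samples.sample_ids)
            cols = set(self.beta.columns)
            only_sheet = sorted(sheet - cols)
            only_matrix = sorted(cols - sheet)
            if only_sheet or only_matrix:
                raise DataError(
                    f"sample mismatch between beta matrix and sheet: "
                    f"missing from matrix {only_sheet}, missing from sheet {only_matrix}"
                )
            self.beta = self.beta[self.samples.sample_ids]
        vals = self.beta.to_numpy()
        if np.isnan(vals).any():
            bad = self.beta.index[np.isnan(vals).any(axis=1)][0]
            raise DataError(f"missing beta value at probe {bad}")
        if (vals < 0).any() or (vals > 1).any():
            bad = self.beta.index[((vals < 0) | (vals > 1)).any(axis=1)][0]
            raise DataError(f"beta value outside [0, 1] at probe {bad}")
        if self.detection_p is not None and self.detection_p.shape != self.beta.shape:
            raise DataError("detection_p shape differs from beta matrix")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    def tumor_beta(self) -> pd.DataFrame:
        return self.beta[self.samples.tumor_ids]

    def normal_beta(self) -> pd.DataFrame:
        return self.beta[self.samples.normal_ids]

    def subset_probes(self, probe_ids: Iterable[str]) -> "MethylationSet":
        ids = pd.Index(probe_ids)
        det = self.detection_p.loc[ids] if self.detection_p is not None else None
        return MethylationSet(self.beta.loc[ids], self.samples, det)


@dataclass
class ExpressionSet:
    """Raw read-count matrix (genes x samples) with optional size factors.

    Counts are nonnegative integers.  ``size_factors`` (per-sample positive
    reals) are attached by normalization; ``normalized()`` divides each column
    by its factor.  Gene symbols are uppercased on construction so joins with
    the annotation are case-insensitive.
    """

    counts: pd.DataFrame
    samples: SampleSheet
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.index = self.counts.index.astype(str).str.upper()
        if list(self.counts.columns) != self.samples.sample_ids:
            sheet = set(self.samples.sample_ids)
            cols = set(self.counts.columns)
            only_sheet = sorted(sheet - cols)
            only_matrix = sorted(cols - sheet)
            if only_sheet or only_matrix:
                raise DataError(
                    f"sample mismatch between count matrix and sheet: "
                    f"missing from matrix {only_sheet}, missing from sheet {only_matrix}"
                )
            self.counts = self.counts[self.samples.sample_ids]
        vals = self.counts.to_numpy()
        if np.isnan(vals.astype(float)).any():
            raise DataError("missing values in count matrix")
        if (vals < 0).any():
            bad = self.counts.index[(vals < 0).any(axis=1)][0]
            raise DataError(f"negative count at gene {bad}")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = self.counts.index[(vals != np.round(vals)).any(axis=1)][0]
                raise DataError(f"non-integer count at gene {bad}")
            self.counts = self.counts.astype(np.int64)
        if self.size_factors is not None:
            self.size_factors = self.size_factors.reindex(self.counts.columns)
            if self.size_factors.isna().any() or (self.size_factors <= 0).any():
                raise DataError("size factors must be positive for every sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def normalized(self) -> pd.DataFrame:
        """Counts divided by per-sample size factors."""
        if self.size_factors is None:
            raise DataError("size factors not set; run estimate_size_factors first")
        return self.counts / self.size_factors

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionSet":
        ids = pd.Index([g.upper() for g in gene_ids])
        return ExpressionSet(self.counts.loc[ids], self.samples, self.size_factors)


# ---------------------------------------------------------------------------
# Matrix readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index.name = index_name
    df = raw.apply(pd.to_numeric, errors="coerce")
    bad = df.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric cell at row {raw.index[r]!r}, column {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    return df


def read_beta_matrix(path: str | Path, sample_sheet_path: str | Path) -> MethylationSet:
    """Load a beta matrix TSV against a sample sheet CSV."""
    sheet = read_sample_sheet(sample_sheet_path)
    beta = _read_matrix(path, "probe_id")
    return MethylationSet(beta, sheet)


def write_beta_matrix(meth: MethylationSet, path: str | Path) -> None:
    meth.beta.to_csv(path, sep="\t", index_label="probe_id")


def read_counts_matrix(path: str | Path, sample_sheet_path: str | Path) -> ExpressionSet:
    """Load a gene-level read-count TSV against a sample sheet CSV."""
    sheet = read_sample_sheet(sample_sheet_path)
    counts = _read_matrix(path, "gene")
    return ExpressionSet(counts, sheet)


def write_counts_matrix(expr: ExpressionSet, path: str | Path) -> None:
    expr.counts.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets; names unique, every set non-empty, symbols uppercase."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then gene symbols (tab-delimited)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise DataError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = frozenset(g.upper() for g in fields[2:] if g)
            if not genes:
                raise DataError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")
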