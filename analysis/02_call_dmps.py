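"""Call differentially methylated positions on the simulated cohort.

Filters probes (sex chromosomes, SNP/multi-mapping flags), tests per-probe
M-values (Welch t, BH), thresholds |delta beta| > 0.2 at FDR <= 0.005, and
stratifies the calls by direction, promoter/body location, and CpG context.
"""

from pathlib import Path

from methexpr import (
    DmpThresholds,
    call_dmps,
    composition_report,
    filter_probes,
    read_annotation,
    read_beta_matrix,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    meth = read_beta_matrix(COHORT / "beta.tsv", COHORT / "samples.csv")
    annotation = read_annotation(COHORT / "annotation.tsv")
    thresholds = DmpThresholds()

    filtered = filter_probes(meth, annotation, thresholds)
    dmps = call_dmps(filtered, annotation, thresholds)
    RESULTS.mkdir(exist_ok=True)
    dmps.to_csv(RESULTS / "dmps.tsv", sep="\t", index=False)

    report = composition_report(dmps, annotation)
    report.to_csv(RESULTS / "dmp_composition.tsv", sep="\t", index=False)

    n_removed = len(meth.probe_ids) - len(filtered.probe_ids)
    by = report.set_index(["stratum", "category"])
    print(f"{n_removed} probes removed by QC filters; {len(filtered.probe_ids)} tested")
    print(f"{len(dmps)} DMPs called (|delta beta| > {thresholds.min_abs_delta_beta}, "
          f"FDR <= {thresholds.max_adj_p})")
    print(f"  hypermethylated: {by.at[('direction', 'hyper'), 'count']} "
          f"({by.at[('direction', 'hyper'), 'percent']}%)")
    print(f"  hypomethylated:  {by.at[('direction', 'hypo'), 'count']} "
          f"({by.at[('direction', 'hypo'), 'percent']}%)")
    print(f"  promoter/body region tallies: "
          f"{by.at[('region', 'promoter'), 'count']}/{by.at[('region', 'body'), 'count']}")


if __name__ == "__main__":
    main()
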