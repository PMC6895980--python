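"""Generate the synthetic discovery cohort every later step analyses.

Emulates a two-group design of 32 gonadotroph tumor samples and 5 normal
pituitary samples: 2000 CpG probes with 5% planted DMPs (85% hyper, delta
beta 0.35), 2000 genes with 5% planted 4-fold DEGs, and signed
methylation->expression couplings on 11% of the DMPs (70% negative).

Matrices are written under scratch/cohort/ (large, regenerable); the
planted-truth overview goes to results/.
"""

import json
from pathlib import Path

from methexpr import SimConfig, make_gene_sets, simulate, write_fixture
from methexpr.core_data import write_gmt

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 7


def main() -> None:
    config = SimConfig(seed=SEED)
    dataset = simulate(config)
    COHORT.mkdir(parents=True, exist_ok=True)
    paths = write_fixture(dataset, COHORT, force=True)
    gene_sets = make_gene_sets(dataset, seed=SEED + 1)
    write_gmt(gene_sets, COHORT / "gene_sets.gmt")

    truth_p, truth_g = dataset.truth_probes, dataset.truth_genes
    overview = {
        "seed": SEED,
        "n_probes": config.n_probes,
        "n_genes": config.n_genes,
        "n_tumor": config.n_tumor,
        "n_normal": config.n_normal,
        "planted_dmps": int(truth_p["is_dmp"].sum()),
        "planted_hyper": int((truth_p["true_direction"] == "hyper").sum()),
        "planted_degs": int(truth_g["is_deg"].sum()),
        "planted_couplings": int((truth_p["coupled_gene"] != "").sum()),
        "planted_negative_couplings": int((truth_p["coupling_sign"] == "negative").sum()),
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "cohort_overview.json", "w") as fh:
        json.dump(overview, fh, indent=2)

    print(f"cohort written to {COHORT}")
    for key, value in overview.items():
        print(f"  {key}: {value}")


if __name__ == "__main__":
    main()
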