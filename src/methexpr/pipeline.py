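"""End-to-end orchestration: simulate/load -> DMP -> DEG -> integrate -> enrich.

``run_all`` drives the stages from a single YAML config, writes every
intermediate table under the run directory, and records a manifest (config
hash, seed, per-stage row counts).  Each stage derives its own sub-seed
deterministically from the global seed and the stage name, so re-running
an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import core_data, dmp, expression, integration, enrichment
from .synthetic import SimConfig, make_gene_sets, simulate, write_fixture

logger = logging.getLogger(__name__)

STAGES = ("data", "dmp", "deg", "integrate", "enrich")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic sub-seed below 2^31, keyed by stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, index: bool = False, **kw) -> int:
    tmp = path.with_suffix(path.suffix + ".partial")
    df.to_csv(tmp, sep="\t", index=index, **kw)
    tmp.rename(path)
    return len(df)


def validate_config(config: dict) -> dict:
    """Check the config shape before any compute; returns it normalized."""
    config = dict(config)
    has_sim = "simulate" in config
    inputs = config.get("inputs", {})
    needed = {"beta", "counts", "samples", "annotation"}
    if not has_sim and not needed <= set(inputs):
        missing = sorted(needed - set(inputs))
        raise ValueError(
            f"config needs either a 'simulate' block or inputs {missing}"
        )
    config.setdefault("seed", 0)
    config.setdefault("thresholds", {})
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def run_all(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run every stage; returns the run directory.

    The config either names input files (beta, counts, samples, annotation,
    optional gmt) or carries a ``simulate`` block with SimConfig fields.
    Thresholds live under ``thresholds: {dmp: ..., deg: ..., integration: ...}``.
    """
    config_path = Path(config_path)
    config = load_config(config_path)
    run_dir = Path(out_dir or config.get("out_dir", "methexpr_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "row_counts": {},
        "outputs": {},
    }

    current = "data"
    try:
        if "simulate" in config:
            sim_cfg = SimConfig(**{**config["simulate"], "seed": stage_seed(seed, "simulate")})
            dataset = simulate(sim_cfg)
            fixture_dir = run_dir / "data"
            paths = write_fixture(dataset, fixture_dir, force=True)
            manifest["outputs"].update(
                {k: str(Path(v).relative_to(run_dir)) for k, v in paths.items()}
            )
            meth, expr, annotation = dataset.meth, dataset.expr, dataset.annotation
            gmt = make_gene_sets(dataset, seed=stage_seed(seed, "gene_sets"))
            gmt_path = run_dir / "data" / "gene_sets.gmt"
            core_data.write_gmt(gmt, gmt_path)
            manifest["outputs"]["gmt"] = str(gmt_path.relative_to(run_dir))
        else:
            inputs = config["inputs"]
            meth = core_data.read_beta_matrix(inputs["beta"], inputs["samples"])
            expr = core_data.read_counts_matrix(inputs["counts"], inputs["samples"])
            annotation = core_data.read_annotation(inputs["annotation"])
            gmt = core_data.read_gmt(inputs["gmt"]) if "gmt" in inputs else None

        th = config.get("thresholds", {})

        current = "dmp"
        dmp_th = dmp.DmpThresholds(**th.get("dmp", {}))
        filtered = dmp.filter_probes(meth, annotation, dmp_th)
        dmps = dmp.call_dmps(filtered, annotation, dmp_th)
        manifest["row_counts"]["dmps"] = _write_table(dmps, run_dir / "dmps.tsv")
        if len(dmps):
            comp = dmp.composition_report(dmps, annotation)
            _write_table(comp, run_dir / "dmp_composition.tsv")
            manifest["outputs"]["dmp_composition"] = "dmp_composition.tsv"

        current = "deg"
        deg_th = expression.DegThresholds(**th.get("deg", {}))
        expr_f = expression.filter_low_expression(expr, deg_th)
        expr_f = expression.estimate_size_factors(expr_f)
        degs = expression.call_degs(expr_f, deg_th)
        manifest["row_counts"]["degs"] = _write_table(degs, run_dir / "degs.tsv")

        current = "integrate"
        params = integration.IntegrationParams(**th.get("integration", {}))
        corr = integration.correlate_dmps(dmps, filtered, expr_f, annotation, params)
        manifest["row_counts"]["corr"] = _write_table(corr, run_dir / "corr.tsv")
        quadrants = integration.overlap_with_degs(corr, dmps, degs)
        manifest["row_counts"]["quadrants"] = _write_table(
            quadrants, run_dir / "quadrants.tsv"
        )
        summary = integration.integration_summary(corr, quadrants, n_tested_dmps=len(dmps))
        with open(run_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest["outputs"]["summary"] = "summary.json"

        current = "enrich"
        if gmt is not None and len(corr):
            universe = [str(g) for g in expr_f.gene_ids]
            query = sorted(set(corr["gene"]))
            enr = enrichment.enrich(query, gmt, universe)
            manifest["row_counts"]["enrichment"] = _write_table(
                enr, run_dir / "enrichment.tsv"
            )
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(current, exc) from exc

    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return run_dir
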