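"""Config-driven orchestration of the full analysis, with a manifest.

Stages run in order identify → divergence → structure → expression → stats.
Every stage writes its table to the output directory as TSV/JSON so the
run is inspectable and restartable; a manifest records the config, its
hash, package versions and the seed.  Per-pair failures inside a stage are
isolated and logged; a missing input file aborts before any stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .dup_identify import (
    DuplicateCriteria,
    identify_duplicates,
    pairs_to_frame,
    summarize_by_chromosome,
)
from .divergence_stats import (
    ancova_structure_expression,
    chromosome_distribution_test,
    compare_sd_nsd,
    identity_distribution_tests,
)
from .expression_divergence import (
    compare_pair_expression,
    divergence_summary,
    expression_table,
    expression_vs_divergence_regression,
    flag_high_divergence_pairs,
)
from .io_formats import (
    apply_lineage_flags,
    read_alignment_table,
    read_expression_matrix,
    read_fasta,
    read_gene_models,
    read_lineage_table,
)
from .seq_divergence import divergence_table
from .structure_divergence import (
    compare_structure,
    structure_table,
    structure_vs_ds_trend,
)
from .synthetic_data import SimulationConfig, simulate_study

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture", "load_config"]

log = logging.getLogger("dupdiverge")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    proteins: str
    cds: str
    gene_models: str
    hits: str
    expression: str
    out_dir: str
    lineage: str | None = None
    gene_models_format: str = "tsv"
    min_coverage: float = 0.8
    long_identity: float = 0.30
    long_length: int = 150
    fpkm_off: float = 1.0
    fpkm_on: float = 2.0
    log_offset: float = 1.0
    structure_bin_size: int = 200
    expression_bin_size: int = 5
    dn_split: float = 0.3
    r_max: float | None = None
    min_tissues_expressed: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in [0, 1]")
        if not 0.0 <= self.long_identity <= 1.0:
            raise ValueError("long_identity must be in [0, 1]")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be > 0")
        if self.structure_bin_size < 1 or self.expression_bin_size < 1:
            raise ValueError("bin sizes must be ≥ 1")
        if self.fpkm_off > self.fpkm_on:
            raise ValueError("fpkm_off cutoff must not exceed fpkm_on cutoff")
        if self.min_tissues_expressed < 1:
            raise ValueError("min_tissues_expressed must be ≥ 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig(**data)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    if isinstance(obj, (bool, int, str)) or obj is None:
        return obj
    if hasattr(obj, "item"):
        return _jsonable(obj.item())
    return str(obj)


def _write_json(data: Any, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns a name → path map of the written outputs."""
    out_dir = Path(config.out_dir)
    for name in ("proteins", "cds", "gene_models", "hits", "expression"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} not found: {path}")
    if config.lineage and not Path(config.lineage).exists():
        raise FileNotFoundError(f"input 'lineage' not found: {config.lineage}")
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        proteins = {r.id: r for r in read_fasta(config.proteins, kind="protein")}
        cds = {r.id: r for r in read_fasta(config.cds, kind="cds")}
        models_list = read_gene_models(config.gene_models, format=config.gene_models_format)
        if config.lineage:
            models_list = apply_lineage_flags(models_list, read_lineage_table(config.lineage))
        models = {m.gene_id: m for m in models_list}
        hits = read_alignment_table(config.hits)
        matrix = read_expression_matrix(config.expression)
        log.info("loaded %d proteins, %d gene models, %d hits", len(proteins), len(models), len(hits))

        # --- identify
        criteria = DuplicateCriteria(
            min_coverage=config.min_coverage,
            long_identity=config.long_identity,
            long_length=config.long_length,
        )
        pairs = identify_duplicates(hits, proteins, models, criteria)
        log.info("identified %d duplicate pairs", len(pairs))
        pairs_frame = pairs_to_frame(pairs)
        outputs["pairs"] = out_dir / "pairs.tsv"
        pairs_frame.to_csv(outputs["pairs"], sep="\t", index=False)
        summaries, genome, chrom_table = summarize_by_chromosome(pairs, models)
        outputs["chromosome_summary"] = out_dir / "chromosome_summary.tsv"
        chrom_table.to_csv(outputs["chromosome_summary"], sep="\t", index=False)

        pair_keys = [(p.gene_a, p.gene_b) for p in pairs]
        lineage_map = {(p.gene_a, p.gene_b): p.lineage for p in pairs}

        # --- sequence divergence
        div = divergence_table(pair_keys, proteins, cds)
        outputs["divergence"] = out_dir / "divergence.tsv"
        div.to_csv(outputs["divergence"], sep="\t")
        n_failed = int((div["error"] != "").sum())
        if n_failed:
            log.warning("divergence estimation failed for %d pairs", n_failed)

        # --- structure
        struct_frame = structure_table(pair_keys, models)
        outputs["structure"] = out_dir / "structure.tsv"
        struct_frame.to_csv(outputs["structure"], sep="\t")
        comparisons = [compare_structure(models[a], models[b]) for a, b in pair_keys]
        ds_series = [float(div.loc[k, "dS"]) for k in pair_keys]
        trend: dict[str, Any]
        try:
            t = structure_vs_ds_trend(comparisons, ds_series, bin_size=config.structure_bin_size)
            trend = _jsonable(t)
        except ValueError as exc:
            trend = {"error": str(exc)}
            log.warning("structure trend skipped: %s", exc)
        outputs["structure_trend"] = out_dir / "structure_trend.json"
        _write_json(trend, outputs["structure_trend"])

        # --- expression
        expr_comparisons = [
            compare_pair_expression(k, matrix, offset=config.log_offset)
            for k in pair_keys if k[0] in matrix and k[1] in matrix
        ]
        expr_keys = [(c.gene_a, c.gene_b) for c in expr_comparisons]
        expr_frame = expression_table(expr_keys, matrix, offset=config.log_offset)
        outputs["expression"] = out_dir / "expression.tsv"
        expr_frame.to_csv(outputs["expression"], sep="\t")
        summary = divergence_summary(expr_comparisons, matrix.tissue_names, lineage_map)
        regressions: dict[str, Any] = {}
        ds_by_key = {k: float(div.loc[k, "dS"]) for k in pair_keys}
        dn_by_key = {k: float(div.loc[k, "dN"]) for k in pair_keys}
        gated = [
            c for c in expr_comparisons
            if min(c.n_tissues_expressed_a, c.n_tissues_expressed_b) >= config.min_tissues_expressed
        ]
        for cov, values_map, split in (
            ("dS", ds_by_key, None),
            ("dN", dn_by_key, config.dn_split),
        ):
            try:
                res = expression_vs_divergence_regression(
                    gated,
                    [values_map[(c.gene_a, c.gene_b)] for c in gated],
                    covariate=cov,
                    dn_split=split,
                    bin_size=config.expression_bin_size,
                )
                regressions[cov] = _jsonable(res)
            except ValueError as exc:
                regressions[cov] = {"error": str(exc)}
                log.warning("%s regression skipped: %s", cov, exc)
        expr_report = {"summary": summary, "regressions": regressions}
        if config.r_max is not None:
            expr_report["high_divergence_pairs"] = flag_high_divergence_pairs(
                expr_comparisons, config.r_max, lineage_map
            )
        outputs["expression_summary"] = out_dir / "expression_summary.json"
        _write_json(expr_report, outputs["expression_summary"])

        # --- stats
        stats_report: dict[str, Any] = {}
        try:
            stats_report["sd_vs_nsd"] = _jsonable(
                compare_sd_nsd(expr_comparisons, comparisons, lineage_map)
            )
        except (ValueError, KeyError) as exc:
            stats_report["sd_vs_nsd"] = {"error": str(exc)}
        try:
            stats_report["ancova"] = _jsonable(
                ancova_structure_expression(expr_comparisons, comparisons, ds_by_key)
            )
        except (ValueError, KeyError) as exc:
            stats_report["ancova"] = {"error": str(exc)}
        try:
            stats_report["identity_distributions"] = identity_distribution_tests(pairs)
        except ValueError as exc:
            stats_report["identity_distributions"] = {"error": str(exc)}
        stats_report["chromosome_distribution"] = chromosome_distribution_test(summaries, genome)
        outputs["stats"] = out_dir / "stats.json"
        _write_json(stats_report, outputs["stats"])

        # --- manifest
        manifest = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "dupdiverge_version": __version__,
            "python_version": sys.version.split()[0],
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        outputs["manifest"] = out_dir / "manifest.json"
        _write_json(manifest, outputs["manifest"])
        return outputs
    finally:
        log.removeHandler(handler)
        handler.close()


def make_fixture(sim_config: SimulationConfig, out_dir: str | Path):
    """Write a synthetic study bundle (thin wrapper over simulate_study)."""
    return simulate_study(sim_config, out_dir)
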