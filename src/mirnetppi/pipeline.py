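"""Config-driven orchestration of the full workflow.

Runs de-mirna -> integrate -> enrich -> ppi in order, writing every
intermediate table, both network exports and a machine-readable JSON
run report.  Any stage failure aborts with the stage name and cause;
partial outputs are kept next to a FAILED marker.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import diffexpr, enrichment, io_formats, mir_target_integration as integration, ppi_neighborhood as ppi
from .diffexpr import SamConfig

SCHEMA_VERSION = 1

log = logging.getLogger("mirnetppi")


@dataclass
class PipelineConfig:
    """Validated inputs and parameters for one run.

    Defaults mirror the study settings: SAM delta 2 with 1000
    permutations, union merge policy, strict negative correlation,
    min_hits 8, STRING min_score 0.9, top_k 20.
    """

    mirna_matrix: str
    labels: str
    mrna_matrix: str
    target_tables: list[dict]  # [{"path": ..., "dialect": ...}, ...]
    gmt: str
    ppi_edges: str
    ppi_seed_gene: str
    out_dir: str
    sam: SamConfig = field(default_factory=SamConfig)
    delta_target_calls: int | None = None
    merge_policy: str = "union"
    screen_method: str = "auto"
    screen_threshold: float = 0.0
    log2fc_pseudocount: float = 1.0
    log2fc_call_threshold: float = 1.0
    enrich_mode: str = "hypergeometric"
    min_hits: int = 8
    universe: str | None = None  # path to one-gene-per-line file; default = expressed genes
    ppi_min_score: float = 0.9
    ppi_top_k: int = 20
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise io_formats.ConfigError(
                f"config schema_version {self.schema_version} != {SCHEMA_VERSION}"
            )
        for p in [self.mirna_matrix, self.labels, self.mrna_matrix, self.gmt, self.ppi_edges] + [
            t["path"] for t in self.target_tables
        ]:
            if not Path(p).exists():
                raise io_formats.ConfigError(f"input file not found: {p}")
        if not 0 <= self.ppi_min_score <= 1:
            raise io_formats.ConfigError("ppi_min_score must be in [0,1]")
        if self.ppi_top_k < 1 or self.min_hits < 0:
            raise io_formats.ConfigError("ppi_top_k must be >=1 and min_hits >=0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sam = SamConfig(**raw.pop("sam", {}))
        cfg = cls(sam=sam, **raw)
        cfg.validate()
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        return d


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, label), optional header line."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise io_formats.ParseError(f"{path}:{lineno}: expected 2 fields")
            if lineno == 1 and parts[0].lower() in ("sample", "sample_id"):
                continue
            out[parts[0]] = parts[1]
    return out


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("[%(stage)s] %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def _stage_log(stage: str, message: str) -> None:
    log.info(message, extra={"stage": stage})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return (and write) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    report: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed, "config": config.echo()}
    stage = "setup"
    try:
        label_map = read_labels(config.labels)
        mirna = io_formats.read_expression_matrix(config.mirna_matrix, label_map, mode="intensity")
        mrna = io_formats.read_expression_matrix(config.mrna_matrix, label_map, mode="fpkm")

        stage = "de-mirna"
        sam_cfg = SamConfig(
            config.sam.n_permutations, config.sam.delta, config.sam.s0_method,
            config.sam.s0_fixed, config.seed,
        )
        fit = diffexpr.sam_fit(mirna, sam_cfg)
        if config.delta_target_calls is not None:
            delta = diffexpr.tune_delta(fit, config.delta_target_calls, sam_cfg)
            sam_cfg = SamConfig(sam_cfg.n_permutations, delta, sam_cfg.s0_method,
                                sam_cfg.s0_fixed, sam_cfg.rng_seed)
            _stage_log(stage, f"delta tuned to {delta:.3f} targeting {config.delta_target_calls} calls")
        sam_res = diffexpr.sam_call(fit, sam_cfg)
        diffexpr.write_calls(sam_res.calls, out / "de_mirna.tsv")
        called = [c for c in sam_res.calls if c.called]
        report["de_mirna"] = {
            "n_features": len(sam_res.calls),
            "n_called": sam_res.n_called,
            "n_up": sum(c.direction == "up" for c in called),
            "n_down": sum(c.direction == "down" for c in called),
            "delta": sam_cfg.delta,
            "s0": fit.s0,
            "pi0": fit.pi0,
            "fdr_median": sam_res.fdr_median,
        }
        _stage_log(stage, f"{sam_res.n_called} miRNAs called at delta={sam_cfg.delta:.3f}")

        stage = "mrna-log2fc"
        gene_calls = diffexpr.log2fc_table(
            mrna, config.log2fc_pseudocount, config.log2fc_call_threshold
        )
        diffexpr.write_calls(gene_calls, out / "mrna_log2fc.tsv")

        stage = "integrate"
        restrict = {c.feature_id for c in called}
        if not restrict:
            _stage_log(stage, "no miRNAs called; downstream tables are empty")
            merged_summary = {"n_union_pairs": 0, "n_intersection_pairs": 0, "n_union_genes": 0,
                              "n_intersection_genes": 0, "n_multi_targeted_genes": 0,
                              "shared_gene_percentage": 0, "per_source_genes": {},
                              "policy": config.merge_policy}
            screen_res = integration.ScreenResult([], [], config.screen_method)
            passed = []
        else:
            tables = [
                io_formats.read_target_table(t["path"], t.get("dialect", "generic"))
                for t in config.target_tables
            ]
            merged = integration.merge_predictions(tables, restrict, config.merge_policy)
            merged_summary = merged.summary()
            screen_res = integration.screen_negative_pairs(
                merged, sam_res.calls, mirna, mrna,
                method=config.screen_method, threshold=config.screen_threshold,
                pseudocount=config.log2fc_pseudocount,
            )
            passed = screen_res.passed_pairs
        integration.screened_pairs_frame(screen_res).to_csv(out / "pairs.tsv", sep="\t", index=False)
        nodes, edges = integration.build_mir_mrna_network(passed, sam_res.calls, gene_calls)
        io_formats.write_network(nodes, edges, "SIF", out / "mir_mrna.sif")
        io_formats.write_network(nodes, edges, "GraphML", out / "mir_mrna.graphml")
        report["integration"] = {**merged_summary, **screen_res.summary()}
        _stage_log(stage, f"{len(passed)} anti-concordant pairs passed the screen")

        stage = "enrich"
        query = {p.gene for p in passed}
        if config.universe:
            with open(config.universe) as fh:
                universe = {line.strip() for line in fh if line.strip()}
        else:
            universe = set(mrna.feature_ids)
        collection = io_formats.read_gene_sets_gmt(config.gmt)
        if query:
            rows = enrichment.adjust_bh(
                enrichment.ora_test(query, collection, universe, mode=config.enrich_mode)
            )
        else:
            rows = []
        kept = enrichment.filter_min_hits(rows, config.min_hits)
        enrichment.enrichment_frame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        enrichment.enrichment_frame(kept).to_csv(out / "enrichment_min_hits.tsv", sep="\t", index=False)
        enrichment.color_nodes(gene_calls, query).to_csv(out / "node_colors.tsv", sep="\t", index=False)
        enrichment.term_overlap_edges(kept).to_csv(out / "term_edges.tsv", sep="\t", index=False)
        report["enrichment"] = {
            "n_sets_tested": len(collection),
            "n_sets_hit": len(rows),
            "n_sets_min_hits": len(kept),
            "min_hits": config.min_hits,
            "mode": config.enrich_mode,
            "universe_size": len(universe),
        }
        _stage_log(stage, f"{len(rows)} sets hit; {len(kept)} with >= {config.min_hits} hits")

        stage = "ppi"
        ppi_edges = io_formats.read_ppi_edges(config.ppi_edges)
        nbr_rows = ppi.extract_neighborhood(
            ppi_edges, config.ppi_seed_gene, config.ppi_min_score, config.ppi_top_k
        )
        gene_call_map = {c.feature_id: c for c in gene_calls}
        seed_call = gene_call_map.get(config.ppi_seed_gene)
        nbr_report = ppi.classify_concordance(
            ppi.overlay_expression(nbr_rows, gene_calls, seed_call, seed=config.ppi_seed_gene)
        )
        ppi.report_frame(nbr_report).to_csv(out / "neighborhood.tsv", sep="\t", index=False)
        n_nodes, n_edges = ppi.neighborhood_network(nbr_report)
        if len(n_nodes):
            io_formats.write_network(n_nodes, n_edges, "GraphML", out / "ppi_neighborhood.graphml")
        report["ppi"] = nbr_report.summary()
        _stage_log(stage, f"{len(nbr_report.rows)} neighbors of {config.ppi_seed_gene}")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
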