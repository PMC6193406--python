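"""End-to-end orchestration: simulate/load -> MI network -> DE -> modules -> ORA.

Every stage writes its inputs and outputs to the run directory as plain
text, and the final report JSON carries a provenance block (config, seed,
versions), so a run is reproducible byte for byte from its own artifacts.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import infomod
from infomod.dataset import ExpressionDataset
from infomod.simulate import SimulationConfig, GroundTruth, simulate_expression, generate_gene_sets
from infomod import mi as mi_mod
from infomod import de as de_mod
from infomod import mapeq
from infomod.enrich import enrich_modules, read_gmt, write_gmt, write_enrichment

__all__ = ["PipelineConfig", "run_pipeline", "summarize_module_expression"]

log = logging.getLogger("infomod.pipeline")


@dataclass
class PipelineConfig:
    """Everything one run needs; paths may be replaced by a simulation."""

    expression_path: str | None = None
    labels_path: str | None = None
    gmt_path: str | None = None
    simulation: SimulationConfig | None = None
    top_edges: int = mi_mod.DEFAULT_TOP_EDGES
    dpi_epsilon: float | None = None
    fdr_threshold: float = de_mod.DEFAULT_FDR
    lfc_threshold: float = de_mod.DEFAULT_LFC
    trials: int = 10
    seed: int = 0
    max_depth: int = 5
    min_split: int = 3
    min_module_size: int = 5
    universe_policy: str = "annotation"
    component_floor: int = 3  # smaller components are censused but not analyzed
    n_decoy_sets: int = 10
    decoy_size: int = 20
    out_dir: str = "infomod_run"

    def validate(self) -> None:
        if self.fdr_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.top_edges < 1:
            raise ValueError("top_edges must be >= 1")
        if self.simulation is None and self.expression_path is None:
            raise ValueError("either an expression matrix or a simulation config is required")
        for p in (self.expression_path, self.labels_path, self.gmt_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def summarize_module_expression(tree: mapeq.ModuleTree, degs: pd.DataFrame | None) -> pd.DataFrame:
    """Per-module DE overlay: median log2FC, fraction up / down / unclassified.

    Genes missing from the DEG table count as unclassified.  With no DEG
    table at all, fractions are 0 and medians unavailable (NaN).
    """
    rows = []
    if degs is not None and len(degs):
        lfc = dict(zip(degs["gene"], degs["log2FC"]))
        up = set(degs.loc[degs["is_deg"] & (degs["log2FC"] > 0), "gene"])
        down = set(degs.loc[degs["is_deg"] & (degs["log2FC"] < 0), "gene"])
    else:
        lfc, up, down = {}, set(), set()
    for m in tree.walk():
        if not m.path:
            continue
        genes = m.genes
        covered = [g for g in genes if g in lfc]
        rows.append(
            {
                "module_path": m.path,
                "module_label": m.label,
                "size": m.size,
                "median_log2FC": float(np.median([lfc[g] for g in covered])) if covered else float("nan"),
                "fraction_up": sum(g in up for g in genes) / m.size,
                "fraction_down": sum(g in down for g in genes) / m.size,
                "fraction_unclassified": 1.0 - len(covered) / m.size,
            }
        )
    return pd.DataFrame(rows)


@_stage("data")
def _load_data(config: PipelineConfig, out: Path):
    if config.simulation is not None:
        data, truth = simulate_expression(config.simulation, seed=config.seed)
        sets = generate_gene_sets(
            truth, n_decoy_sets=config.n_decoy_sets, decoy_size=config.decoy_size, seed=config.seed
        )
        data.write_tsv(out / "expression.tsv", out / "labels.tsv")
        truth.write_json(out / "truth.json")
        write_gmt(sets, out / "gene_sets.gmt")
        return data, truth, sets
    data = ExpressionDataset.read_tsv(config.expression_path, config.labels_path)
    sets = read_gmt(config.gmt_path) if config.gmt_path else None
    return data, None, sets


@_stage("network")
def _build_network(config: PipelineConfig, data: ExpressionDataset, out: Path):
    table = mi_mod.build_mi_table(data)
    mi_mod.write_edge_list(table, out / "mi_table.tsv")
    if config.dpi_epsilon is not None:
        table = mi_mod.dpi_prune(table, config.dpi_epsilon)
    net = mi_mod.prune_top_edges(table, config.top_edges)
    mi_mod.write_edge_list(net, out / "network_edges.tsv")
    mi_mod.write_sif(net, out / "network.sif")
    return table, net


@_stage("deg")
def _run_de(config: PipelineConfig, data: ExpressionDataset, out: Path):
    degs = de_mod.run_de(data, config.fdr_threshold, config.lfc_threshold)
    de_mod.write_deg_table(degs, out / "deg_table.tsv")
    return degs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report bundle (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data, truth, sets = _load_data(config, out)
    mi_table, net = _build_network(config, data, out)

    degs = None
    has_both = {"tumor", "normal"} <= set(data.condition)
    if has_both:
        degs = _run_de(config, data, out)
    else:
        log.warning("missing condition labels: skipping the DE overlay")

    components = mapeq.connected_components(net)
    sizes = [len(c) for c in components]
    census = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_components": len(components),
        "component_sizes": sizes,
        "n_two_node_islands": sum(1 for s in sizes if s == 2),
        "giant_component_share": (max(sizes) / sum(sizes)) if sizes else 0.0,
        "clique_components": [
            sorted(c)
            for c in components
            if len(c) >= 3
            and net.subgraph(c).number_of_edges() == len(c) * (len(c) - 1) // 2
        ],
    }

    module_reports = []
    expression_summaries = []
    enrichments = []
    analyzed = [c for c in components if len(c) >= config.component_floor]
    comp_seeds = np.random.SeedSequence(config.seed).spawn(max(1, len(analyzed)))
    for idx, (component, comp_seed) in enumerate(zip(analyzed, comp_seeds), start=1):
        t0 = time.perf_counter()
        tree = mapeq.build_hierarchy(
            net,
            component,
            trials=config.trials,
            seed=int(comp_seed.generate_state(1)[0]),
            max_depth=config.max_depth,
            min_split=config.min_split,
        )
        scores = mapeq.pagerank(net, component)
        mapeq.label_modules(tree, scores)
        rates = mapeq.visit_rates(net, component)
        mapeq.write_tree_file(tree, rates, out / f"component_{idx}.tree")
        mapeq.tree_to_json(tree, out / f"component_{idx}.json")
        module_reports.append(
            {
                "component": idx,
                "size": len(component),
                "codelength_bits": round(tree.codelength, 10),
                "n_modules": len(tree.children),
                "n_submodules": sum(len(m.children) for m in tree.children),
                "module_labels": [m.label for m in tree.children],
            }
        )
        summary = summarize_module_expression(tree, degs)
        summary.insert(0, "component", idx)
        expression_summaries.append(summary)
        if sets:
            enr = enrich_modules(
                tree,
                sets,
                universe_policy=config.universe_policy,
                min_module_size=config.min_module_size,
            )
            if len(enr):
                enr.insert(0, "component", idx)
                enrichments.append(enr)
        log.info("component %d (%d nodes) analyzed in %.2fs", idx, len(component), time.perf_counter() - t0)

    if expression_summaries:
        pd.concat(expression_summaries, ignore_index=True).to_csv(
            out / "module_expression.tsv", sep="\t", index=False, float_format="%.6f"
        )
    if enrichments:
        write_enrichment(pd.concat(enrichments, ignore_index=True), out / "enrichment.tsv")

    report = {
        "census": census,
        "components_analyzed": len(analyzed),
        "modules": module_reports,
        "n_degs": int(degs["is_deg"].sum()) if degs is not None else None,
        "n_enrichment_tests": int(sum(len(e) for e in enrichments)),
        "n_significant_enrichments": int(
            sum(int(e["significant"].sum()) for e in enrichments)
        ),
        "provenance": {
            "config": asdict(config),
            "seed": config.seed,
            "package_version": infomod.__version__,
            "python": ".".join(map(str, sys.version_info[:3])),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
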