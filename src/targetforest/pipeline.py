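"""End-to-end orchestration: expression -> networks -> PCSF -> ranking.

The pipeline wires the stage modules together under a single flat
configuration whose defaults follow the published analysis settings:
soft-threshold power beta = 10, physical-interaction edge filter, 50
randomized PCSF runs at 10% edge-cost noise, and the strict >40% structure
coverage gate. Every run emits a JSON manifest recording parameters, seeds
and per-stage summaries sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import druggability as drug_mod
from . import networks as net_mod
from . import pcsf as pcsf_mod
from . import prizes as prize_mod
from . import ranking as rank_mod

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "report_summary"]


@dataclass
class PipelineConfig:
    """Flat key-value configuration for a full run.

    Paths may be None when the corresponding stage is fed in memory.
    ``prize_scale`` calibrates variant-frequency prizes (<= 1 by
    construction) against edge costs (near 1 on weakly rewired edges); see
    the methods notes for the default's rationale.
    """

    expression_case: str | None = None
    expression_control: str | None = None
    ppi_annotations: str | None = None
    variants: str | None = None
    druggability: str | None = None
    outdir: str = "targetforest_out"

    beta: int = 10
    signed_adjacency: bool = False
    d_floor: float = 0.0
    physical_label: str = "physical interaction"
    weighted_betweenness: bool = False

    prize_scheme: str = "frequency"
    cohort_size: int | None = None  # default: number of distinct samples in the variant table

    omega: float = 0.5
    prize_scale: float = 5.0
    n_runs: int = 50
    noise: float = 0.1
    seed: int = 0

    ranking_universe: str = "union"  # "union" (PCSF nodes) or "network"
    rank_combine: str = "geometric"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    network: net_mod.DifferentialNetwork
    betweenness: dict[str, float]
    prize_map: prize_mod.PrizeMap
    occurrences: pcsf_mod.OccurrenceTable
    union_solution: pcsf_mod.PCSFSolution
    druggability: list
    rank_table: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_all(
    config: PipelineConfig,
    *,
    expr_case=None,
    expr_control=None,
    annotations=None,
    variants=None,
    druggability_records=None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Execute networks -> prizes -> pcsf -> druggability -> ranking.

    Inputs may be given as file paths in the config or directly as in-memory
    objects (keyword arguments take precedence). When ``write_outputs`` is
    true the rank table (TSV), the filtered network and PCSF forest
    (GraphML), the differential edge list and the JSON manifest are written
    to ``config.outdir``.
    """
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    # -- stage: inputs ------------------------------------------------------
    load = _stage("inputs")(_load_inputs)
    expr_case, expr_control, annotations, variants, druggability_records = load(
        config, expr_case, expr_control, annotations, variants, druggability_records
    )

    # -- stage: networks ----------------------------------------------------
    @_stage("networks")
    def networks_stage():
        net_case = net_mod.compute_adjacency(expr_case, beta=config.beta,
                                             signed=config.signed_adjacency)
        net_ctrl = net_mod.compute_adjacency(expr_control, beta=config.beta,
                                             signed=config.signed_adjacency)
        dn_full = net_mod.differential_edges(net_case, net_ctrl, d_floor=config.d_floor)
        dn_phys = net_mod.filter_physical(dn_full, annotations, label=config.physical_label)
        dn = net_mod.largest_component(dn_phys)
        btw = net_mod.betweenness(dn, weighted=config.weighted_betweenness)
        manifest["stages"]["networks"] = {
            "genes_in": expr_case.n_genes,
            "samples_case": expr_case.n_samples,
            "samples_control": expr_control.n_samples,
            "edges_differential": dn_full.n_edges,
            "edges_physical": dn_phys.n_edges,
            "nodes_physical": dn_phys.n_nodes,
            "largest_component_nodes": dn.n_nodes,
            "largest_component_edges": dn.n_edges,
        }
        return dn, btw

    dn, btw = networks_stage()

    # -- stage: prizes ------------------------------------------------------
    @_stage("prizes")
    def prizes_stage():
        cohort = config.cohort_size or len({v.sample for v in variants}) or 1
        pm = prize_mod.compute_prizes(
            variants, cohort_size=cohort, scheme=config.prize_scheme,
            network_genes=dn.nodes,
        )
        manifest["stages"]["prizes"] = {
            "cohort_size": cohort,
            "prized_genes": sum(1 for _, p in pm.items() if p > 0),
            "prized_in_network": sum(1 for g in dn.nodes if pm.get(g, 0.0) > 0),
        }
        return pm

    prize_map = prizes_stage()

    # -- stage: pcsf --------------------------------------------------------
    @_stage("pcsf")
    def pcsf_stage():
        inst = pcsf_mod.instance_from_network(
            dn, prize_map, omega=config.omega, prize_scale=config.prize_scale
        )
        occ, union = pcsf_mod.randomized_runs(
            inst, n_runs=config.n_runs, noise=config.noise, seed=config.seed
        )
        comps = pcsf_mod.components(union)
        manifest["stages"]["pcsf"] = {
            "omega": config.omega,
            "prize_scale": config.prize_scale,
            "n_runs": config.n_runs,
            "noise": config.noise,
            "seed": config.seed,
            "union_nodes": union.n_nodes,
            "union_edges": len(union.edges),
            "n_subgraphs": len(comps),
            "subgraph_sizes": [s for _, _, s in comps],
            "n_terminal": sum(1 for t in union.node_types.values() if t == "Terminal"),
            "n_steiner": sum(1 for t in union.node_types.values() if t == "Steiner"),
        }
        return inst, occ, union

    inst, occurrences, union_solution = pcsf_stage()

    # -- stage: druggability ------------------------------------------------
    @_stage("druggability")
    def druggability_stage():
        records = druggability_records or []
        n_zero = sum(1 for r in records if r.drug_score == 0)
        manifest["stages"]["druggability"] = {
            "proteins": len(records),
            "zero_score": n_zero,
            "zero_score_fraction": round(n_zero / len(records), 4) if records else None,
        }
        return records

    drecords = druggability_stage()

    # -- stage: ranking -----------------------------------------------------
    @_stage("ranking")
    def ranking_stage():
        if config.ranking_universe == "union":
            universe = sorted(union_solution.nodes)
        elif config.ranking_universe == "network":
            universe = sorted(dn.nodes)
        else:
            raise ValueError(f"unknown ranking universe {config.ranking_universe!r}")
        table = rank_mod.assemble_rank_table(
            btw, drecords, occurrences, union_solution, prize_map,
            universe=universe, combine=config.rank_combine,
        )
        n_indirect = int((table["evidence"] == "Indirect").sum()) if len(table) else 0
        manifest["stages"]["ranking"] = {
            "universe": config.ranking_universe,
            "universe_size": len(universe),
            "n_indirect": n_indirect,
            "top10": table["gene"].head(10).tolist(),
        }
        return table

    rank_table = ranking_stage()

    if write_outputs:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rank_mod.write_rank_table(rank_table, outdir / "rank_table.tsv")
        net_mod.write_graphml(dn, outdir / "differential_network.graphml", btw)
        net_mod.write_edge_list(dn, outdir / "differential_edges.tsv")
        pcsf_mod.write_solution_graphml(
            union_solution, inst, outdir / "pcsf_forest.graphml", occurrences
        )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        network=dn,
        betweenness=btw,
        prize_map=prize_map,
        occurrences=occurrences,
        union_solution=union_solution,
        druggability=drecords,
        rank_table=rank_table,
        manifest=manifest,
    )


def _load_inputs(config, expr_case, expr_control, annotations, variants, druggability_records):
    if expr_case is None:
        if not config.expression_case:
            raise ValueError("no case expression input")
        expr_case = net_mod.read_expression_tsv(config.expression_case, "case")
    if expr_control is None:
        if not config.expression_control:
            raise ValueError("no control expression input")
        expr_control = net_mod.read_expression_tsv(config.expression_control, "control")
    if annotations is None:
        if not config.ppi_annotations:
            raise ValueError("no PPI annotation input")
        annotations = net_mod.read_ppi_annotations(config.ppi_annotations)
    if variants is None:
        if not config.variants:
            raise ValueError("no variant input")
        variants = prize_mod.read_variants_tsv(config.variants)
    if druggability_records is None:
        if config.druggability:
            druggability_records = drug_mod.read_druggability_tsv(config.druggability)
        else:
            warnings.warn("no druggability input; all drug scores default to 0",
                          UserWarning, stacklevel=2)
            druggability_records = []
    return expr_case, expr_control, annotations, variants, druggability_records


def report_summary(manifest: dict) -> str:
    """Human-readable per-stage summary of a run manifest."""
    s = manifest.get("stages", {})
    net = s.get("networks", {})
    pc = s.get("pcsf", {})
    rk = s.get("ranking", {})
    lines = [
        "targetforest run summary",
        "========================",
        f"genes in                 : {net.get('genes_in', 0)}",
        f"differential edges       : {net.get('edges_differential', 0)}",
        f"physical edges kept      : {net.get('edges_physical', 0)}",
        f"largest component        : {net.get('largest_component_nodes', 0)} nodes / "
        f"{net.get('largest_component_edges', 0)} edges",
        f"PCSF proteins (union)    : {pc.get('union_nodes', 0)}",
        f"PCSF subgraphs           : {pc.get('n_subgraphs', 0)}",
        f"subgraph sizes           : {pc.get('subgraph_sizes', [])}",
        f"Terminal / Steiner       : {pc.get('n_terminal', 0)} / {pc.get('n_steiner', 0)}",
        f"ranking universe         : {rk.get('universe', '?')} ({rk.get('universe_size', 0)})",
        f"indirect-evidence count  : {rk.get('n_indirect', 0)}",
        f"top 10 targets           : {', '.join(rk.get('top10', [])) or '(none)'}",
    ]
    return "\n".join(lines)
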