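"""Rank-product integration of network topology and druggability.

Each protein in the ranking universe carries three metrics: betweenness
centrality in the differential interaction network, the number of
randomized-PCSF bootstrap runs it appeared in (occurrences), and its
structural drug-ability score. Per metric, the N proteins are ranked 1..N
with the largest value receiving rank N and tied values sharing the minimum
rank of their tie block; the combined rank-product score is the geometric
mean of the three ranks, so a larger score marks a more important protein.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rank_metric",
    "rank_product",
    "assemble_rank_table",
    "metric_correlation",
    "write_rank_table",
]

RANK_TABLE_COLUMNS = [
    "uniprot_id",
    "gene",
    "betweenness",
    "drug_score",
    "occurrences",
    "rank_betweenness",
    "rank_drug",
    "rank_occurrences",
    "rank_product",
    "type",
    "cluster",
    "evidence",
]


def rank_metric(values: Sequence[float]) -> list[int]:
    """Ascending ranks 1..N (largest value -> rank N); ties share their
    block's minimum rank."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty metric vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("metric values must be finite")
    return [int(r) for r in stats.rankdata(arr, method="min")]


def rank_product(ranks: Sequence[float]) -> float:
    """Geometric mean of the per-metric ranks."""
    arr = np.asarray(ranks, dtype=float)
    if np.any(arr < 1):
        raise ValueError("ranks must be >= 1")
    return float(np.exp(np.mean(np.log(arr))))


def assemble_rank_table(
    betweenness_map: Mapping[str, float],
    druggability_records: Iterable,
    occurrences,
    pcsf_solution,
    prize_map,
    universe: Iterable[str] | None = None,
    combine: str = "geometric",
    gene_to_uniprot: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Build the final per-protein target table.

    The ranking universe defaults to the node set of the PCSF (union)
    solution; pass an explicit iterable (e.g. the full differential network's
    nodes) to rank a wider universe. Every universe member must have a
    betweenness entry (hard error otherwise: it signals a universe mismatch).
    Missing druggability records score 0; missing occurrence entries count 0.
    ``combine`` selects the rank combination: "geometric" (default,
    rank product) or "arithmetic" (mean rank).
    """
    from .pcsf import components as pcsf_components

    if combine not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown rank combination {combine!r}")
    genes = sorted(universe) if universe is not None else sorted(pcsf_solution.nodes)
    if not genes:
        return pd.DataFrame(columns=RANK_TABLE_COLUMNS)
    missing = [g for g in genes if g not in betweenness_map]
    if missing:
        raise ValueError(
            f"{len(missing)} universe protein(s) lack a betweenness entry "
            f"(universe mismatch), e.g. {missing[:3]}"
        )
    drug = {r.protein_id: r.drug_score for r in druggability_records}
    clusters = {v: cid for cid, cset, _ in pcsf_components(pcsf_solution) for v in cset}

    bvals = [float(betweenness_map[g]) for g in genes]
    dvals = [float(drug.get(g, 0.0)) for g in genes]
    ovals = [int(occurrences.get(g, 0)) for g in genes]
    rb = rank_metric(bvals)
    rd = rank_metric(dvals)
    ro = rank_metric(ovals)
    if combine == "geometric":
        rp = [rank_product(t) for t in zip(rb, rd, ro)]
    else:
        rp = [float(np.mean(t)) for t in zip(rb, rd, ro)]

    rows = []
    for i, g in enumerate(genes):
        in_forest = g in pcsf_solution.nodes
        rows.append(
            {
                "uniprot_id": (gene_to_uniprot or {}).get(g, g),
                "gene": g,
                "betweenness": bvals[i],
                "drug_score": dvals[i],
                "occurrences": ovals[i],
                "rank_betweenness": rb[i],
                "rank_drug": rd[i],
                "rank_occurrences": ro[i],
                "rank_product": rp[i],
                "type": pcsf_solution.node_types.get(g, "") if in_forest else "",
                "cluster": clusters.get(g, 0),
                "evidence": "Direct" if prize_map.get(g, 0.0) > 0 else "Indirect",
            }
        )
    df = pd.DataFrame(rows, columns=RANK_TABLE_COLUMNS)
    df = df.sort_values(["rank_product", "gene"], ascending=[False, True]).reset_index(drop=True)
    return df


def metric_correlation(
    betweenness_map: Mapping[str, float],
    druggability_records: Iterable,
    universe: Iterable[str] | None = None,
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between betweenness and drug score.

    Used to check that structural druggability contributes information
    orthogonal to network topology. Requires >= 3 proteins; a zero-variance
    metric makes the correlation undefined (ValueError).
    """
    drug = {r.protein_id: r.drug_score for r in druggability_records}
    genes = sorted(universe) if universe is not None else sorted(betweenness_map)
    if len(genes) < 3:
        raise ValueError("need >= 3 proteins for a correlation")
    x = np.array([float(betweenness_map[g]) for g in genes])
    y = np.array([float(drug.get(g, 0.0)) for g in genes])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance metric: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def write_rank_table(df: pd.DataFrame, path) -> None:
    """TSV with the published target-table column layout."""
    out = df.rename(
        columns={
            "uniprot_id": "Uniprot ID",
            "gene": "HGNC symbol",
            "betweenness": "Betweenness",
            "drug_score": "Drug score",
            "occurrences": "Occurrences",
            "rank_product": "Rank product",
            "type": "Type",
            "cluster": "Cluster",
            "evidence": "Evidence",
        }
    )
    cols = [
        "Uniprot ID", "HGNC symbol", "Betweenness", "Drug score", "Occurrences",
        "Rank product", "Type", "Cluster", "Evidence",
    ]
    out[cols].to_csv(path, sep="\t", index=False)
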