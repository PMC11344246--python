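"""Differential co-expression networks.

Builds per-cohort soft-thresholded co-expression adjacencies from normalized
expression, combines them into a single differential interaction network,
restricts it to edges with curated physical-interaction support, and computes
the topology metrics (largest connected component, betweenness centrality)
used downstream for target prioritisation.

The adjacency follows the unsigned weighted-correlation convention
``a_ij = |pearson(x_i, x_j)| ** beta`` with a soft-threshold power ``beta``
(default 10); a signed variant ``a_ij = ((1 + r) / 2) ** beta`` is available.
The per-edge differential weight is ``d_ij = |a_case,ij - a_control,ij|`` and
the associated Steiner-forest edge cost is ``c_ij = 1 - d_ij``, so strongly
rewired gene pairs are cheap to include in a subnetwork.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CoexpressionNetwork",
    "PPIAnnotation",
    "DifferentialNetwork",
    "read_expression_tsv",
    "read_ppi_annotations",
    "compute_adjacency",
    "differential_edges",
    "filter_physical",
    "largest_component",
    "betweenness",
    "write_edge_list",
    "write_graphml",
]

PHYSICAL_LABEL = "physical interaction"


@dataclass
class ExpressionMatrix:
    """Genes x samples normalized expression for one cohort."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in expression matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class CoexpressionNetwork:
    """Soft-thresholded co-expression adjacency for one cohort.

    ``adjacency`` is symmetric with zero diagonal and entries in [0, 1].
    ``flagged_genes`` lists genes whose expression was constant, for which
    correlations are undefined and adjacencies were set to 0.
    """

    gene_ids: list[str]
    adjacency: np.ndarray
    beta: int
    cohort_label: str = ""
    flagged_genes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PPIAnnotation:
    """Curated annotation for an unordered interacting gene pair."""

    gene_a: str
    gene_b: str
    interaction_types: frozenset[str]
    methods: frozenset[str] = frozenset()
    n_publications: int = 0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction annotation for {self.gene_a}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


class DifferentialNetwork:
    """Undirected graph whose edges carry a differential weight and a cost.

    Thin wrapper over :class:`networkx.Graph`; every edge has attributes
    ``d`` (differential co-expression weight in [0, 1]) and ``cost``
    (``1 - d``, exactly).
    """

    def __init__(self, graph: nx.Graph | None = None, beta: int | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self.beta = beta

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str, dict]]:
        return self.graph.edges(data=True)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": min(u, v), "gene_b": max(u, v), "d": dat["d"], "cost": dat["cost"]}
            for u, v, dat in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "d", "cost"])
        return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    def copy(self) -> "DifferentialNetwork":
        return DifferentialNetwork(self.graph.copy(), beta=self.beta)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path, cohort_label: str = "") -> ExpressionMatrix:
    """Read an expression TSV: first column gene id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        cohort_label=cohort_label,
    )


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_ppi_annotations(path) -> list[PPIAnnotation]:
    """Read the curated PPI annotation TSV.

    Columns: gene_a, gene_b, interaction_types (semicolon-joined), methods
    (semicolon-joined), n_publications.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PPIAnnotation(
                gene_a=str(row.gene_a),
                gene_b=str(row.gene_b),
                interaction_types=frozenset(
                    t.strip() for t in str(row.interaction_types).split(";") if t.strip()
                ),
                methods=frozenset(
                    m.strip() for m in str(row.methods).split(";") if m.strip()
                ),
                n_publications=int(row.n_publications) if str(row.n_publications) else 0,
            )
        )
    return out


def write_ppi_annotations(annotations: Sequence[PPIAnnotation], path) -> None:
    rows = [
        {
            "gene_a": a.gene_a,
            "gene_b": a.gene_b,
            "interaction_types": ";".join(sorted(a.interaction_types)),
            "methods": ";".join(sorted(a.methods)),
            "n_publications": a.n_publications,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "interaction_types", "methods", "n_publications"]).to_csv(
        path, sep="\t", index=False
    )


def write_edge_list(dn: DifferentialNetwork, path) -> None:
    """3-column edge list TSV (gene_a, gene_b, d)."""
    dn.edge_frame()[["gene_a", "gene_b", "d"]].to_csv(path, sep="\t", index=False)


def write_graphml(dn: DifferentialNetwork, path, betweenness_map: Mapping[str, float] | None = None) -> None:
    """GraphML export with node attribute ``betweenness``, edge attrs ``d``/``cost``."""
    g = dn.graph.copy()
    if betweenness_map is None:
        betweenness_map = betweenness(dn)
    nx.set_node_attributes(g, {n: float(betweenness_map.get(n, 0.0)) for n in g.nodes}, "betweenness")
    for _, _, dat in g.edges(data=True):
        ann = dat.pop("annotation", None)
        if ann is not None:  # flatten to GraphML-serializable scalars
            dat["interaction_types"] = ";".join(sorted(ann.interaction_types))
            dat["n_publications"] = int(ann.n_publications)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def compute_adjacency(expr: ExpressionMatrix, beta: int = 10, signed: bool = False) -> CoexpressionNetwork:
    """Soft-thresholded Pearson correlation adjacency.

    Unsigned (default): ``a_ij = |r_ij| ** beta``; signed: ``((1+r)/2) ** beta``.
    Diagonal is set to 0 (no self-edges). Genes with constant expression have
    undefined correlations; their adjacencies are set to 0, a warning is
    emitted, and the genes are recorded in ``flagged_genes``.
    """
    if expr.n_samples < 3:
        raise ValueError(f"need >=3 samples for correlation, got {expr.n_samples}")
    if not (isinstance(beta, (int, np.integer)) and beta >= 1):
        raise ValueError(f"beta must be a positive integer, got {beta!r}")
    x = expr.values
    sd = x.std(axis=1)
    constant = sd == 0.0
    flagged = [g for g, c in zip(expr.gene_ids, constant) if c]
    if flagged:
        warnings.warn(
            f"{len(flagged)} gene(s) with constant expression; their adjacencies set to 0: "
            + ", ".join(flagged[:5]) + ("..." if len(flagged) > 5 else ""),
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    r = np.clip(r, -1.0, 1.0)
    if signed:
        a = ((1.0 + r) / 2.0) ** beta
    else:
        a = np.abs(r) ** beta
    if flagged:
        idx = np.where(constant)[0]
        a[idx, :] = 0.0
        a[:, idx] = 0.0
    np.fill_diagonal(a, 0.0)
    a = (a + a.T) / 2.0  # guard against tiny asymmetries
    return CoexpressionNetwork(
        gene_ids=list(expr.gene_ids),
        adjacency=a,
        beta=int(beta),
        cohort_label=expr.cohort_label,
        flagged_genes=flagged,
    )


def differential_edges(
    net_case: CoexpressionNetwork,
    net_control: CoexpressionNetwork,
    d_floor: float = 0.0,
) -> DifferentialNetwork:
    """Per-edge differential network: ``d = |a_case - a_control|``, ``cost = 1 - d``.

    Both networks must share the soft-threshold power. Gene sets are
    intersected with a warning if they differ; disjoint gene sets are an
    error. Edges with ``d < d_floor`` are dropped (default floor 0 keeps every
    pair, leaving edge selection to the physical-interaction filter).
    """
    if net_case.beta != net_control.beta:
        raise ValueError(f"beta mismatch: {net_case.beta} vs {net_control.beta}")
    genes_case = net_case.gene_ids
    genes_ctrl = net_control.gene_ids
    if genes_case == genes_ctrl:
        genes = list(genes_case)
        a_case = net_case.adjacency
        a_ctrl = net_control.adjacency
    else:
        shared = sorted(set(genes_case) & set(genes_ctrl))
        if not shared:
            raise ValueError("cohort networks have disjoint gene sets")
        warnings.warn(
            f"gene sets differ; intersecting to {len(shared)} shared genes",
            UserWarning,
            stacklevel=2,
        )
        ic = [genes_case.index(g) for g in shared]
        jc = [genes_ctrl.index(g) for g in shared]
        a_case = net_case.adjacency[np.ix_(ic, ic)]
        a_ctrl = net_control.adjacency[np.ix_(jc, jc)]
        genes = shared

    d = np.abs(a_case - a_ctrl)
    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = d[iu, ju] >= d_floor
    for i, j in zip(iu[keep], ju[keep]):
        dij = float(d[i, j])
        g.add_edge(genes[i], genes[j], d=dij, cost=1.0 - dij)
    return DifferentialNetwork(g, beta=net_case.beta)


def filter_physical(
    dn: DifferentialNetwork,
    annotations: Sequence[PPIAnnotation],
    label: str = PHYSICAL_LABEL,
) -> DifferentialNetwork:
    """Keep exactly the edges annotated with the physical-interaction label.

    Label matching is case-insensitive. Annotations for pairs absent from the
    network are ignored. An empty result is a warning, not an error. The
    operation is idempotent and only ever removes edges.
    """
    wanted = label.lower()
    physical_pairs = {
        a.pair for a in annotations if any(t.lower() == wanted for t in a.interaction_types)
    }
    g = nx.Graph()
    ann_by_pair = {a.pair: a for a in annotations}
    kept_nodes: set[str] = set()
    edges = []
    for u, v, dat in dn.graph.edges(data=True):
        pair = (min(u, v), max(u, v))
        if pair in physical_pairs:
            dat = dict(dat)
            dat["annotation"] = ann_by_pair[pair]
            edges.append((u, v, dat))
            kept_nodes.update(pair)
    g.add_nodes_from(sorted(kept_nodes))
    g.add_edges_from(edges)
    if g.number_of_edges() == 0:
        warnings.warn("no edges with physical-interaction annotation survive the filter",
                      UserWarning, stacklevel=2)
    return DifferentialNetwork(g, beta=dn.beta)


def largest_component(dn: DifferentialNetwork) -> DifferentialNetwork:
    """Subgraph induced by the largest connected component.

    Size ties are broken by the lexicographically smallest member gene id so
    the result is deterministic. An empty graph yields an empty network with a
    warning.
    """
    if dn.n_nodes == 0:
        warnings.warn("largest_component of an empty network", UserWarning, stacklevel=2)
        return DifferentialNetwork(nx.Graph(), beta=dn.beta)
    comps = [sorted(c) for c in nx.connected_components(dn.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    best = comps[0]
    return DifferentialNetwork(dn.graph.subgraph(best).copy(), beta=dn.beta)


def betweenness(dn: DifferentialNetwork, weighted: bool = False) -> dict[str, float]:
    """Unnormalized undirected betweenness centrality.

    Default counts unweighted shortest paths; ``weighted=True`` uses the edge
    ``cost`` attribute as distance.
    """
    weight = "cost" if weighted else None
    return dict(nx.betweenness_centrality(dn.graph, normalized=False, weight=weight))
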