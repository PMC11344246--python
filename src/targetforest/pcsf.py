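"""Prize-Collecting Steiner Forest (PCSF) solvers.

The instance is an undirected graph whose nodes carry non-negative prizes
(here: somatic-variant scores) and whose edges carry non-negative costs
(here: 1 - differential co-expression weight). A solution is a forest F
maximizing

    f(F) = sum_{v in F} b * p_v  -  sum_{e in F} c_e  -  omega * kappa(F)

where ``b`` scales prizes against costs, ``omega`` is a per-tree penalty
(kappa(F) = number of trees; an isolated selected node counts as a tree) and
the empty forest (f = 0) is admissible. Selected nodes with positive prize
are Terminals; prize-zero nodes recruited to connect them are Steiner nodes.

Three solution routes are provided: an exact enumeration for small
instances (the test oracle), a Goemans-Williamson-style primal-dual
heuristic with strong pruning and a greedy local-search polish, and a
randomized-edge-cost bootstrap that reruns the heuristic under
multiplicative cost noise and reports per-node occurrence counts plus the
MST-reduced union forest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PCSFInstance",
    "PCSFSolution",
    "OccurrenceTable",
    "solve_exact",
    "solve_heuristic",
    "randomized_runs",
    "components",
    "instance_from_network",
    "read_instance_tsv",
    "write_instance_tsv",
    "write_solution_graphml",
]

_EPS = 1e-12

EXACT_MAX_NODES = 16
EXACT_MAX_EDGES = 20


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass
class PCSFInstance:
    """Prized, edge-costed graph plus the objective parameters omega and b."""

    prizes: dict[str, float]
    edges: list[tuple[str, str, float]]
    omega: float = 0.5
    prize_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError(f"omega must be non-negative, got {self.omega}")
        if self.prize_scale <= 0:
            raise ValueError(f"prize_scale must be positive, got {self.prize_scale}")
        seen = set()
        norm_edges = []
        for u, v, c in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"edge cost must be finite and >=0, got {c} on ({u},{v})")
            pair = (u, v) if u < v else (v, u)
            if pair in seen:
                raise ValueError(f"duplicate edge {pair}")
            seen.add(pair)
            norm_edges.append((pair[0], pair[1], float(c)))
            for x in pair:
                self.prizes.setdefault(x, 0.0)
        for g, p in self.prizes.items():
            if not np.isfinite(p) or p < 0:
                raise ValueError(f"prize must be finite and >=0, got {p} for {g}")
        self.edges = sorted(norm_edges)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.prizes)

    def edge_cost(self) -> dict[tuple[str, str], float]:
        return {(u, v): c for u, v, c in self.edges}

    def scaled_prize(self, v: str) -> float:
        return self.prize_scale * self.prizes.get(v, 0.0)


@dataclass
class PCSFSolution:
    """A forest: selected nodes, tree edges, objective and node roles."""

    nodes: set[str]
    edges: set[tuple[str, str]]
    objective: float
    node_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = {(u, v) if u < v else (v, u) for u, v in self.edges}
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) references an unselected node")
        g = self._graph()
        if g.number_of_nodes() and not nx.is_forest(g):
            raise ValueError("solution contains a cycle")
        if len(self.edges) != self.n_nodes - self.n_components:
            raise ValueError("solution is not a forest (edge/component count mismatch)")

    def _graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_components(self) -> int:
        if not self.nodes:
            return 0
        return nx.number_connected_components(self._graph())

    def component_sets(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self._graph())]


@dataclass
class OccurrenceTable:
    """Per-node selection counts over the randomized bootstrap runs."""

    occurrences: dict[str, int]
    n_runs: int
    noise: float
    seed: int

    def get(self, node: str, default: int = 0) -> int:
        return self.occurrences.get(node, default)

    def to_series(self) -> pd.Series:
        return pd.Series(self.occurrences, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _objective(inst: PCSFInstance, nodes: Iterable[str], edges: Iterable[tuple[str, str]],
               n_components: int) -> float:
    b = inst.prize_scale
    cost = inst.edge_cost()
    return (
        sum(b * inst.prizes.get(v, 0.0) for v in nodes)
        - sum(cost[e] for e in edges)
        - inst.omega * n_components
    )


def _node_types(inst: PCSFInstance, nodes: Iterable[str]) -> dict[str, str]:
    return {v: ("Terminal" if inst.prizes.get(v, 0.0) > 0 else "Steiner") for v in nodes}


class _UnionFind:
    def __init__(self, items: Iterable):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x, y) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[ry] = rx
        return True


# ---------------------------------------------------------------------------
# Exact solver (oracle for small instances)
# ---------------------------------------------------------------------------

def solve_exact(inst: PCSFInstance) -> PCSFSolution:
    """Enumerate every node subset; optimal forest per subset via a rooted MST.

    For a fixed selected node set S the best forest covering S is the minimum
    spanning tree of S plus a virtual root joined to every node at cost omega
    (dropping the root edges yields the tree partition, each paying omega), so
    scanning all 2^|S| subsets in lexicographic order is an exact, fully
    deterministic optimizer. Guarded to small instances; use
    :func:`solve_heuristic` beyond the guard.
    """
    nodes = inst.nodes
    if len(nodes) > EXACT_MAX_NODES or len(inst.edges) > EXACT_MAX_EDGES:
        raise ValueError(
            f"solve_exact is limited to <={EXACT_MAX_NODES} nodes and "
            f"<={EXACT_MAX_EDGES} edges ({len(nodes)} nodes / {len(inst.edges)} edges "
            "given); use solve_heuristic"
        )
    b = inst.prize_scale
    omega = inst.omega
    edges = inst.edges  # already sorted by (u, v)
    # Kruskal scan order: cost, then lexicographic; root edges (cost omega) mixed in.
    real_sorted = sorted(edges, key=lambda e: (e[2], e[0], e[1]))

    best = (0.0, (), ())  # objective, node tuple, edge tuple  (empty forest)
    n = len(nodes)
    for mask in range(1, 1 << n):
        sel = [nodes[i] for i in range(n) if mask >> i & 1]
        sel_set = set(sel)
        prize_sum = sum(b * inst.prizes[v] for v in sel)
        if prize_sum < best[0] - _EPS:  # even a free forest cannot beat the incumbent
            continue
        # Kruskal over S + virtual root (root edges cost omega, added in node order)
        cand = [(c, u, v) for u, v, c in real_sorted if u in sel_set and v in sel_set]
        cand += [(omega, "\x00root", v) for v in sel]
        cand.sort(key=lambda e: (e[0], e[1], e[2]))
        uf = _UnionFind(sel + ["\x00root"])
        mst_cost = 0.0
        chosen = []
        for c, u, v in cand:
            if uf.union(u, v):
                mst_cost += c
                if u != "\x00root":
                    chosen.append((u, v))
        obj = prize_sum - mst_cost
        candidate = (obj, tuple(sel), tuple(sorted(chosen)))
        if obj > best[0] + _EPS:
            best = candidate
        elif abs(obj - best[0]) <= _EPS and (candidate[1], candidate[2]) < (best[1], best[2]):
            best = candidate  # tie: lexicographically smallest node set, then edge set
    obj, sel, chosen = best
    return PCSFSolution(
        nodes=set(sel),
        edges=set(chosen),
        objective=obj,
        node_types=_node_types(inst, sel),
    )


# ---------------------------------------------------------------------------
# Goemans-Williamson-style heuristic
# ---------------------------------------------------------------------------

def _gw_grow(inst: PCSFInstance) -> list[tuple[str, str]]:
    """Primal-dual moat growth on the virtual-root transformation.

    Every node is linked to a virtual root by an edge of cost omega. Clusters
    not containing the root grow uniform duals until either an inter-cluster
    edge goes tight (merge; the edge joins the tentative forest) or the
    cluster's prize potential is exhausted (deactivate). Returns the tight
    merge edges (root edges excluded).

    Vectorized event simulation: cluster membership is a flat relabelling
    array, so each event costs O(n + m) numpy work and there are at most 2n
    events.
    """
    nodes = inst.nodes
    n = len(nodes)
    if n == 0:
        return []
    idx_of = {v: i for i, v in enumerate(nodes)}
    root_cluster = n
    b = inst.prize_scale

    eu = np.array([idx_of[u] for u, v, _ in inst.edges] + list(range(n)), dtype=np.intp)
    ev = np.array([idx_of[v] for u, v, _ in inst.edges] + [n] * n, dtype=np.intp)
    cost = np.array([c for _, _, c in inst.edges] + [inst.omega] * n, dtype=float)
    load = np.zeros_like(cost)
    is_root_edge = np.arange(len(cost)) >= len(inst.edges)

    comp = np.arange(n + 1, dtype=np.intp)  # cluster id per node; n is the root
    active = np.zeros(n + 1, dtype=bool)
    surplus = np.zeros(n + 1, dtype=float)
    for i, v in enumerate(nodes):
        surplus[i] = b * inst.prizes[v]
        active[i] = surplus[i] > _EPS
    merge_edges: list[tuple[str, str]] = []

    while active.any():
        cu, cv = comp[eu], comp[ev]
        rate = active[cu].astype(np.int64) + active[cv].astype(np.int64)
        live = (cu != cv) & (rate > 0)
        t_edge = np.full(len(cost), np.inf)
        t_edge[live] = (cost[live] - load[live]) / rate[live]
        e_best = int(np.argmin(t_edge))
        e_time = t_edge[e_best]

        t_clu = np.where(active, surplus, np.inf)
        c_best = int(np.argmin(t_clu))
        c_time = t_clu[c_best]

        delta = min(e_time, c_time)
        if not np.isfinite(delta):
            break
        delta = max(delta, 0.0)
        surplus[active] -= delta
        load[live] += delta * rate[live]

        if e_time <= c_time + _EPS:
            a, bcl = comp[eu[e_best]], comp[ev[e_best]]
            new, old = (a, bcl) if a < bcl else (bcl, a)
            if root_cluster in (a, bcl):
                new, old = root_cluster, (a if bcl == root_cluster else bcl)
            comp[comp == old] = new
            if new == root_cluster:
                surplus[new] = 0.0
                active[new] = False
            else:
                surplus[new] = surplus[a] + surplus[bcl]
                active[new] = surplus[new] > _EPS
            active[old] = False
            if not is_root_edge[e_best]:
                u, v, _ = inst.edges[e_best]
                merge_edges.append((u, v))
        else:
            active[c_best] = False
    return merge_edges


def _strong_prune(tree_nodes: list[str], tree_edges: list[tuple[str, str]],
                  weight: Mapping[str, float], cost: Mapping[tuple[str, str], float],
                  ) -> tuple[float, set[str], set[tuple[str, str]]]:
    """Best net-worth subtree of a tree (node weights minus edge costs).

    Rerooting DP over all directed edges; returns (value, nodes, edges) of the
    best subtree, which always contains at least one node.
    """
    if len(tree_nodes) == 1:
        v = tree_nodes[0]
        return weight.get(v, 0.0), {v}, set()
    adj: dict[str, list[str]] = {v: [] for v in tree_nodes}
    for u, v in tree_edges:
        adj[u].append(v)
        adj[v].append(u)
    for v in adj:
        adj[v].sort()

    def ecost(u, v):
        return cost[(u, v) if u < v else (v, u)]

    rootv = tree_nodes[0]
    order = []
    parent: dict[str, str | None] = {rootv: None}
    stack = [rootv]
    while stack:
        x = stack.pop()
        order.append(x)
        for y in adj[x]:
            if y != parent[x]:
                parent[y] = x
                stack.append(y)
    # dval[(u, v)] = value of the best subtree containing u on u's side of edge (u, v)
    dval: dict[tuple[str, str], float] = {}
    for x in reversed(order):  # children before parents
        p = parent[x]
        if p is not None:
            dval[(x, p)] = weight.get(x, 0.0) + sum(
                max(0.0, dval[(y, x)] - ecost(x, y)) for y in adj[x] if y != p
            )
    for x in order:  # parents before children
        for y in adj[x]:
            if parent.get(y) == x:
                dval[(x, y)] = weight.get(x, 0.0) + sum(
                    max(0.0, dval[(z, x)] - ecost(x, z)) for z in adj[x] if z != y
                )
    best_of = {
        v: weight.get(v, 0.0)
        + sum(max(0.0, dval[(u, v)] - ecost(u, v)) for u in adj[v])
        for v in tree_nodes
    }
    best_v = min(tree_nodes, key=lambda v: (-best_of[v], v))
    best_val = best_of[best_v]
    # reconstruct: from best_v include every neighbour whose directed value is profitable
    keep_nodes = {best_v}
    keep_edges: set[tuple[str, str]] = set()
    stack2: list[tuple[str, str | None]] = [(best_v, None)]
    while stack2:
        x, par = stack2.pop()
        for y in adj[x]:
            if y == par:
                continue
            if dval[(y, x)] - ecost(x, y) > _EPS:
                keep_nodes.add(y)
                keep_edges.add((x, y) if x < y else (y, x))
                stack2.append((y, x))
    return best_val, keep_nodes, keep_edges


def _local_search(inst: PCSFInstance, nodes: set[str], edges: set[tuple[str, str]]
                  ) -> tuple[set[str], set[tuple[str, str]]]:
    """Greedy hill-climb over single add/remove/merge/split moves."""
    b = inst.prize_scale
    omega = inst.omega
    cost = inst.edge_cost()
    neighbours: dict[str, list[tuple[str, float]]] = {v: [] for v in inst.nodes}
    for (u, v), c in cost.items():
        neighbours[u].append((v, c))
        neighbours[v].append((u, c))

    def comp_id() -> dict[str, int]:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        out = {}
        for i, c in enumerate(nx.connected_components(g)):
            for v in c:
                out[v] = i
        return out

    max_rounds = 4 * (len(inst.nodes) + 1)
    for _ in range(max_rounds):
        cid = comp_id()
        deg: dict[str, int] = {v: 0 for v in nodes}
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        best_gain, best_move = _EPS, None
        # add singleton
        for v in inst.nodes:
            if v not in nodes:
                gain = b * inst.prizes[v] - omega
                if gain > best_gain:
                    best_gain, best_move = gain, ("add_singleton", v)
        # attach an outside node to a tree / merge two trees / split
        for (u, v), c in cost.items():
            iu, iv = u in nodes, v in nodes
            if iu and not iv:
                gain = b * inst.prizes[v] - c
                if gain > best_gain:
                    best_gain, best_move = gain, ("attach", v, (u, v))
            elif iv and not iu:
                gain = b * inst.prizes[u] - c
                if gain > best_gain:
                    best_gain, best_move = gain, ("attach", u, (u, v))
            elif iu and iv and cid[u] != cid[v]:
                gain = omega - c
                if gain > best_gain:
                    best_gain, best_move = gain, ("merge", (u, v))
        for u, v in edges:
            gain = cost[(u, v)] - omega
            if gain > best_gain:
                best_gain, best_move = gain, ("split", (u, v))
        # two-step moves through an outside node w: attach a path w-v, or
        # bridge two trees via w (escapes single-move local optima)
        for w in inst.nodes:
            if w in nodes:
                continue
            f_nb = [(u, c) for u, c in neighbours[w] if u in nodes]
            o_nb = [(v, c) for v, c in neighbours[w] if v not in nodes]
            if f_nb:
                ubest, cu = min(f_nb, key=lambda t: (t[1], t[0]))
                for v, cv in o_nb:
                    gain = b * (inst.prizes[w] + inst.prizes[v]) - cu - cv
                    if gain > best_gain:
                        best_gain = gain
                        best_move = ("attach_path", (w, v),
                                     ((min(ubest, w), max(ubest, w)),
                                      (min(w, v), max(w, v))))
            if len(f_nb) >= 2:
                by_comp: dict[int, tuple[str, float]] = {}
                for u, c in f_nb:
                    k = cid[u]
                    if k not in by_comp or (c, u) < (by_comp[k][1], by_comp[k][0]):
                        by_comp[k] = (u, c)
                if len(by_comp) >= 2:
                    two = sorted(by_comp.values(), key=lambda t: (t[1], t[0]))[:2]
                    (u1, c1), (u2, c2) = two
                    gain = b * inst.prizes[w] - c1 - c2 + omega
                    if gain > best_gain:
                        best_gain = gain
                        best_move = ("bridge", w,
                                     ((min(u1, w), max(u1, w)),
                                      (min(u2, w), max(u2, w))))
        # remove any node (leaf, singleton, or internal — splitting its tree)
        for v in sorted(nodes):
            incident = [e for e in edges if v in e]
            gain = sum(cost[e] for e in incident) - b * inst.prizes[v] \
                - omega * (len(incident) - 1)
            if gain > best_gain:
                best_gain, best_move = gain, ("remove_node", v, tuple(incident))
        # cycle improvement: add a non-forest edge inside one tree, then delete
        # either the costliest path edge or a degree-2 path node
        tree_adj: dict[str, list[str]] = {v: [] for v in nodes}
        for u, v in edges:
            tree_adj[u].append(v)
            tree_adj[v].append(u)
        for (u, v), c_uv in cost.items():
            if (u, v) in edges or u not in nodes or v not in nodes or cid[u] != cid[v]:
                continue
            # unique tree path u -> v
            parent = {u: None}
            stack = [u]
            while stack and v not in parent:
                x = stack.pop()
                for y in tree_adj[x]:
                    if y not in parent:
                        parent[y] = x
                        stack.append(y)
            path = [v]
            while path[-1] != u:
                path.append(parent[path[-1]])
            path_edges = [
                (min(a, bb), max(a, bb)) for a, bb in zip(path, path[1:])
            ]
            worst = max(path_edges, key=lambda e: (cost[e], e))
            gain = cost[worst] - c_uv
            if gain > best_gain:
                best_gain, best_move = gain, ("swap_edge", (u, v), worst)
            for w in path[1:-1]:
                if deg[w] == 2:
                    e1 = (min(w, parent[w]), max(w, parent[w]))
                    i = path.index(w)
                    nxt = path[i - 1]
                    e2 = (min(w, nxt), max(w, nxt))
                    gain = cost[e1] + cost[e2] - b * inst.prizes[w] - c_uv
                    if gain > best_gain:
                        best_gain, best_move = gain, ("reroute", (u, v), w, (e1, e2))
        if best_move is None:
            break
        kind = best_move[0]
        if kind == "add_singleton":
            nodes.add(best_move[1])
        elif kind == "attach":
            nodes.add(best_move[1])
            edges.add(best_move[2])
        elif kind in ("merge",):
            edges.add(best_move[1])
        elif kind == "split":
            edges.discard(best_move[1])
        elif kind == "remove_node":
            nodes.discard(best_move[1])
            edges.difference_update(best_move[2])
        elif kind == "swap_edge":
            edges.add(best_move[1])
            edges.discard(best_move[2])
        elif kind == "reroute":
            edges.add(best_move[1])
            nodes.discard(best_move[2])
            edges.difference_update(best_move[3])
        elif kind == "attach_path":
            nodes.update(best_move[1])
            edges.update(best_move[2])
        elif kind == "bridge":
            nodes.add(best_move[1])
            edges.update(best_move[2])
    return nodes, edges


def solve_heuristic(inst: PCSFInstance) -> PCSFSolution:
    """Primal-dual growth + strong pruning + greedy local search.

    Deterministic given the instance (nodes and edges are processed in sorted
    order). Always returns a valid forest with objective >= 0: components
    whose pruned net worth does not exceed the per-tree penalty omega are
    dropped, and the empty forest is the fallback.
    """
    merge_edges = _gw_grow(inst)
    b = inst.prize_scale
    weight = {v: b * p for v, p in inst.prizes.items()}
    cost = inst.edge_cost()

    g = nx.Graph()
    g.add_nodes_from(inst.nodes)
    g.add_edges_from(merge_edges)
    sel_nodes: set[str] = set()
    sel_edges: set[tuple[str, str]] = set()
    for comp in nx.connected_components(g):
        tnodes = sorted(comp)
        tedges = [e for e in merge_edges if e[0] in comp and e[1] in comp]
        val, knodes, kedges = _strong_prune(tnodes, tedges, weight, cost)
        if val - inst.omega > _EPS:
            sel_nodes |= knodes
            sel_edges |= kedges
    sel_nodes, sel_edges = _local_search(inst, sel_nodes, sel_edges)
    g2 = nx.Graph()
    g2.add_nodes_from(sel_nodes)
    g2.add_edges_from(sel_edges)
    ncomp = nx.number_connected_components(g2) if sel_nodes else 0
    obj = _objective(inst, sel_nodes, sel_edges, ncomp)
    if obj < 0:  # safety net: empty forest is always admissible
        sel_nodes, sel_edges, obj = set(), set(), 0.0
    return PCSFSolution(
        nodes=sel_nodes,
        edges=sel_edges,
        objective=obj,
        node_types=_node_types(inst, sel_nodes),
    )


# ---------------------------------------------------------------------------
# Randomized-edge-cost bootstrap
# ---------------------------------------------------------------------------

def randomized_runs(
    inst: PCSFInstance,
    n_runs: int = 50,
    noise: float = 0.1,
    seed: int = 0,
) -> tuple[OccurrenceTable, PCSFSolution]:
    """Rerun the heuristic under multiplicative edge-cost noise.

    Run r perturbs each edge cost to ``c * (1 + u)`` with
    ``u ~ Uniform(-noise, +noise)`` drawn from a generator seeded by
    ``(seed, r)``. Occurrences count, per node, the runs whose solution
    contains it. The union of all run forests may contain cycles; each union
    component is reduced to its minimum spanning tree under the ORIGINAL
    costs, restoring the per-subgraph tree property. Deterministic given the
    seed.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >=1, got {n_runs}")
    if not (0.0 <= noise < 1.0):
        raise ValueError(f"noise must be in [0, 1), got {noise}")
    if noise == 0.0:
        warnings.warn("noise=0: all runs are identical and occurrences are degenerate",
                      UserWarning, stacklevel=2)
    occurrences: dict[str, int] = {}
    union_nodes: set[str] = set()
    union_edges: set[tuple[str, str]] = set()
    base_edges = inst.edges
    for r in range(n_runs):
        rng = np.random.default_rng([int(seed), r])
        u = rng.uniform(-noise, noise, size=len(base_edges))
        pert = [(a, b2, c * (1.0 + ui)) for (a, b2, c), ui in zip(base_edges, u)]
        run_inst = PCSFInstance(
            prizes=dict(inst.prizes), edges=pert,
            omega=inst.omega, prize_scale=inst.prize_scale,
        )
        sol = solve_heuristic(run_inst)
        for v in sol.nodes:
            occurrences[v] = occurrences.get(v, 0) + 1
        union_nodes |= sol.nodes
        union_edges |= sol.edges

    # MST-reduce each union component under original costs
    cost = inst.edge_cost()
    g = nx.Graph()
    g.add_nodes_from(union_nodes)
    for e in union_edges:
        g.add_edge(*e, weight=cost[e])
    forest_edges: set[tuple[str, str]] = set()
    for comp in nx.connected_components(g):
        sub = sorted(
            ((cost[(min(u, v), max(u, v))], min(u, v), max(u, v))
             for u, v in g.subgraph(comp).edges()),
        )
        uf = _UnionFind(comp)
        for c, a, b2 in sub:
            if uf.union(a, b2):
                forest_edges.add((a, b2))
    ncomp = nx.number_connected_components(g) if union_nodes else 0
    union_sol = PCSFSolution(
        nodes=union_nodes,
        edges=forest_edges,
        objective=_objective(inst, union_nodes, forest_edges, ncomp),
        node_types=_node_types(inst, union_nodes),
    )
    table = OccurrenceTable(
        occurrences=occurrences, n_runs=n_runs, noise=noise, seed=int(seed)
    )
    return table, union_sol


def components(sol: PCSFSolution) -> list[tuple[int, set[str], int]]:
    """(cluster_id, node set, size) per tree, largest first, ids 1..k."""
    comps = [sorted(c) for c in sol.component_sets()]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [(i + 1, set(c), len(c)) for i, c in enumerate(comps)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def instance_from_network(dn, prize_map, omega: float = 0.5, prize_scale: float = 1.0
                          ) -> PCSFInstance:
    """Build an instance from a differential network and a prize map.

    Prized genes absent from the network are dropped (they cannot be
    connected); network genes without variants get prize 0.
    """
    prizes = {v: prize_map.get(v, 0.0) for v in dn.graph.nodes}
    edges = [(u, v, dat["cost"]) for u, v, dat in dn.graph.edges(data=True)]
    return PCSFInstance(prizes=prizes, edges=edges, omega=omega, prize_scale=prize_scale)


def read_instance_tsv(nodes_path, edges_path, omega: float = 0.5, prize_scale: float = 1.0
                      ) -> PCSFInstance:
    ndf = pd.read_csv(nodes_path, sep="\t")
    edf = pd.read_csv(edges_path, sep="\t")
    prizes = {str(r.gene): float(r.prize) for r in ndf.itertuples(index=False)}
    edges = [(str(r.gene_a), str(r.gene_b), float(r.cost)) for r in edf.itertuples(index=False)]
    return PCSFInstance(prizes=prizes, edges=edges, omega=omega, prize_scale=prize_scale)


def write_instance_tsv(inst: PCSFInstance, nodes_path, edges_path) -> None:
    pd.DataFrame(
        [{"gene": g, "prize": p} for g, p in sorted(inst.prizes.items())]
    ).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(
        [{"gene_a": u, "gene_b": v, "cost": c} for u, v, c in inst.edges]
    ).to_csv(edges_path, sep="\t", index=False)


def write_solution_graphml(sol: PCSFSolution, inst: PCSFInstance, path,
                           occurrences: OccurrenceTable | None = None) -> None:
    g = nx.Graph()
    clusters = {v: cid for cid, cset, _ in components(sol) for v in cset}
    for v in sorted(sol.nodes):
        g.add_node(
            v,
            type=sol.node_types.get(v, "Steiner"),
            prize=float(inst.prizes.get(v, 0.0)),
            occurrences=int(occurrences.get(v)) if occurrences else 0,
            cluster=int(clusters.get(v, 0)),
        )
    cost = inst.edge_cost()
    for u, v in sorted(sol.edges):
        g.add_edge(u, v, cost=float(cost[(u, v)]))
    nx.write_graphml(g, path)


def write_run_manifest(path, *, seed: int, n_runs: int, noise: float,
                       omega: float, prize_scale: float, **extra) -> None:
    manifest = dict(seed=seed, n_runs=n_runs, noise=noise, omega=omega,
                    prize_scale=prize_scale, **extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
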