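"""Differential co-expression network construction and topology metrics."""

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from targetforest.networks import (
    DifferentialNetwork,
    ExpressionMatrix,
    PPIAnnotation,
    betweenness,
    compute_adjacency,
    differential_edges,
    filter_physical,
    largest_component,
)


def _expr_with_correlation(r: float, n: int = 30, seed: int = 0) -> ExpressionMatrix:
    """Two genes whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    zx = (x - x.mean()) / x.std()
    z_perp = z - (z @ zx) / (zx @ zx) * zx
    z_perp = (z_perp - z_perp.mean()) / z_perp.std()
    y = r * zx + np.sqrt(1 - r**2) * z_perp
    m = ExpressionMatrix(["gA", "gB"], [f"s{i}" for i in range(n)], np.vstack([zx, y]))
    assert abs(np.corrcoef(m.values)[0, 1] - r) < 1e-12
    return m


class TestComputeAdjacency:
    @pytest.mark.parametrize(
        "r,beta,expected",
        [
            (1.0, 10, 1.0),               # identical profiles
            (0.5, 10, 0.5**10),           # 0.0009765625
            (-1.0, 10, 1.0),              # unsigned convention: |-1|^10
            (-0.5, 10, 0.5**10),
        ],
    )
    def test_soft_threshold_values(self, r, beta, expected):
        if abs(r) == 1.0:
            x = np.arange(5, dtype=float)
            m = ExpressionMatrix(["gA", "gB"], list("abcde"), np.vstack([x, r * x]))
        else:
            m = _expr_with_correlation(r)
        net = compute_adjacency(m, beta=beta)
        assert net.adjacency[0, 1] == pytest.approx(expected, abs=1e-12)
        assert net.adjacency[0, 0] == 0.0  # self-edges excluded

    def test_signed_convention(self):
        x = np.arange(5, dtype=float)
        m = ExpressionMatrix(["gA", "gB"], list("abcde"), np.vstack([x, -x]))
        net = compute_adjacency(m, beta=10, signed=True)
        assert net.adjacency[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_flagged_and_zeroed(self):
        vals = np.vstack([np.arange(5.0), np.full(5, 3.0), np.arange(5.0)[::-1]])
        m = ExpressionMatrix(["gA", "gflat", "gC"], list("abcde"), vals)
        with pytest.warns(UserWarning, match="constant"):
            net = compute_adjacency(m, beta=10)
        assert net.flagged_genes == ["gflat"]
        assert np.all(net.adjacency[1, :] == 0.0)
        assert net.adjacency[0, 2] == pytest.approx(1.0)

    def test_requires_three_samples_and_valid_beta(self):
        m = ExpressionMatrix(["gA", "gB"], ["s1", "s2"], np.ones((2, 2)) * [[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="samples"):
            compute_adjacency(m)
        m3 = ExpressionMatrix(["gA", "gB"], list("abc"), np.arange(6.0).reshape(2, 3))
        with pytest.raises(ValueError, match="beta"):
            compute_adjacency(m3, beta=0)

    @settings(max_examples=50, derandomize=True)
    @given(
        r1=st.floats(0.0, 1.0, exclude_max=True),
        r2=st.floats(0.0, 1.0, exclude_max=True),
        beta=st.integers(1, 12),
    )
    def test_monotone_in_absolute_correlation(self, r1, r2, beta):
        a1, a2 = r1**beta, r2**beta
        if r1 < r2:
            assert a1 < a2 or (a1 == a2 == 0.0)
        assert 0.0 <= a1 <= 1.0


def _net_from_matrix(genes, a, beta=10):
    return type("N", (), {"gene_ids": genes, "adjacency": np.asarray(a, float), "beta": beta})()


class TestDifferentialEdges:
    @pytest.mark.parametrize(
        "a_case,a_ctrl,d,c",
        [(0.7, 0.7, 0.0, 1.0), (1.0, 0.0, 1.0, 0.0), (0.8, 0.3, 0.5, 0.5)],
    )
    def test_weight_and_cost(self, a_case, a_ctrl, d, c):
        genes = ["gA", "gB"]
        dn = differential_edges(
            _net_from_matrix(genes, [[0, a_case], [a_case, 0]]),
            _net_from_matrix(genes, [[0, a_ctrl], [a_ctrl, 0]]),
        )
        dat = dn.graph.edges["gA", "gB"]
        assert dat["d"] == pytest.approx(d, abs=1e-15)
        assert dat["cost"] == pytest.approx(c, abs=1e-15)
        assert dat["d"] + dat["cost"] == 1.0  # exact identity

    def test_symmetric_in_cohort_labels(self, rng):
        n = 6
        genes = [f"g{i}" for i in range(n)]
        a = np.abs(rng.uniform(size=(n, n))); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = np.abs(rng.uniform(size=(n, n))); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        d1 = differential_edges(_net_from_matrix(genes, a), _net_from_matrix(genes, b))
        d2 = differential_edges(_net_from_matrix(genes, b), _net_from_matrix(genes, a))
        for u, v, dat in d1.edges():
            assert d2.graph.edges[u, v]["d"] == dat["d"]

    def test_gene_set_mismatch(self):
        n1 = _net_from_matrix(["gA", "gB"], [[0, 0.5], [0.5, 0]])
        n2 = _net_from_matrix(["gB", "gC"], [[0, 0.5], [0.5, 0]])
        with pytest.warns(UserWarning, match="intersect"):
            dn = differential_edges(n1, n2)
        assert dn.nodes == ["gB"]
        n3 = _net_from_matrix(["gX", "gY"], [[0, 0.5], [0.5, 0]])
        with pytest.raises(ValueError, match="disjoint"):
            differential_edges(n1, n3)

    def test_beta_mismatch_is_error(self):
        n1 = _net_from_matrix(["gA", "gB"], [[0, 0.5], [0.5, 0]], beta=10)
        n2 = _net_from_matrix(["gA", "gB"], [[0, 0.5], [0.5, 0]], beta=6)
        with pytest.raises(ValueError, match="beta"):
            differential_edges(n1, n2)


def _toy_network(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, d=0.5, cost=0.5)
    return DifferentialNetwork(g)


def _phys(a, b):
    return PPIAnnotation(a, b, frozenset({"physical interaction"}))


class TestFilterPhysical:
    def test_retains_only_physical_pairs(self):
        dn = _toy_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "A")])
        ann = [
            _phys("A", "B"),
            _phys("C", "B"),
            PPIAnnotation("C", "D", frozenset({"co-expression"})),
            _phys("X", "Y"),  # pair absent from the network: ignored
        ]
        out = filter_physical(dn, ann)
        assert {tuple(sorted(e[:2])) for e in out.edges()} == {("A", "B"), ("B", "C")}

    def test_empty_result_warns(self):
        dn = _toy_network([("A", "B")])
        with pytest.warns(UserWarning, match="no edges"):
            out = filter_physical(dn, [])
        assert out.n_edges == 0

    def test_idempotent_and_subset(self):
        dn = _toy_network([("A", "B"), ("B", "C"), ("C", "A")])
        ann = [_phys("A", "B"), _phys("B", "C")]
        once = filter_physical(dn, ann)
        twice = filter_physical(once, ann)
        e_in = {tuple(sorted(e[:2])) for e in dn.edges()}
        e1 = {tuple(sorted(e[:2])) for e in once.edges()}
        e2 = {tuple(sorted(e[:2])) for e in twice.edges()}
        assert e1 == e2 and e1 <= e_in

    def test_case_insensitive_label(self):
        dn = _toy_network([("A", "B")])
        ann = [PPIAnnotation("A", "B", frozenset({"Physical Interaction"}))]
        assert filter_physical(dn, ann).n_edges == 1


class TestLargestComponent:
    def test_picks_largest(self):
        dn = _toy_network([("A", "B"), ("B", "C"), ("D", "E")])
        assert sorted(largest_component(dn).nodes) == ["A", "B", "C"]

    def test_tie_breaks_lexicographically(self):
        dn = _toy_network([("C", "D"), ("A", "B")])
        assert sorted(largest_component(dn).nodes) == ["A", "B"]

    def test_connected_graph_is_identity(self):
        dn = _toy_network([("A", "B"), ("B", "C")])
        assert sorted(largest_component(dn).nodes) == sorted(dn.nodes)

    def test_empty_graph_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = largest_component(DifferentialNetwork())
        assert out.n_nodes == 0


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Exhaustive simple-path enumeration oracle for unnormalized betweenness."""
    nodes = sorted(graph.nodes)
    bc = {v: 0.0 for v in nodes}
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}

    def all_paths(s, t):
        out, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                out.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return out

    for s, t in combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(sp)
    return bc


class TestBetweenness:
    def test_path_and_star(self):
        path = _toy_network([("A", "B"), ("B", "C")])
        assert betweenness(path) == {"A": 0.0, "B": 1.0, "C": 0.0}
        star = _toy_network([("X", "a"), ("X", "b"), ("X", "c")])
        assert betweenness(star)["X"] == 3.0

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(n)})
            nx.set_edge_attributes(g, 0.5, "cost")
            dn = DifferentialNetwork(g)
            oracle = brute_force_betweenness(g)
            got = betweenness(dn)
            for v in oracle:
                assert got[v] == pytest.approx(oracle[v], abs=1e-9)
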