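import io
import itertools

import networkx as nx
import numpy as np
import pytest

from netpharm.network import (
    EdgeListError,
    Network,
    average_degree,
    average_degree_from_counts,
    build_tripartite,
    node_topology,
    read_edge_list,
    write_edge_list,
)
from oracles import betweenness_by_enumeration


class TestReadEdgeList:
    def test_minimal_path_graph(self):
        net = read_edge_list(io.StringIO("A\tB\nB\tC\n"))
        assert net.n_nodes == 3 and net.n_edges == 2

    def test_duplicates_and_reversals_collapse(self):
        net = read_edge_list(io.StringIO("A\tB\nB\tA\nA\tB\n"))
        assert net.n_nodes == 2 and net.n_edges == 1

    def test_self_loops_dropped_against_set_oracle(self):
        rng = np.random.default_rng(7)
        lines, pairs = [], set()
        nodes = [f"g{i}" for i in range(12)]
        for i in range(90):
            u, v = rng.choice(nodes, size=2, replace=True)
            while u == v:
                u, v = rng.choice(nodes, size=2, replace=True)
            lines.append(f"{u}\t{v}")
            pairs.add(frozenset((u, v)))
        for i in range(10):  # ten self-loops scattered in
            n = nodes[i]
            lines.insert(i * 9, f"{n}\t{n}")
        net = read_edge_list(io.StringIO("\n".join(lines) + "\n"))
        assert net.edges == pairs
        assert net.n_edges == len(pairs)

    def test_extra_columns_and_comments_ignored(self):
        net = read_edge_list(io.StringIO("# header\nA\tB\t0.9\nB\tC\t0.4\n"))
        assert net.n_edges == 2

    def test_malformed_line_names_line_number(self):
        with pytest.raises(EdgeListError, match="line 2"):
            read_edge_list(io.StringIO("A\tB\njustone\n"))

    def test_empty_input_raises(self):
        with pytest.raises(EdgeListError, match="empty"):
            read_edge_list(io.StringIO("# only a comment\n"))

    def test_round_trip_is_idempotent(self):
        rng = np.random.default_rng(3)
        edges = [
            (f"n{rng.integers(20)}", f"n{rng.integers(20)}") for _ in range(60)
        ]
        net = Network.from_edges(edges)
        buf = io.StringIO()
        write_edge_list(net, buf)
        again = read_edge_list(io.StringIO(buf.getvalue()))
        assert again.nodes == net.nodes and again.edges == net.edges


class TestNodeTopology:
    def test_path_graph_hand_enumeration(self, path_graph):
        topo = node_topology(path_graph)
        assert topo.loc["A", "avg_shortest_path"] == pytest.approx(1.5)
        assert topo.loc["B", "betweenness"] == pytest.approx(1.0)
        assert topo.loc["A", "betweenness"] == 0.0

    def test_star_center_and_leaves(self, star_graph):
        topo = node_topology(star_graph)
        assert topo.loc["c", "avg_shortest_path"] == pytest.approx(1.0)
        assert topo.loc["c", "betweenness"] == pytest.approx(1.0)
        leaves = topo.drop("c")
        assert (leaves["betweenness"] == 0).all()
        np.testing.assert_allclose(leaves["avg_shortest_path"], 2 - 1 / 5)

    def test_betweenness_matches_path_enumeration_oracle(self):
        """Brandes accumulation vs exhaustive shortest-path enumeration
        on 30 random graphs with up to 25 nodes."""
        from conftest import random_graph

        rng = np.random.default_rng(42)
        for _ in range(30):
            g = random_graph(rng)
            net = Network(graph=g)
            topo = node_topology(net)
            oracle = betweenness_by_enumeration(g)
            for v in g.nodes:
                assert topo.loc[v, "betweenness"] == pytest.approx(
                    oracle[v], abs=1e-12
                )

    def test_tree_raw_betweenness_equals_interior_pair_count(self):
        """On a tree the unique s-t path makes total raw betweenness
        equal the number of (unordered) pairs times interior nodes on
        their path, i.e. sum over pairs of (d(s,t) - 1)."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            t = nx.random_labeled_tree(int(rng.integers(4, 15)),
                                       seed=int(rng.integers(2**31)))
            raw = nx.betweenness_centrality(t, normalized=False)
            expected = sum(
                nx.shortest_path_length(t, s, u) - 1
                for s, u in itertools.combinations(t.nodes, 2)
            )
            assert sum(raw.values()) == pytest.approx(expected)

    def test_avg_shortest_path_invariant_under_relabeling(self):
        from conftest import random_graph

        rng = np.random.default_rng(11)
        g = random_graph(rng)
        topo = node_topology(Network(graph=g))
        perm = {v: f"x{i}" for i, v in enumerate(sorted(g.nodes))}
        topo2 = node_topology(Network(graph=nx.relabel_nodes(g, perm)))
        for v in g.nodes:
            a, b = topo.loc[v, "avg_shortest_path"], topo2.loc[perm[v], "avg_shortest_path"]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)

    def test_isolated_node_has_undefined_path_length(self):
        net = Network.from_edges([("A", "B")], nodes=["Z"])
        topo = node_topology(net)
        assert np.isnan(topo.loc["Z", "avg_shortest_path"])
        assert topo.loc["Z", "component_size"] == 1

    def test_disconnected_components_scored_separately(self):
        net = Network.from_edges([("A", "B"), ("B", "C"), ("X", "Y")])
        topo = node_topology(net)
        assert topo.loc["X", "avg_shortest_path"] == pytest.approx(1.0)
        assert topo.loc["X", "betweenness"] == 0.0
        assert topo.loc["B", "betweenness"] == pytest.approx(1.0)


class TestAverageDegree:
    def test_published_network_counts(self):
        assert average_degree_from_counts(432, 1540) == pytest.approx(7.13, abs=0.005)

    def test_path_graph(self, path_graph):
        assert average_degree(path_graph) == pytest.approx(4 / 3)

    def test_k_regular_graph(self):
        g = nx.random_regular_graph(4, 10, seed=1)
        assert average_degree(Network(graph=g)) == pytest.approx(4.0)

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            average_degree(Network())


class TestBuildTripartite:
    COMPOUNDS = {
        "matrine": ["CASP3", "MMP2", "MYC"],
        "oxymatrine": ["MMP2", "REG1A"],
        "sophoridine": ["MMP2", "REG1A"],
        "N-methylcytisine": ["MMP2"],
    }

    def test_compound_degrees_match_narrative(self):
        net = build_tripartite(self.COMPOUNDS)
        assert net.degree("matrine") >= 3
        assert net.node_role["matrine"] == "compound"
        assert net.node_role["CASP3"] == "target"

    def test_empty_gene_map_gives_bipartite_graph(self):
        net = build_tripartite(self.COMPOUNDS, None, {})
        assert set(net.node_role.values()) == {"compound", "target"}

    def test_random_three_layer_against_set_union_oracle(self):
        rng = np.random.default_rng(19)
        ct = {f"c{i}": [f"t{j}" for j in rng.integers(0, 5, 3)] for i in range(4)}
        tp = Network.from_edges(
            [(f"t{rng.integers(5)}", f"p{rng.integers(6)}") for _ in range(10)]
        )
        gm = {f"p{i}": [f"m{j}" for j in rng.integers(0, 4, 2)] for i in range(6)}
        net = build_tripartite(ct, tp, gm)
        expected = set()
        for c, ts in ct.items():
            expected |= {frozenset((c, t)) for t in ts}
        expected |= tp.edges
        for g, ms in gm.items():
            expected |= {frozenset((g, m)) for m in ms}
        assert net.edges == expected

    def test_conflicting_roles_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            build_tripartite({"drugA": ["T1"]}, None, {"G1": ["drugA"]})
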