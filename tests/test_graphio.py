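"""Network data model, edge-list / Pajek parsing, and topology statistics."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spreadrank.generators import BAParams, barabasi_albert, fixture_graph
from spreadrank.graphio import (
    GraphParseError,
    Network,
    degree_assortativity,
    giant_component,
    mean_shortest_path_length,
    read_edge_list,
    read_pajek,
    topology_stats,
    write_edge_list,
)

from conftest import random_graph


class TestNetwork:
    def test_canonicalizes_edges(self):
        net = Network(3, [(2, 1), (1, 0), (0, 1)])
        assert net.n_edges == 2
        assert net.edge_set() == {(0, 1), (1, 2)}

    def test_rejects_self_loop_and_out_of_range(self):
        with pytest.raises(ValueError):
            Network(3, [(1, 1)])
        with pytest.raises(ValueError):
            Network(2, [(0, 5)])

    def test_degrees_and_adjacency_symmetry(self):
        net = random_graph(20, 0.3, seed=1)
        a = net.adjacency()
        assert (a != a.T).nnz == 0
        assert np.array_equal(net.degrees(), np.asarray(a.sum(axis=1)).ravel())


class TestEdgeList:
    @pytest.mark.parametrize(
        "text, n, edges",
        [
            ("a b\nb c", 3, {(0, 1), (1, 2)}),
            ("0 1\n1 0\n0 0", 2, {(0, 1)}),
            ("", 0, set()),
            ("# comment\nx y # trailing\n", 2, {(0, 1)}),
        ],
    )
    def test_parse(self, text, n, edges):
        net = read_edge_list(io.StringIO(text))
        assert net.n_nodes == n
        assert net.edge_set() == edges

    def test_malformed_line_names_line_number(self):
        with pytest.raises(GraphParseError, match="line 2"):
            read_edge_list(io.StringIO("a b\na b c"))

    def test_write_ordering(self):
        net = Network(3, [(1, 2), (0, 1)])
        buf = io.StringIO()
        write_edge_list(net, buf)
        assert buf.getvalue() == "0 1\n1 2\n"

    def test_write_empty(self):
        buf = io.StringIO()
        write_edge_list(Network(1, []), buf)
        assert buf.getvalue() == ""

    @given(st.integers(2, 12), st.floats(0.2, 0.9), st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_roundtrip_identity(self, n, p, seed):
        net = random_graph(n, p, seed)
        # drop isolated nodes: an edge list cannot represent them
        net = giant_component(net) if net.n_edges else net
        if net.n_edges == 0:
            return
        buf = io.StringIO()
        write_edge_list(net, buf)
        buf.seek(0)
        assert read_edge_list(buf) == net


class TestPajek:
    def test_basic(self):
        text = '*Vertices 2\n1 "x"\n2 "y"\n*Edges\n1 2'
        net = read_pajek(io.StringIO(text))
        assert net.n_nodes == 2
        assert net.edge_set() == {(0, 1)}
        assert net.node_labels == ("x", "y")

    def test_arcs_treated_as_edges_and_weights_ignored(self):
        text = "*Vertices 3\n*Arcs\n1 2 0.5\n2 3 2.0\n2 1 1.0"
        net = read_pajek(io.StringIO(text))
        assert net.edge_set() == {(0, 1), (1, 2)}

    def test_missing_sections_error(self):
        with pytest.raises(GraphParseError):
            read_pajek(io.StringIO("*Edges\n1 2"))
        with pytest.raises(GraphParseError):
            read_pajek(io.StringIO("*Vertices 2\n1 \"a\"\n2 \"b\""))

    def test_vertex_count_mismatch_errors(self):
        with pytest.raises(GraphParseError):
            read_pajek(io.StringIO('*Vertices 3\n1 "a"\n2 "b"\n*Edges\n1 2'))


class TestGiantComponent:
    def test_two_triangles_plus_isolate(self):
        net = Network(7, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        gc = giant_component(net)
        # tie between equal triangles: the one with the smallest index wins
        assert (gc.n_nodes, gc.n_edges) == (3, 3)
        assert gc.edge_set() == {(0, 1), (0, 2), (1, 2)}

    def test_connected_graph_is_identity(self, star4):
        assert giant_component(star4) == star4

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            giant_component(Network(0, []))


class TestTopologyStats:
    def test_complete_k4(self, k4):
        st_ = topology_stats(k4)
        assert st_.mean_degree == 3.0
        assert st_.mean_distance == 1.0
        assert st_.assortativity is None  # zero degree variance

    def test_path_p3(self, p3):
        st_ = topology_stats(p3)
        assert st_.mean_degree == pytest.approx(4 / 3)
        assert st_.mean_distance == pytest.approx(4 / 3)

    def test_star_matches_brute_force_pearson(self, star4):
        st_ = topology_stats(star4)
        assert st_.mean_degree == pytest.approx(1.6)
        assert st_.mean_distance == pytest.approx(1.6)
        # oracle: Pearson over the 8 directed edge end-degree pairs
        deg = star4.degrees()
        pairs = [(deg[u], deg[v]) for u, v in star4.edges] + [
            (deg[v], deg[u]) for u, v in star4.edges
        ]
        x, y = np.array(pairs).T
        r_oracle = np.corrcoef(x, y)[0, 1]
        assert st_.assortativity == pytest.approx(r_oracle) == pytest.approx(-1.0)

    def test_mean_degree_identity(self, ba_small):
        st_ = topology_stats(ba_small, exact_distances=False, n_sources=50, seed=0)
        assert st_.mean_degree == 2 * st_.E / st_.N

    def test_sampled_with_all_sources_equals_exact(self, ba_small):
        exact = mean_shortest_path_length(ba_small, exact=True)
        full_sample = mean_shortest_path_length(
            ba_small, exact=False, n_sources=ba_small.n_nodes, seed=1
        )
        assert full_sample == pytest.approx(exact)

    def test_assortativity_matches_networkx(self, ba_small):
        import networkx as nx

        r = degree_assortativity(ba_small)
        r_nx = nx.degree_assortativity_coefficient(ba_small.to_networkx())
        assert r == pytest.approx(r_nx, abs=1e-10)
        assert -1.0 <= r <= 1.0

    def test_assortativity_relabeling_invariant(self):
        net = random_graph(15, 0.3, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(net.n_nodes)
        relabeled = Network(net.n_nodes, perm[net.edges])
        assert degree_assortativity(relabeled) == pytest.approx(degree_assortativity(net))

    def test_edgeless_graph_undefined(self):
        st_ = topology_stats(Network(3, []))
        assert st_.mean_distance is None and st_.assortativity is None
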