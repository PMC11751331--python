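import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phimpact import (
    ParseError,
    graph_from_edges,
    induced_subgraph,
    normalize_symbol,
    read_driver_catalog,
    read_edge_list,
    read_gene_sets,
    read_mutation_table,
    shortest_path_matrix,
    write_edge_list,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestEdgeList:
    def test_basic_parse(self, tmp_path):
        p = write(tmp_path, "e.tsv", "A\tB\nB\tC\n")
        g = read_edge_list(p)
        assert set(g.nodes) == {"A", "B", "C"}
        assert g.number_of_edges() == 2

    def test_normalization_and_dedup(self, tmp_path):
        p = write(tmp_path, "e.tsv", "A B\nB A\na b\n")
        g = read_edge_list(p)
        assert set(g.nodes) == {"A", "B"}
        assert g.number_of_edges() == 1

    def test_self_loop_dropped_node_kept(self, tmp_path, caplog):
        p = write(tmp_path, "e.tsv", "A\tA\n")
        with caplog.at_level("WARNING", logger="phimpact"):
            g = read_edge_list(p)
        assert set(g.nodes) == {"A"} and g.number_of_edges() == 0
        assert "self-loop" in caplog.text

    def test_malformed_line_names_lineno(self, tmp_path):
        p = write(tmp_path, "e.tsv", "A\tB\nJUSTONE\n")
        with pytest.raises(ParseError, match=":2:"):
            read_edge_list(p)

    def test_empty_file_errors(self, tmp_path):
        p = write(tmp_path, "e.tsv", "# only a comment\n")
        with pytest.raises(ParseError):
            read_edge_list(p)

    def test_round_trip_preserves_graph(self, tmp_path):
        g = graph_from_edges(
            [("A", "B"), ("B", "C", 2.5)], nodes=["LONER"]
        )
        p = tmp_path / "rt.tsv"
        write_edge_list(g, p)
        h = read_edge_list(p)
        assert set(g.nodes) == set(h.nodes)
        assert set(map(frozenset, g.edges)) == set(map(frozenset, h.edges))
        assert h["B"]["C"]["weight"] == 2.5


class TestGeneSets:
    def test_gmt_line(self, tmp_path):
        p = write(tmp_path, "s.gmt", "PCD\tdesc\tTP53\tCASP3\n")
        (gs,) = read_gene_sets(p)
        assert gs.name == "PCD" and gs.genes == {"TP53", "CASP3"}

    def test_duplicate_gene_stored_once(self, tmp_path):
        p = write(tmp_path, "s.gmt", "S\td\tTP53\ttp53\n")
        (gs,) = read_gene_sets(p)
        assert gs.genes == {"TP53"}

    def test_two_lines_in_order(self, tmp_path):
        p = write(tmp_path, "s.gmt", "S1\td\tA\nS2\td\tB\n")
        sets = read_gene_sets(p)
        assert [s.name for s in sets] == ["S1", "S2"]

    def test_short_line_errors(self, tmp_path):
        p = write(tmp_path, "s.gmt", "ONLY\tTWO\n")
        with pytest.raises(ParseError):
            read_gene_sets(p)


MAF_HEADER = "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"


class TestMutationTable:
    def test_set_semantics(self, tmp_path):
        p = write(
            tmp_path, "m.tsv",
            MAF_HEADER
            + "TP53\tS1\tMissense_Mutation\n"
            + "TP53\tS1\tNonsense_Mutation\n"
            + "KRAS\tS2\tMissense_Mutation\n",
        )
        t = read_mutation_table(p, "X")
        assert t.records == {("S1", "TP53"), ("S2", "KRAS")}

    def test_nonsilent_filter(self, tmp_path):
        p = write(
            tmp_path, "m.tsv",
            MAF_HEADER + "TP53\tS1\tSilent\nKRAS\tS2\tMissense_Mutation\n",
        )
        t = read_mutation_table(p, "X", nonsilent_only=True)
        assert "TP53" not in t.genes and "KRAS" in t.genes

    def test_missing_column_errors(self, tmp_path):
        p = write(tmp_path, "m.tsv", "Hugo_Symbol\nTP53\n")
        with pytest.raises(ParseError, match="Tumor_Sample_Barcode"):
            read_mutation_table(p, "X")

    def test_empty_table_warns(self, tmp_path, caplog):
        p = write(tmp_path, "m.tsv", MAF_HEADER)
        with caplog.at_level("WARNING", logger="phimpact"):
            t = read_mutation_table(p, "X")
        assert t.records == frozenset()
        assert "no usable rows" in caplog.text


class TestDriverCatalog:
    def test_union_with_provenance(self, tmp_path):
        a = write(tmp_path, "ncg.txt", "TP53\nATM\n")
        b = write(tmp_path, "intogen.txt", "tp53\nSTAT3\n# comment\n")
        cat = read_driver_catalog([a, b])
        assert cat.genes == {"TP53", "ATM", "STAT3"}
        assert cat.sources["TP53"] == {"ncg", "intogen"}
        assert cat.sources["ATM"] == {"ncg"}

    def test_single_file_identity(self, tmp_path):
        a = write(tmp_path, "d.txt", "BRCA1\n")
        assert read_driver_catalog([a]).genes == {"BRCA1"}

    def test_all_empty_errors(self, tmp_path):
        a = write(tmp_path, "d.txt", "# nothing\n")
        with pytest.raises(ParseError):
            read_driver_catalog([a])


class TestInducedSubgraph:
    def test_triangle_restriction(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        h = induced_subgraph(g, {"A", "B"})
        assert set(h.nodes) == {"A", "B"} and h.number_of_edges() == 1

    def test_superset_identity(self):
        g = graph_from_edges([("A", "B")])
        h = induced_subgraph(g, {"A", "B", "X"})
        assert nx.utils.graphs_equal(g, h)

    def test_disjoint_warns_empty(self, caplog):
        g = graph_from_edges([("A", "B")])
        with caplog.at_level("WARNING", logger="phimpact"):
            h = induced_subgraph(g, {"X"})
        assert h.number_of_nodes() == 0
        assert "empty intersection" in caplog.text

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        g = nx.relabel_nodes(
            nx.gnp_random_graph(8, 0.4, seed=seed),
            {n: f"N{n}" for n in range(8)},
        )
        genes = {f"N{n}" for n in range(0, 8, 2)}
        once = induced_subgraph(g, genes)
        twice = induced_subgraph(once, genes)
        assert nx.utils.graphs_equal(once, twice)


class TestShortestPathMatrix:
    def test_path_graph_hops(self):
        g = graph_from_edges([("A", "B"), ("B", "C")])
        D = shortest_path_matrix(g)
        assert D.d("A", "C") == 2

    def test_components_are_infinitely_far(self):
        g = graph_from_edges([("A", "B"), ("C", "D")])
        D = shortest_path_matrix(g)
        assert math.isinf(D.d("A", "C"))

    def test_dodecahedron_diameter_matches_bfs(self, dodecahedron):
        D = shortest_path_matrix(dodecahedron)
        # independent oracle: networkx BFS eccentricities
        assert D.diameter == max(nx.eccentricity(dodecahedron).values()) == 5

    def test_weighted_dijkstra(self):
        g = graph_from_edges([("A", "B", 0.5), ("B", "C", 0.5), ("A", "C", 2.0)])
        D = shortest_path_matrix(g, weighted=True)
        assert D.d("A", "C") == 1.0

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            shortest_path_matrix(nx.Graph())

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_zero_diagonal(self, seed):
        g = nx.gnp_random_graph(9, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {n: f"N{n}" for n in g.nodes})
        D = shortest_path_matrix(g)
        assert np.allclose(np.diag(D.values), 0)
        fin = np.isfinite(D.values)
        assert np.array_equal(fin, fin.T)
        assert np.allclose(D.values[fin], D.values.T[fin])


def test_normalize_symbol_rejects_empty():
    with pytest.raises(ValueError):
        normalize_symbol("   ")
    assert normalize_symbol(" tp53 ") == "TP53"


def test_distance_matrix_csv_round_trip(tmp_path, octahedron_dm):
    p = tmp_path / "d.csv"
    octahedron_dm.to_csv(p)
    back = type(octahedron_dm).from_csv(p)
    assert back.nodes == octahedron_dm.nodes
    assert np.array_equal(back.values, octahedron_dm.values)
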