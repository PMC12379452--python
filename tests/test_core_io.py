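import numpy as np
import networkx as nx
import pytest

from calcinet import (
    AlignmentError,
    FunctionalGraph,
    TracesFormatError,
    align_cells,
    read_cells,
    read_graph,
    read_traces,
    write_graph,
    write_traces,
    TraceMatrix,
    CellTable,
)


def test_read_traces_with_id_column(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("a,1,2,3,4,5\nb,2,3,4,5,6\nc,0,0,1,0,0\n")
    t = read_traces(p, frame_interval_s=2.0)
    assert (t.n_cells, t.n_time) == (3, 5)
    assert t.cell_ids == ["a", "b", "c"]
    np.testing.assert_allclose(t.values[0], [1, 2, 3, 4, 5])


def test_read_traces_headerless_numeric_synthesizes_ids(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("1.5,2.5,3.5\n4.0,5.0,6.0\n")
    t = read_traces(p, 1.0)
    assert t.cell_ids == ["0", "1"]
    assert t.n_time == 3


def test_read_traces_header_and_ids(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("Cell,t0,t1,t2\nroi1,0.1,0.2,0.3\nroi2,1,1,1\n")
    t = read_traces(p, 1.0)
    assert t.cell_ids == ["roi1", "roi2"]
    np.testing.assert_allclose(t.values[1], [1, 1, 1])


def test_read_traces_missing_value_names_cell(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("a,1,2,3\nb,4,,6\n")
    with pytest.raises(TracesFormatError, match="'b'"):
        read_traces(p, 1.0)


def test_read_traces_single_row_450_frames(tmp_path):
    # the scale of one 15-min 0.5 Hz recording row
    p = tmp_path / "t.csv"
    vals = np.arange(450, dtype=float)
    p.write_text("only," + ",".join(map(str, vals)) + "\n")
    t = read_traces(p, 2.0)
    assert (t.n_cells, t.n_time) == (1, 450)
    assert t.duration_s == 900.0


def test_read_traces_transpose(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("1,10\n2,20\n3,30\n")  # time in rows
    t = read_traces(p, 1.0, transpose=True)
    assert (t.n_cells, t.n_time) == (2, 3)
    np.testing.assert_allclose(t.values[0], [1, 2, 3])


def test_read_traces_too_short_rejected(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("a,1\nb,2\n")
    with pytest.raises(TracesFormatError, match="2 time points"):
        read_traces(p, 1.0)


def test_traces_roundtrip(tmp_path, toy_traces):
    p = tmp_path / "t.csv"
    write_traces(toy_traces, p)
    back = read_traces(p, toy_traces.frame_interval_s)
    assert back.cell_ids == toy_traces.cell_ids
    np.testing.assert_allclose(back.values, toy_traces.values, atol=1e-9)


def test_read_cells_optional_label(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("X,Y,Cell\n1,2,a\n3,4,b\n")
    c = read_cells(p)
    assert c.labels is None
    assert c.cell_ids == ["a", "b"]


def test_read_cells_label_and_case_insensitive(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("x,y,cell,label\n1,2,a,RFP\n3,4,b,\n5,6,c,RFP\n")
    c = read_cells(p)
    assert c.labels == ["RFP", None, "RFP"]
    assert c.label_values() == ["RFP"]
    assert list(c.labeled_mask("RFP")) == [True, False, True]


def test_read_cells_duplicate_ids_rejected(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("X,Y,Cell\n1,2,a\n3,4,a\n")
    with pytest.raises(TracesFormatError, match="duplicate"):
        read_cells(p)


def test_read_cells_missing_column(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("X,Cell\n1,a\n")
    with pytest.raises(TracesFormatError, match="y"):
        read_cells(p)


def test_align_mismatch_lists_symmetric_difference(toy_traces):
    cells = CellTable(
        x=np.zeros(6), y=np.zeros(6),
        cell_ids=[f"c{i}" for i in range(5)] + ["zz"],
    )
    with pytest.raises(AlignmentError) as err:
        align_cells(toy_traces, cells)
    assert "c5" in str(err.value) and "zz" in str(err.value)


def test_align_is_order_independent(toy_traces):
    rng = np.random.default_rng(0)
    perm = rng.permutation(6)
    ids = [f"c{i}" for i in range(6)]
    cells = CellTable(
        x=np.arange(6, dtype=float)[perm],
        y=np.arange(6, dtype=float)[perm] * 2,
        cell_ids=[ids[i] for i in perm],
        labels=[("L" if i % 2 else None) for i in perm],
    )
    aligned = align_cells(toy_traces, cells)
    assert aligned.cell_ids == ids
    np.testing.assert_allclose(aligned.x, np.arange(6.0))
    assert aligned.labels == [None, "L", None, "L", None, "L"]


def _triangle_graph():
    g = nx.Graph()
    for i, (x, y) in enumerate([(0, 0), (1, 0), (0, 1)]):
        g.add_node(f"n{i}", x=float(x), y=float(y), label="RFP")
    g.add_edge("n0", "n1", weight=0.75)
    g.add_edge("n1", "n2", weight=0.5)
    g.add_edge("n0", "n2", weight=0.6123456789)
    return FunctionalGraph(graph=g, theta=0.3)


@pytest.mark.parametrize("fmt", ["graphml", "edge_csv"])
def test_write_graph_formats(tmp_path, fmt):
    g = _triangle_graph()
    p = tmp_path / f"g.{fmt}"
    write_graph(g, p, format=fmt)
    assert p.stat().st_size > 0


def test_graphml_roundtrip_nodes_edges_weights_attrs(tmp_path):
    g = _triangle_graph()
    g.graph.nodes["n0"]["community"] = 0
    g.graph.nodes["n1"]["community"] = 0
    g.graph.nodes["n2"]["community"] = 1
    p = tmp_path / "g.graphml"
    write_graph(g, p)
    back = read_graph(p, theta=0.3)
    assert set(back.graph.nodes) == set(g.graph.nodes)
    assert set(map(frozenset, back.graph.edges)) == set(
        map(frozenset, g.graph.edges)
    )
    for u, v, d in g.graph.edges(data=True):
        assert abs(back.graph[u][v]["weight"] - d["weight"]) < 1e-9
    assert back.graph.nodes["n2"]["community"] == 1
    assert back.graph.nodes["n1"]["label"] == "RFP"
    assert back.graph.nodes["n1"]["x"] == 1.0


def test_graphml_roundtrip_edgeless(tmp_path):
    g = nx.Graph()
    g.add_node("a", x=0.0, y=0.0)
    g.add_node("b", x=1.0, y=1.0)
    p = tmp_path / "g.graphml"
    write_graph(FunctionalGraph(g, None), p)
    back = read_graph(p)
    assert set(back.graph.nodes) == {"a", "b"}
    assert back.n_edges == 0


def test_write_graph_unknown_format(tmp_path):
    with pytest.raises(ValueError, match="format"):
        write_graph(_triangle_graph(), tmp_path / "g.x", format="dot")


def test_trace_matrix_validation():
    with pytest.raises(TracesFormatError, match="duplicate"):
        TraceMatrix(np.zeros((2, 3)), ["a", "a"], 1.0)
    with pytest.raises(TracesFormatError, match="non-finite"):
        TraceMatrix(np.array([[1.0, np.nan]]), ["a"], 1.0)
    with pytest.raises(TracesFormatError, match="positive"):
        TraceMatrix(np.zeros((1, 3)), ["a"], 0.0)
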