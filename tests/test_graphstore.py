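"""Property graph: mutation, indexes, traversal, serialization."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from pathkb.graphstore import (
    GraphEdge,
    GraphError,
    GraphFormatError,
    GraphNode,
    PropertyGraph,
    export_graph,
    import_graph,
)


def small_graph():
    g = PropertyGraph()
    g.add_node(GraphNode(1, ("Reaction", "ReactionLikeEvent", "Event", "DatabaseObject"),
                         {"stId": "R-1", "displayName": "rxn"}))
    g.add_node(GraphNode(2, ("SimpleEntity", "PhysicalEntity", "DatabaseObject"), {"stId": "R-2"}))
    g.add_node(GraphNode(3, ("Complex", "PhysicalEntity", "DatabaseObject"), {"stId": "R-3"}))
    g.add_edge(GraphEdge(1, 2, "input", {"order": 0}))
    g.add_edge(GraphEdge(1, 3, "input", {"order": 1}))
    g.add_edge(GraphEdge(1, 3, "output", {"order": 0}))
    return g


def random_graph(seed: int, n_nodes: int = 40, n_edges: int = 120) -> PropertyGraph:
    rng = random.Random(seed)
    g = PropertyGraph()
    for i in range(1, n_nodes + 1):
        g.add_node(GraphNode(i, ("SimpleEntity", "PhysicalEntity", "DatabaseObject"), {"stId": f"R-{i}"}))
    orders: dict[tuple[int, str], int] = {}
    for _ in range(n_edges):
        src, tgt = rng.randint(1, n_nodes), rng.randint(1, n_nodes)
        etype = rng.choice(["input", "output", "hasComponent"])
        order = orders.get((src, etype), 0)
        orders[(src, etype)] = order + 1
        g.add_edge(GraphEdge(src, tgt, etype, {"order": order}))
    return g


class TestMutation:
    def test_add_then_lookup_round_trip(self):
        g = small_graph()
        node = g.find("dbId", 1)[0]
        assert node.node_id == 1 and node.properties["stId"] == "R-1"

    def test_duplicate_node_rejected(self):
        g = small_graph()
        with pytest.raises(GraphError, match="duplicate"):
            g.add_node(GraphNode(1, ("X",)))

    def test_dangling_endpoint_rejected(self):
        g = small_graph()
        with pytest.raises(GraphError, match="dangling"):
            g.add_edge(GraphEdge(1, 99, "input", {"order": 2}))

    def test_node_count_after_n_adds(self):
        g = PropertyGraph()
        for i in range(25):
            g.add_node(GraphNode(i + 1, ("DatabaseObject",)))
        assert g.n_nodes == 25

    def test_remove_node_cleans_edges_and_indexes(self):
        g = small_graph()
        g.remove_node(3)
        assert g.n_edges == 1 and g.find("stId", "R-3") == []
        assert g.check_invariants() == []

    def test_empty_labels_rejected(self):
        with pytest.raises(GraphError):
            GraphNode(1, ())


class TestFind:
    def test_find_by_st_id(self):
        g = small_graph()
        assert [n.node_id for n in g.find("stId", "R-2")] == [2]

    def test_absent_key_empty_result(self):
        g = small_graph()
        assert g.find("stId", "nope") == [] and g.find("dbId", 42) == []

    def test_label_lookup_is_polymorphic(self):
        # an ancestor label matches every subtype node
        g = small_graph()
        assert [n.node_id for n in g.find("label", "PhysicalEntity")] == [2, 3]
        assert [n.node_id for n in g.find("label", "Event")] == [1]

    def test_event_label_count_on_synthetic_graph(self, seeded_kbs):
        _config, store, _truth, graph, _report = seeded_kbs[0]
        by_class = lambda c: sum(  # noqa: E731
            1 for i in store.instances.values() if store.schema.is_a(i.class_name, c)
        )
        assert len(graph.find("label", "Event")) == by_class("Pathway") + by_class("ReactionLikeEvent")


class TestNeighbors:
    def test_ordered_slot_order(self):
        g = small_graph()
        assert [n.node_id for _e, n in g.neighbors(1, ("input",), "out")] == [2, 3]

    def test_in_direction_returns_consumers(self):
        g = small_graph()
        assert [n.node_id for _e, n in g.neighbors(3, ("input",), "in")] == [1]

    def test_unknown_node_errors(self):
        with pytest.raises(GraphError):
            small_graph().neighbors(99)

    def test_every_edge_once_in_out_and_in(self):
        g = random_graph(seed=5)
        out_keys = [e.key() for n in g.nodes() for e, _ in g.neighbors(n.node_id, None, "out")]
        in_keys = [e.key() for n in g.nodes() for e, _ in g.neighbors(n.node_id, None, "in")]
        expected = sorted(e.key() for e in g.edges())
        assert sorted(out_keys) == expected and sorted(in_keys) == expected


class TestTraverse:
    def test_leaf_node_reaches_nothing(self):
        g = small_graph()
        assert g.traverse([2], ("input",), "out") == {}

    def test_two_node_cycle_terminates_and_includes_start(self):
        g = PropertyGraph()
        g.add_node(GraphNode(1, ("Pathway", "Event", "DatabaseObject")))
        g.add_node(GraphNode(2, ("Pathway", "Event", "DatabaseObject")))
        g.add_edge(GraphEdge(1, 2, "hasEvent", {"order": 0}))
        g.add_edge(GraphEdge(2, 1, "hasEvent", {"order": 0}))
        assert set(g.traverse([1], ("hasEvent",), "out")) == {1, 2}

    def test_depth_is_minimum(self):
        g = small_graph()
        depths = g.traverse([1], ("input", "output"), "out")
        assert depths == {2: 1, 3: 1}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_fixed_point(self, seed):
        g = random_graph(seed=seed, n_nodes=60, n_edges=200)
        start = [1]
        # naive oracle: repeated one-step expansion until stable
        reached: set[int] = set()
        frontier = {n.node_id for _e, n in g.neighbors(1, ("input",), "out")}
        while frontier - reached:
            reached |= frontier
            frontier = {
                n.node_id for f in frontier for _e, n in g.neighbors(f, ("input",), "out")
            }
        assert set(g.traverse(start, ("input",), "out")) == reached

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_networkx_reachability(self, seed):
        g = random_graph(seed=seed)
        nxg = nx.MultiDiGraph()
        nxg.add_nodes_from(n.node_id for n in g.nodes())
        nxg.add_edges_from((e.source, e.target) for e in g.edges())
        for start in (1, 2, 3):
            expected = set(nx.descendants(nxg, start))
            if any(nxg.has_edge(m, start) for m in expected | {start}):
                expected.add(start)
            assert set(g.traverse([start], None, "out")) == expected

    def test_result_independent_of_start_order(self):
        g = random_graph(seed=9)
        a = g.traverse([1, 2, 3], None, "out")
        b = g.traverse([3, 1, 2], None, "out")
        assert a == b


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.sampled_from(["node", "edge", "del_edge", "del_node"]),
                          st.integers(0, 19), st.integers(0, 19)), max_size=40))
def test_index_consistency_under_random_operations(ops):
    """Any add/remove sequence leaves internal indexes consistent."""
    g = PropertyGraph()
    for kind, a, b in ops:
        try:
            if kind == "node":
                g.add_node(GraphNode(a, ("SimpleEntity", "PhysicalEntity"), {"stId": f"R-{a}"}))
            elif kind == "edge":
                order = len([e for e in g.edges() if e.source == a and e.type == "input"])
                g.add_edge(GraphEdge(a, b, "input", {"order": order}))
            elif kind == "del_edge" and g.edges():
                g.remove_edge(g.edges()[a % len(g.edges())])
            elif kind == "del_node" and g.nodes():
                g.remove_node(g.nodes()[a % g.n_nodes].node_id)
        except GraphError:
            pass
        problems = [p for p in g.check_invariants() if "non-contiguous" not in p]
        assert problems == []


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["json", "graphml"])
    def test_round_trip(self, fmt, tmp_path, seeded_kbs):
        _c, _s, _t, graph, _r = seeded_kbs[1]
        path = tmp_path / f"g.{fmt}"
        export_graph(graph, fmt, path)
        assert import_graph(path, fmt) == graph

    def test_graphml_preserves_edge_order_properties(self, tmp_path):
        g = random_graph(seed=3)
        path = tmp_path / "g.graphml"
        export_graph(g, "graphml", path)
        back = import_graph(path, "graphml")
        assert [(e.key(), tuple(sorted(e.properties.items()))) for e in back.edges()] == [
            (e.key(), tuple(sorted(e.properties.items()))) for e in g.edges()
        ]

    @pytest.mark.parametrize("fmt", ["json", "graphml"])
    def test_empty_graph_round_trip(self, fmt, tmp_path):
        path = tmp_path / f"empty.{fmt}"
        export_graph(PropertyGraph(), fmt, path)
        assert import_graph(path, fmt).n_nodes == 0

    def test_cypher_statement_counts_match(self, tmp_path):
        g = small_graph()
        path = tmp_path / "g.cypher"
        export_graph(g, "cypher_script", path)
        lines = path.read_text(encoding="utf-8").splitlines()
        assert sum(1 for l in lines if l.startswith("CREATE (:")) == g.n_nodes
        assert sum(1 for l in lines if l.startswith("MATCH (")) == g.n_edges
        assert lines[0].startswith("CREATE CONSTRAINT")

    def test_cypher_escapes_quotes(self, tmp_path):
        g = PropertyGraph()
        g.add_node(GraphNode(1, ("SimpleEntity",), {"displayName": "D-glucose 6'-phosphate \\ 'salt'"}))
        path = tmp_path / "g.cypher"
        export_graph(g, "cypher_script", path)
        assert "\\'salt\\'" in path.read_text(encoding="utf-8")

    def test_malformed_json_reports_location(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"nodes": [')
        with pytest.raises(GraphFormatError, match="line"):
            import_graph(path, "json")

    def test_malformed_graphml_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.graphml"
        path.write_text("<graphml><node ></graphml>")
        with pytest.raises(GraphFormatError):
            import_graph(path, "graphml")
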