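"""Embedded labelled property graph with typed, ordered, directed edges.

This is the storage layer the rest of the toolkit queries: nodes carry a
label chain (concrete class first, then its ancestors, so label lookup is
polymorphic the way multi-label graph databases resolve supertypes) and a
flat map of primitive properties; edges are typed by slot name and carry
an ``order`` index so ordered multi-valued slots survive migration.

Indexes by node id, by the ``stId`` property and by label are maintained
under every mutation.  Import/export covers GraphML (via lxml), a JSON
document and a write-only Cypher script.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

from lxml import etree

__all__ = [
    "GraphNode",
    "GraphEdge",
    "PropertyGraph",
    "GraphError",
    "GraphFormatError",
    "export_graph",
    "import_graph",
]

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


class GraphError(ValueError):
    """Structural violation: duplicate node, dangling endpoint, unknown node."""


class GraphFormatError(ValueError):
    """Malformed serialized graph document."""


@dataclass(frozen=True)
class GraphNode:
    node_id: int
    labels: tuple[str, ...]
    properties: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if not self.labels:
            raise GraphError(f"node {self.node_id}: labels must be non-empty")

    @property
    def concrete_class(self) -> str:
        return self.labels[0]


@dataclass(frozen=True)
class GraphEdge:
    source: int
    target: int
    type: str
    properties: dict[str, Any] = field(default_factory=dict)

    @property
    def order(self) -> int:
        return int(self.properties.get("order", 0))

    def key(self) -> tuple[int, str, int, int]:
        return (self.source, self.type, self.target, self.order)


class PropertyGraph:
    """Labelled property graph over plain dict indexes."""

    def __init__(self) -> None:
        self._nodes: dict[int, GraphNode] = {}
        self._out: dict[int, list[GraphEdge]] = {}
        self._in: dict[int, list[GraphEdge]] = {}
        self._by_st_id: dict[str, set[int]] = {}
        self._by_label: dict[str, set[int]] = {}
        self._edge_keys: set[tuple[int, str, int, int]] = set()

    # -- size ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edge_keys)

    def nodes(self) -> list[GraphNode]:
        return [self._nodes[i] for i in sorted(self._nodes)]

    def edges(self) -> list[GraphEdge]:
        out: list[GraphEdge] = []
        for nid in sorted(self._out):
            out.extend(self._out[nid])
        return sorted(out, key=GraphEdge.key)

    # -- mutation -------------------------------------------------------

    def add_node(self, node: GraphNode) -> int:
        if node.node_id in self._nodes:
            raise GraphError(f"duplicate node_id {node.node_id}")
        self._nodes[node.node_id] = node
        self._out[node.node_id] = []
        self._in[node.node_id] = []
        st_id = node.properties.get("stId")
        if isinstance(st_id, str):
            self._by_st_id.setdefault(st_id, set()).add(node.node_id)
        for label in node.labels:
            self._by_label.setdefault(label, set()).add(node.node_id)
        return node.node_id

    def add_edge(self, edge: GraphEdge) -> None:
        if edge.source not in self._nodes:
            raise GraphError(f"dangling edge source {edge.source}")
        if edge.target not in self._nodes:
            raise GraphError(f"dangling edge target {edge.target}")
        if edge.key() in self._edge_keys:
            raise GraphError(f"duplicate edge {edge.key()}")
        self._out[edge.source].append(edge)
        self._in[edge.target].append(edge)
        self._edge_keys.add(edge.key())

    def remove_edge(self, edge: GraphEdge) -> None:
        if edge.key() not in self._edge_keys:
            raise GraphError(f"no such edge {edge.key()}")
        self._out[edge.source] = [e for e in self._out[edge.source] if e.key() != edge.key()]
        self._in[edge.target] = [e for e in self._in[edge.target] if e.key() != edge.key()]
        self._edge_keys.discard(edge.key())

    def remove_node(self, node_id: int) -> None:
        node = self.node(node_id)
        for edge in list(self._out[node_id]) + list(self._in[node_id]):
            if edge.key() in self._edge_keys:
                self.remove_edge(edge)
        del self._nodes[node_id]
        del self._out[node_id]
        del self._in[node_id]
        st_id = node.properties.get("stId")
        if isinstance(st_id, str):
            self._by_st_id[st_id].discard(node_id)
            if not self._by_st_id[st_id]:
                del self._by_st_id[st_id]
        for label in node.labels:
            self._by_label[label].discard(node_id)
            if not self._by_label[label]:
                del self._by_label[label]

    def copy(self) -> "PropertyGraph":
        g = PropertyGraph()
        for node in self.nodes():
            g.add_node(GraphNode(node.node_id, node.labels, dict(node.properties)))
        for edge in self.edges():
            g.add_edge(GraphEdge(edge.source, edge.target, edge.type, dict(edge.properties)))
        return g

    # -- lookup ---------------------------------------------------------

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._nodes

    def node(self, node_id: int) -> GraphNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise GraphError(f"unknown node {node_id}") from None

    def find(self, by: str, key: Any) -> list[GraphNode]:
        """Look up nodes by ``dbId`` (node id), ``stId`` property or label.

        Identifier lookups return zero or one node; label lookup returns
        every node carrying the label, ancestor labels included.
        """
        if by == "dbId":
            node = self._nodes.get(key)
            return [node] if node is not None else []
        if by == "stId":
            ids = self._by_st_id.get(key, set())
            return [self._nodes[min(ids)]] if ids else []
        if by == "label":
            return [self._nodes[i] for i in sorted(self._by_label.get(key, set()))]
        raise ValueError(f"unknown lookup kind {by!r}")

    def resolve(self, identifier: int | str) -> GraphNode | None:
        """Accept either a dbId integer or an stId string."""
        if isinstance(identifier, int):
            hits = self.find("dbId", identifier)
        else:
            hits = self.find("stId", identifier)
        return hits[0] if hits else None

    def neighbors(
        self,
        node_id: int,
        edge_types: Iterable[str] | None = None,
        direction: str = "out",
    ) -> list[tuple[GraphEdge, GraphNode]]:
        """Adjacent (edge, node) pairs, sorted by (type, order, endpoint)."""
        self.node(node_id)
        if direction == "out":
            edges, end = self._out[node_id], lambda e: e.target
        elif direction == "in":
            edges, end = self._in[node_id], lambda e: e.source
        else:
            raise ValueError(f"direction must be out or in, got {direction!r}")
        wanted = None if edge_types is None else set(edge_types)
        picked = [e for e in edges if wanted is None or e.type in wanted]
        picked.sort(key=lambda e: (e.type, e.order, end(e)))
        return [(e, self._nodes[end(e)]) for e in picked]

    def traverse(
        self,
        start_ids: Iterable[int],
        edge_types: Iterable[str] | None = None,
        direction: str = "out",
        max_depth: int | None = None,
    ) -> dict[int, int]:
        """Breadth-first transitive closure restricted to ``edge_types``.

        Returns ``{node_id: min_depth}`` over nodes reached by a path of
        one or more edges; a start node appears only if a cycle leads
        back to it.  Terminates on cyclic graphs.
        """
        starts = sorted(set(start_ids))
        for s in starts:
            self.node(s)
        depth: dict[int, int] = {}
        expanded: set[int] = set()
        queue: deque[tuple[int, int]] = deque((s, 0) for s in starts)
        while queue:
            nid, d = queue.popleft()
            if nid in expanded:
                continue
            expanded.add(nid)
            if max_depth is not None and d >= max_depth:
                continue
            for _edge, nbr in self.neighbors(nid, edge_types, direction):
                if nbr.node_id not in depth:
                    depth[nbr.node_id] = d + 1
                    if nbr.node_id not in expanded:
                        queue.append((nbr.node_id, d + 1))
        return depth

    # -- comparison -----------------------------------------------------

    def canonical(self) -> tuple:
        nodes = tuple(
            (n.node_id, n.labels, tuple(sorted(n.properties.items()))) for n in self.nodes()
        )
        edges = tuple(
            (e.source, e.type, e.target, tuple(sorted(e.properties.items()))) for e in self.edges()
        )
        return (nodes, edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PropertyGraph):
            return NotImplemented
        return self.canonical() == other.canonical()

    def check_invariants(self) -> list[str]:
        """Internal consistency: index agreement and order contiguity."""
        problems: list[str] = []
        for st_id, ids in self._by_st_id.items():
            for nid in ids:
                if self._nodes.get(nid, GraphNode(nid, ("?",))).properties.get("stId") != st_id:
                    problems.append(f"stId index stale for {st_id!r}")
        for label, ids in self._by_label.items():
            for nid in ids:
                if nid not in self._nodes or label not in self._nodes[nid].labels:
                    problems.append(f"label index stale for {label!r}")
        for node in self._nodes.values():
            st_id = node.properties.get("stId")
            if isinstance(st_id, str) and node.node_id not in self._by_st_id.get(st_id, set()):
                problems.append(f"node {node.node_id} missing from stId index")
            for label in node.labels:
                if node.node_id not in self._by_label.get(label, set()):
                    problems.append(f"node {node.node_id} missing from label index")
        by_slot: dict[tuple[int, str], list[int]] = {}
        for edge in self.edges():
            if edge.source not in self._nodes or edge.target not in self._nodes:
                problems.append(f"dangling edge {edge.key()}")
            by_slot.setdefault((edge.source, edge.type), []).append(edge.order)
        for (src, typ), orders in by_slot.items():
            if sorted(orders) != list(range(len(orders))):
                problems.append(f"non-contiguous order for ({src}, {typ}): {sorted(orders)}")
        return problems


# ---------------------------------------------------------------------------
# Serialization


def _to_document(graph: PropertyGraph) -> dict:
    return {
        "nodes": [
            {"id": n.node_id, "labels": list(n.labels), "properties": dict(sorted(n.properties.items()))}
            for n in graph.nodes()
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "type": e.type,
                "properties": dict(sorted(e.properties.items())),
            }
            for e in graph.edges()
        ],
    }


def _from_document(doc: dict) -> PropertyGraph:
    graph = PropertyGraph()
    try:
        for n in doc["nodes"]:
            graph.add_node(GraphNode(int(n["id"]), tuple(n["labels"]), dict(n.get("properties", {}))))
        for e in doc["edges"]:
            graph.add_edge(
                GraphEdge(int(e["source"]), int(e["target"]), str(e["type"]), dict(e.get("properties", {})))
            )
    except (KeyError, TypeError) as exc:
        raise GraphFormatError(f"malformed graph document: {exc!r}") from exc
    return graph


_GML_TYPES = {bool: "boolean", int: "long", float: "double", str: "string"}


def _gml_key_type(values: list) -> str:
    kinds = {type(v) for v in values}
    if kinds <= {bool}:
        return "boolean"
    if kinds <= {int}:
        return "long"
    if kinds <= {int, float}:
        return "double"
    return "string"


def _gml_parse(value: str, kind: str) -> Any:
    if kind == "boolean":
        return value == "true"
    if kind == "long":
        return int(value)
    if kind == "double":
        return float(value)
    return value


def _to_graphml(graph: PropertyGraph) -> bytes:
    node_props: dict[str, list] = {}
    edge_props: dict[str, list] = {}
    for n in graph.nodes():
        for k, v in n.properties.items():
            node_props.setdefault(k, []).append(v)
    for e in graph.edges():
        for k, v in e.properties.items():
            edge_props.setdefault(k, []).append(v)

    root = etree.Element(f"{{{GRAPHML_NS}}}graphml", nsmap={None: GRAPHML_NS})

    def declare(key_id: str, domain: str, name: str, kind: str) -> None:
        etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id=key_id, attrib={
            "for": domain, "attr.name": name, "attr.type": kind,
        })

    declare("labels", "node", "labels", "string")
    node_kinds = {k: _gml_key_type(vs) for k, vs in sorted(node_props.items())}
    edge_kinds = {k: _gml_key_type(vs) for k, vs in sorted(edge_props.items())}
    for k, kind in node_kinds.items():
        declare(f"n_{k}", "node", k, kind)
    declare("type", "edge", "type", "string")
    for k, kind in edge_kinds.items():
        declare(f"e_{k}", "edge", k, kind)

    g = etree.SubElement(root, f"{{{GRAPHML_NS}}}graph", id="G", edgedefault="directed")

    def data(parent, key_id: str, value: Any) -> None:
        el = etree.SubElement(parent, f"{{{GRAPHML_NS}}}data", key=key_id)
        el.text = ("true" if value else "false") if isinstance(value, bool) else str(value)

    for n in graph.nodes():
        el = etree.SubElement(g, f"{{{GRAPHML_NS}}}node", id=str(n.node_id))
        data(el, "labels", "|".join(n.labels))
        for k in sorted(n.properties):
            data(el, f"n_{k}", n.properties[k])
    for e in graph.edges():
        el = etree.SubElement(g, f"{{{GRAPHML_NS}}}edge", source=str(e.source), target=str(e.target))
        data(el, "type", e.type)
        for k in sorted(e.properties):
            data(el, f"e_{k}", e.properties[k])
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _from_graphml(payload: bytes) -> PropertyGraph:
    try:
        root = etree.fromstring(payload)
    except etree.XMLSyntaxError as exc:
        raise GraphFormatError(f"GraphML parse error: {exc}") from exc
    ns = {"g": GRAPHML_NS}
    keys: dict[str, tuple[str, str]] = {}  # key id -> (attr.name, attr.type)
    for key_el in root.findall("g:key", ns):
        keys[key_el.get("id")] = (key_el.get("attr.name"), key_el.get("attr.type"))
    graph = PropertyGraph()
    g = root.find("g:graph", ns)
    if g is None:
        raise GraphFormatError("GraphML parse error: missing <graph> element")
    for node_el in g.findall("g:node", ns):
        labels: tuple[str, ...] = ()
        props: dict[str, Any] = {}
        for data_el in node_el.findall("g:data", ns):
            name, kind = keys[data_el.get("key")]
            text = data_el.text or ""
            if name == "labels":
                labels = tuple(text.split("|"))
            else:
                props[name] = _gml_parse(text, kind)
        graph.add_node(GraphNode(int(node_el.get("id")), labels, props))
    for edge_el in g.findall("g:edge", ns):
        etype = ""
        props = {}
        for data_el in edge_el.findall("g:data", ns):
            name, kind = keys[data_el.get("key")]
            text = data_el.text or ""
            if name == "type":
                etype = text
            else:
                props[name] = _gml_parse(text, kind)
        graph.add_edge(GraphEdge(int(edge_el.get("source")), int(edge_el.get("target")), etype, props))
    return graph


def _cypher_quote(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return str(value)
    text = str(value).replace("\\", "\\\\").replace("'", "\\'")
    return f"'{text}'"


def _to_cypher(graph: PropertyGraph) -> str:
    """Write-only Cypher script: a uniqueness-constraint preamble on dbId
    followed by one CREATE statement per node and per edge."""
    lines = [
        "CREATE CONSTRAINT db_id_unique IF NOT EXISTS "
        "FOR (n:DatabaseObject) REQUIRE n.dbId IS UNIQUE;",
    ]
    for n in graph.nodes():
        labels = ":".join(n.labels)
        props = {"dbId": n.node_id, **n.properties}
        body = ", ".join(f"{k}: {_cypher_quote(v)}" for k, v in sorted(props.items()))
        lines.append(f"CREATE (:{labels} {{{body}}});")
    for e in graph.edges():
        body = ", ".join(f"{k}: {_cypher_quote(v)}" for k, v in sorted(e.properties.items()))
        props = f" {{{body}}}" if body else ""
        lines.append(
            f"MATCH (a {{dbId: {e.source}}}), (b {{dbId: {e.target}}}) "
            f"CREATE (a)-[:{e.type}{props}]->(b);"
        )
    return "\n".join(lines) + "\n"


def export_graph(graph: PropertyGraph, format: str, destination) -> None:
    """Serialize to ``json``, ``graphml`` or ``cypher_script`` at a path."""
    from pathlib import Path

    destination = Path(destination)
    if format == "json":
        destination.write_text(json.dumps(_to_document(graph), indent=1, sort_keys=True))
    elif format == "graphml":
        destination.write_bytes(_to_graphml(graph))
    elif format == "cypher_script":
        destination.write_text(_to_cypher(graph), encoding="utf-8")
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_graph(source, format: str) -> PropertyGraph:
    """Load a graph from a ``json`` or ``graphml`` document."""
    from pathlib import Path

    source = Path(source)
    if format == "json":
        try:
            doc = json.loads(source.read_text())
        except json.JSONDecodeError as exc:
            raise GraphFormatError(f"JSON parse error at line {exc.lineno} col {exc.colno}: {exc.msg}") from exc
        return _from_document(doc)
    if format == "graphml":
        return _from_graphml(source.read_bytes())
    raise ValueError(f"unknown import format {format!r}")
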