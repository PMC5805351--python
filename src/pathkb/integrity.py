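"""Post-migration verification between an ObjectStore and its graph.

After a knowledgebase is migrated from the relational/object
representation to the property graph, three content checks are run —
the count of top-level pathways, the ancestor chains of pathways, and
the leaf content of complexes/sets — each comparing the answer computed
by graph traversal against the answer enumerated directly over the
store's slot values.  A conservation check additionally compares the
node-id set and the full (source, type, target, order) edge multiset
against the store, which makes every single-element graph mutation
(node or edge added, deleted or retargeted) detectable.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field

from . import oracles, query
from .graphstore import PropertyGraph
from .model import ObjectStore

__all__ = [
    "CheckResult",
    "IntegrityReport",
    "check_top_level_count",
    "check_ancestors",
    "check_complex_content",
    "verify_all",
]


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class IntegrityReport:
    checks: list[CheckResult]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "checks": [
                    {"name": c.name, "passed": c.passed, "detail": c.detail, "counts": c.counts}
                    for c in self.checks
                ],
            },
            indent=1,
        )

    def summary(self) -> str:
        lines = [f"overall: {'PASS' if self.passed else 'FAIL'}"]
        for c in self.checks:
            lines.append(f"  [{'ok' if c.passed else 'FAIL'}] {c.name}: {c.detail}")
        return "\n".join(lines)


def check_top_level_count(store: ObjectStore, graph: PropertyGraph) -> CheckResult:
    """Top-level pathway counts agree between store and graph.

    Graph-side, a top-level pathway is a Pathway node with no incoming
    ``hasEvent`` edge.
    """
    store_count = len(store.top_level_pathways)
    graph_count = sum(
        1
        for node in graph.find("label", "Pathway")
        if not graph.neighbors(node.node_id, ("hasEvent",), "in")
    )
    return CheckResult(
        "top_level_count",
        store_count == graph_count,
        f"store {store_count} vs graph {graph_count}",
        {"store": store_count, "graph": graph_count},
    )


def check_ancestors(store: ObjectStore, graph: PropertyGraph, pathway_id: int) -> CheckResult:
    """A pathway (or any event) has identical ancestor chains in both
    representations."""
    name = f"ancestors[{pathway_id}]"
    if pathway_id not in store.instances:
        return CheckResult(name, False, f"db_id {pathway_id} absent from store")
    if pathway_id not in graph:
        return CheckResult(name, False, f"db_id {pathway_id} absent from graph")
    try:
        graph_chains = query.event_ancestors(graph, pathway_id)
    except (query.NotFoundError, query.TypeMismatchError) as exc:
        return CheckResult(name, False, f"graph query failed: {exc}")
    store_chains = oracles.ancestors_store(store, pathway_id)
    ok = graph_chains == store_chains
    return CheckResult(
        name,
        ok,
        "chains agree" if ok else f"graph {graph_chains} vs store {store_chains}",
        {"graph_chains": len(graph_chains), "store_chains": len(store_chains)},
    )


def check_complex_content(store: ObjectStore, graph: PropertyGraph, complex_id: int) -> CheckResult:
    """The content of a complex/set is the same in both representations,
    compared both as leaf molecules (candidates excluded and included)
    and as direct components."""
    name = f"complex_content[{complex_id}]"
    if complex_id not in store.instances:
        return CheckResult(name, False, f"db_id {complex_id} absent from store")
    if complex_id not in graph:
        return CheckResult(name, False, f"db_id {complex_id} absent from graph")
    inst = store.instances[complex_id]
    for include_candidates in (False, True):
        g = query.decompose_entity(graph, complex_id, include_candidates=include_candidates)
        s = oracles.decompose_store(store, complex_id, include_candidates=include_candidates)
        if g != s:
            return CheckResult(
                name,
                False,
                f"leaf content differs (candidates={include_candidates}): graph {sorted(g)} vs store {sorted(s)}",
            )
    for slot in ("hasComponent", "hasMember", "hasCandidate"):
        raw = inst.slot_values.get(slot, [])
        store_direct = list(raw) if isinstance(raw, list) else [raw]
        graph_direct = [n.node_id for _e, n in graph.neighbors(complex_id, (slot,), "out")]
        if store_direct != graph_direct:
            return CheckResult(
                name, False, f"direct {slot} differs: graph {graph_direct} vs store {store_direct}"
            )
    return CheckResult(name, True, "content agrees", {})


def _check_conservation(
    store: ObjectStore, graph: PropertyGraph, include_orphans: bool
) -> list[CheckResult]:
    reachable = oracles.reachable_set(store)
    orphans = set(store.instances) - reachable
    expected_ids = reachable | (orphans if include_orphans else set())

    graph_ids = {n.node_id for n in graph.nodes()}
    node_ok = graph_ids == expected_ids
    orphan_note = f"; {len(orphans)} orphan(s) not imported" if orphans and not include_orphans else ""
    nodes = CheckResult(
        "node_conservation",
        node_ok,
        (f"{len(graph_ids)} nodes = {len(expected_ids)} imported instances" if node_ok
         else f"graph {len(graph_ids)} nodes vs {len(expected_ids)} expected instances") + orphan_note,
        {"graph_nodes": len(graph_ids), "expected_instances": len(expected_ids), "orphans": len(orphans)},
    )

    store_edges = Counter(
        (db_id, slot, target, order)
        for db_id in expected_ids
        for slot, order, target in store.instances[db_id].references(store.schema)
    )
    graph_edges = Counter((e.source, e.type, e.target, e.order) for e in graph.edges())
    edge_ok = store_edges == graph_edges
    edges = CheckResult(
        "edge_conservation",
        edge_ok,
        (f"{sum(graph_edges.values())} edges = {sum(store_edges.values())} reference slot values" if edge_ok
         else "edge multiset differs from store reference slot values"),
        {"graph_edges": sum(graph_edges.values()), "store_reference_values": sum(store_edges.values())},
    )
    return [nodes, edges]


def verify_all(
    store: ObjectStore,
    graph: PropertyGraph,
    sample: int | str = "all",
    seed: int | None = None,
    include_orphans: bool = False,
) -> IntegrityReport:
    """Run all integrity checks.

    ``sample="all"`` checks ancestors for every pathway and content for
    every complex/set; an integer samples that many of each with the
    given seed (deterministic).  ``include_orphans`` must mirror the
    flag the graph was imported with; orphans excluded by flag are
    reported in the conservation detail but do not fail the check.
    """
    checks = [check_top_level_count(store, graph)]
    checks.extend(_check_conservation(store, graph, include_orphans))

    in_graph = {n.node_id for n in graph.nodes()}
    pathways = sorted(
        i.db_id
        for i in store.instances.values()
        if store.schema.is_a(i.class_name, "Pathway") and i.db_id in in_graph
    )
    containers = sorted(
        i.db_id
        for i in store.instances.values()
        if i.class_name in ("Complex", "EntitySet") and i.db_id in in_graph
    )
    if sample != "all":
        rng = random.Random(seed)
        if len(pathways) > int(sample):
            pathways = sorted(rng.sample(pathways, int(sample)))
        if len(containers) > int(sample):
            containers = sorted(rng.sample(containers, int(sample)))
    for pid in pathways:
        checks.append(check_ancestors(store, graph, pid))
    for cid in containers:
        checks.append(check_complex_content(store, graph, cid))
    return IntegrityReport(checks)
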