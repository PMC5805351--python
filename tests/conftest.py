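import random

import pytest

from pathkb import SynthConfig, generate, import_knowledgebase, worked_toy
from pathkb.graphstore import GraphEdge, GraphNode, PropertyGraph

# Twenty seeded knowledgebase configurations spanning 100-500 instances,
# cycling through four structural variants (baseline, wide, large, orphaned).
_VARIANTS = [
    dict(),
    dict(n_proteins=80, n_chemicals=30, n_top_pathways=4),
    dict(n_proteins=140, n_chemicals=60, n_top_pathways=6, reactions_per_pathway=(3, 6)),
    dict(n_proteins=40, n_chemicals=15, n_top_pathways=3, orphan_count=4),
]

SEEDED_CONFIGS = [SynthConfig(seed=seed, **_VARIANTS[seed % len(_VARIANTS)]) for seed in range(20)]


@pytest.fixture(scope="session")
def seeded_kbs():
    """(config, store, ground_truth, graph, report) for 20 seeded KBs."""
    out = []
    for config in SEEDED_CONFIGS:
        store, truth = generate(config)
        graph, report = import_knowledgebase(store)
        out.append((config, store, truth, graph, report))
    return out


@pytest.fixture(scope="session")
def toy():
    store, truth = worked_toy()
    graph, report = import_knowledgebase(store)
    return store, truth, graph, report


def random_mutation(graph: PropertyGraph, rng: random.Random) -> str:
    """Apply one random single-element mutation in place; returns a label.

    Kinds: node added, node deleted, edge added, edge deleted, edge
    retargeted — the events a faulty migration could produce.
    """
    kind = rng.choice(["add_node", "del_node", "add_edge", "del_edge", "retarget_edge"])
    nodes = graph.nodes()
    edges = graph.edges()
    if kind == "add_node":
        new_id = max(n.node_id for n in nodes) + rng.randint(1, 100)
        template = rng.choice(nodes)
        graph.add_node(GraphNode(new_id, template.labels, {"stId": f"R-MUT-{new_id}", "displayName": "spurious"}))
    elif kind == "del_node":
        graph.remove_node(rng.choice(nodes).node_id)
    elif kind == "add_edge":
        src = rng.choice(nodes)
        tgt = rng.choice(nodes)
        etype = rng.choice(["input", "output", "hasEvent", "hasComponent", "hasMember"])
        order = len([e for e in graph.edges() if e.source == src.node_id and e.type == etype])
        graph.add_edge(GraphEdge(src.node_id, tgt.node_id, etype, {"order": order}))
    elif kind == "del_edge":
        graph.remove_edge(rng.choice(edges))
    else:  # retarget_edge
        edge = rng.choice(edges)
        others = [n.node_id for n in nodes if n.node_id != edge.target]
        graph.remove_edge(edge)
        for candidate in rng.sample(others, len(others)):
            retargeted = GraphEdge(edge.source, candidate, edge.type, dict(edge.properties))
            if retargeted.key() not in {e.key() for e in graph.edges()}:
                graph.add_edge(retargeted)
                break
        # if every retarget would collide the mutation degenerates to a
        # deletion, which is still a single-element change
    return kind
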