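"""Traversal queries over the pathway property graph.

These are the knowledgebase use cases that motivate storing pathway data
as a graph: reaction input/output retrieval, recursive enumeration of a
pathway's events, collecting a pathway's participating molecules
(optionally decomposed into leaf molecules), the inverse entity-to-
pathways lookup, event ancestor chains, chains of consecutive reactions
leading to an entity, and lazy/eager object retrieval.

Identifier arguments accept either a ``dbId`` integer or an ``stId``
string.  Node sets are returned sorted by db_id; chains sorted by
(length, db_id sequence) — deterministic order over "natural" order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

from .graphstore import GraphNode, PropertyGraph

__all__ = [
    "NotFoundError",
    "TypeMismatchError",
    "ParticipantRecord",
    "ReactionChain",
    "ObjectView",
    "Placeholder",
    "reaction_io",
    "pathway_events",
    "pathway_participants",
    "decompose_entity",
    "pathways_for_entity",
    "event_ancestors",
    "reaction_chains_to",
    "fetch",
]

COMPOSITION_TYPES = ("hasComponent", "hasMember")
CANDIDATE_TYPE = "hasCandidate"


class NotFoundError(KeyError):
    """Identifier resolves to no node."""


class TypeMismatchError(TypeError):
    """Identifier resolves to a node of the wrong class."""


def _resolve(graph: PropertyGraph, identifier: int | str, expected_label: str | None = None) -> GraphNode:
    node = graph.resolve(identifier)
    if node is None:
        raise NotFoundError(f"no node with identifier {identifier!r}")
    if expected_label is not None and expected_label not in node.labels:
        raise TypeMismatchError(
            f"node {identifier!r} is a {node.concrete_class}, expected {expected_label}"
        )
    return node


@dataclass
class ParticipantRecord:
    """One participating entity of a pathway with role provenance."""

    entity: int
    roles: set[str] = field(default_factory=set)
    via_reactions: set[int] = field(default_factory=set)

    def as_tuple(self) -> tuple[int, tuple[str, ...], tuple[int, ...]]:
        return (self.entity, tuple(sorted(self.roles)), tuple(sorted(self.via_reactions)))


@dataclass(frozen=True)
class ReactionChain:
    """A chain of consecutive reactions whose last step outputs the
    terminal entity."""

    reactions: tuple[int, ...]
    terminal_entity: int


def reaction_io(graph: PropertyGraph, reaction_id: int | str) -> tuple[list[int], list[int]]:
    """Ordered input and output entity ids of a reaction-like event.

    Repeated stoichiometric entities appear repeatedly, in edge order.
    """
    node = _resolve(graph, reaction_id, "ReactionLikeEvent")
    inputs = [n.node_id for _e, n in graph.neighbors(node.node_id, ("input",), "out")]
    outputs = [n.node_id for _e, n in graph.neighbors(node.node_id, ("output",), "out")]
    return inputs, outputs


def pathway_events(graph: PropertyGraph, pathway_id: int | str, recursive: bool = True) -> set[int]:
    """Events contained in a pathway: direct ``hasEvent`` children, or
    the full transitive closure when ``recursive``.  Cycle-safe."""
    node = _resolve(graph, pathway_id, "Pathway")
    depth = None if recursive else 1
    return set(graph.traverse([node.node_id], ("hasEvent",), "out", max_depth=depth))


def _entity_of_catalyst(graph: PropertyGraph, ca_id: int) -> list[int]:
    return [n.node_id for _e, n in graph.neighbors(ca_id, ("physicalEntity",), "out")]


def _entity_of_regulation(graph: PropertyGraph, reg_id: int) -> list[int]:
    return [n.node_id for _e, n in graph.neighbors(reg_id, ("regulator",), "out")]


def _stated_participants(graph: PropertyGraph, rle_id: int, include_catalysts: bool, include_regulators: bool):
    """(entity, role) pairs stated directly on one reaction-like event."""
    inputs, outputs = reaction_io(graph, rle_id)
    pairs = [(e, "input") for e in inputs] + [(e, "output") for e in outputs]
    if include_catalysts:
        for _edge, ca in graph.neighbors(rle_id, ("catalystActivity",), "out"):
            pairs.extend((e, "catalyst") for e in _entity_of_catalyst(graph, ca.node_id))
    if include_regulators:
        for _edge, reg in graph.neighbors(rle_id, ("regulatedBy",), "out"):
            pairs.extend((e, "regulator") for e in _entity_of_regulation(graph, reg.node_id))
    return pairs


def pathway_participants(
    graph: PropertyGraph,
    pathway_id: int | str,
    include_catalysts: bool = True,
    include_regulators: bool = True,
    decompose: bool = False,
    include_candidates: bool = False,
) -> list[ParticipantRecord]:
    """Participating entities over all reactions of a pathway, recursively.

    With ``decompose`` each stated entity is expanded into its leaf
    molecules and records are merged per leaf, with roles and reaction
    provenance unioned.
    """
    node = _resolve(graph, pathway_id, "Pathway")
    events = pathway_events(graph, node.node_id, recursive=True) | {node.node_id}
    records: dict[int, ParticipantRecord] = {}
    for event_id in sorted(events):
        if "ReactionLikeEvent" not in graph.node(event_id).labels:
            continue
        for entity, role in _stated_participants(graph, event_id, include_catalysts, include_regulators):
            targets = (
                decompose_entity(graph, entity, include_candidates=include_candidates)
                if decompose
                else {entity}
            )
            for t in targets:
                rec = records.setdefault(t, ParticipantRecord(t))
                rec.roles.add(role)
                rec.via_reactions.add(event_id)
    return [records[k] for k in sorted(records)]


def _composition_types(include_candidates: bool) -> tuple[str, ...]:
    return COMPOSITION_TYPES + ((CANDIDATE_TYPE,) if include_candidates else ())


def _is_leaf(graph: PropertyGraph, node_id: int, types: tuple[str, ...]) -> bool:
    return not graph.neighbors(node_id, types, "out")


def decompose_entity(
    graph: PropertyGraph, entity_id: int | str, include_candidates: bool = False
) -> set[int]:
    """Leaf molecules of a physical entity.

    Transitive closure over ``hasComponent`` / ``hasMember`` (and
    ``hasCandidate`` when requested); leaves are the reached nodes with
    no outgoing composition edge of the traversed kinds — chemicals,
    proteins, or empty containers.  A leaf input returns itself.
    Terminates on shared and (artificially) cyclic substructure.
    """
    node = _resolve(graph, entity_id, "PhysicalEntity")
    types = _composition_types(include_candidates)
    closure = set(graph.traverse([node.node_id], types, "out")) | {node.node_id}
    return {n for n in closure if _is_leaf(graph, n, types)}


def pathways_for_entity(
    graph: PropertyGraph, entity_id: int | str, leaf_match: bool = True
) -> set[int]:
    """Pathways in which an entity participates — the inverse image of
    :func:`pathway_participants` (catalysts and regulators included,
    decomposition per ``leaf_match``).

    Implemented by upward traversal: composition edges inward (when
    ``leaf_match``), then reaction-role edges inward, then the
    ``hasEvent`` closure inward.  With ``leaf_match`` the entity must
    itself be a leaf molecule (decomposed participant lists contain only
    leaves); a non-leaf entity therefore maps to no pathway.
    """
    node = _resolve(graph, entity_id)
    if "PhysicalEntity" not in node.labels:
        raise TypeMismatchError(f"node {entity_id!r} is a {node.concrete_class}, not a PhysicalEntity")
    if leaf_match:
        if not _is_leaf(graph, node.node_id, _composition_types(False)):
            return set()
        holders = set(graph.traverse([node.node_id], COMPOSITION_TYPES, "in")) | {node.node_id}
    else:
        holders = {node.node_id}

    rles: set[int] = set()
    for h in holders:
        for _e, rxn in graph.neighbors(h, ("input", "output"), "in"):
            rles.add(rxn.node_id)
        for _e, ca in graph.neighbors(h, ("physicalEntity",), "in"):
            for _e2, rxn in graph.neighbors(ca.node_id, ("catalystActivity",), "in"):
                rles.add(rxn.node_id)
        for _e, reg in graph.neighbors(h, ("regulator",), "in"):
            for _e2, rxn in graph.neighbors(reg.node_id, ("regulatedBy",), "in"):
                rles.add(rxn.node_id)

    containers = set(graph.traverse(sorted(rles), ("hasEvent",), "in")) if rles else set()
    return {p for p in containers if "Pathway" in graph.node(p).labels}


def event_ancestors(graph: PropertyGraph, event_id: int | str) -> list[list[int]]:
    """All distinct root-to-event chains following ``hasEvent`` upward.

    Each chain starts at an event with no (off-path) parent and ends at
    the queried event.  Cycle-safe; chains are sorted by their db_id
    sequences.
    """
    node = _resolve(graph, event_id, "Event")
    chains: list[list[int]] = []

    def climb(current: int, path: tuple[int, ...]) -> None:
        parents = [
            n.node_id
            for _e, n in graph.neighbors(current, ("hasEvent",), "in")
            if n.node_id not in path
        ]
        if not parents:
            chains.append(list(reversed(path)))
            return
        for parent in parents:
            climb(parent, path + (parent,))

    climb(node.node_id, (node.node_id,))
    unique = sorted({tuple(c) for c in chains})
    return [list(c) for c in unique]


def _producers(graph: PropertyGraph, entity_id: int) -> list[int]:
    return sorted({n.node_id for _e, n in graph.neighbors(entity_id, ("output",), "in")})


def _predecessors(graph: PropertyGraph, reaction_id: int, link_mode: str) -> set[int]:
    if link_mode == "shared_entity":
        preds: set[int] = set()
        inputs, _ = reaction_io(graph, reaction_id)
        for ent in set(inputs):
            preds.update(_producers(graph, ent))
        return preds
    if link_mode == "preceding_event":
        return {
            n.node_id
            for _e, n in graph.neighbors(reaction_id, ("precedingEvent",), "out")
            if "ReactionLikeEvent" in n.labels
        }
    raise ValueError(f"unknown link_mode {link_mode!r}")


def reaction_chains_to(
    graph: PropertyGraph,
    target_entity_id: int | str,
    max_length: int = 5,
    link_mode: str = "shared_entity",
) -> list[ReactionChain]:
    """All acyclic chains of consecutive reactions ending in a reaction
    that outputs the target entity.

    Consecutive reactions are linked either because a predecessor's
    output is a successor's input (``shared_entity``, the default) or by
    explicit ``precedingEvent`` edges.  Every suffix of a longer chain is
    itself a chain.  Deterministic order: (length, db_id sequence).
    """
    node = _resolve(graph, target_entity_id, "PhysicalEntity")
    found: set[tuple[int, ...]] = set()

    def extend_back(chain: tuple[int, ...]) -> None:
        found.add(chain)
        if len(chain) >= max_length:
            return
        for pred in sorted(_predecessors(graph, chain[0], link_mode)):
            if pred not in chain:
                extend_back((pred,) + chain)

    for producer in _producers(graph, node.node_id):
        extend_back((producer,))
    ordered = sorted(found, key=lambda c: (len(c), c))
    return [ReactionChain(reactions=c, terminal_entity=node.node_id) for c in ordered]


# ---------------------------------------------------------------------------
# Lazy/eager object retrieval


@dataclass
class Placeholder:
    """An unresolved reference in an object view.

    ``is_cycle`` marks a reference back to an ancestor in the current
    view; such references stay placeholders even under full retrieval.
    Resolving a depth-limit placeholder on demand yields exactly what
    eager retrieval would have produced (lazy/eager equivalence).
    """

    graph: PropertyGraph
    node_id: int
    path: tuple[int, ...]
    is_cycle: bool

    def resolve(self, depth: int | str = "shallow") -> "ObjectView":
        return _build_view(self.graph, self.node_id, _depth_budget(depth), self.path)


@dataclass
class ObjectView:
    """A marshalled knowledgebase object: node properties plus reference
    slots holding either nested views or placeholders."""

    node_id: int
    labels: tuple[str, ...]
    properties: dict[str, Any]
    refs: dict[str, list]

    def to_plain(self, materialize: bool = False) -> dict:
        """Nested-dict form for comparison.  With ``materialize``, depth
        placeholders are resolved on demand (cycle cuts stay refs)."""
        out: dict[str, Any] = {
            "dbId": self.node_id,
            "labels": list(self.labels),
            "properties": dict(sorted(self.properties.items())),
            "refs": {},
        }
        for slot, values in sorted(self.refs.items()):
            plain = []
            for v in values:
                if isinstance(v, Placeholder):
                    if materialize and not v.is_cycle:
                        plain.append(v.resolve("full").to_plain(materialize=True))
                    else:
                        plain.append({"ref": v.node_id})
                else:
                    plain.append(v.to_plain(materialize=materialize))
            out["refs"][slot] = plain
        return out


def _depth_budget(depth: int | str) -> int | None:
    if depth == "shallow":
        return 0
    if depth == "full":
        return None
    if isinstance(depth, int) and depth >= 0:
        return depth
    raise ValueError(f"bad fetch depth {depth!r}")


def _build_view(
    graph: PropertyGraph, node_id: int, budget: int | None, path: tuple[int, ...]
) -> ObjectView:
    node = graph.node(node_id)
    refs: dict[str, list] = {}
    new_path = path + (node_id,)
    for edge, nbr in graph.neighbors(node_id, None, "out"):
        values = refs.setdefault(edge.type, [])
        if nbr.node_id in new_path:
            values.append(Placeholder(graph, nbr.node_id, new_path, is_cycle=True))
        elif budget == 0:
            values.append(Placeholder(graph, nbr.node_id, new_path, is_cycle=False))
        else:
            child_budget = None if budget is None else budget - 1
            values.append(_build_view(graph, nbr.node_id, child_budget, new_path))
    return ObjectView(node_id, node.labels, dict(node.properties), refs)


def fetch(graph: PropertyGraph, identifier: int | str, depth: int | str = "shallow") -> ObjectView:
    """Retrieve an object view at the requested depth.

    ``shallow`` returns properties with reference placeholders; an
    integer materialises references to that depth; ``full`` builds the
    complete closure, cutting cycles with permanent placeholders.
    """
    node = _resolve(graph, identifier)
    return _build_view(graph, node.node_id, _depth_budget(depth), ())
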