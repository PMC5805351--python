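"""Brute-force enumerations over the :class:`~pathkb.model.ObjectStore`.

Every traversal the query engine performs on the property graph has a
naive counterpart here that walks the object store's slot values
directly — fixed-point closures, exhaustive path enumeration, recursive
slot expansion.  The integrity module compares the two routes after a
migration, and the test suite uses them as independent oracles: the
functions here never touch a :class:`~pathkb.graphstore.PropertyGraph`.
"""

from __future__ import annotations

from typing import Any

from .model import Instance, ObjectStore

COMPOSITION_SLOTS = ("hasComponent", "hasMember")


def _many(inst: Instance, slot: str) -> list[int]:
    raw = inst.slot_values.get(slot, [])
    return list(raw) if isinstance(raw, list) else [raw]


def _one(inst: Instance, slot: str) -> int | None:
    raw = inst.slot_values.get(slot)
    if isinstance(raw, list):
        return raw[0] if raw else None
    return raw


def _is_a(store: ObjectStore, db_id: int, class_name: str) -> bool:
    inst = store.instances.get(db_id)
    return inst is not None and store.schema.is_a(inst.class_name, class_name)


def reachable_set(store: ObjectStore) -> set[int]:
    """Fixed point of one-step reference expansion from the top-level
    pathways (naive iterate-until-stable formulation)."""
    current = {i for i in store.top_level_pathways if i in store.instances}
    while True:
        nxt = set(current)
        for db_id in current:
            for _slot, _order, target in store.instances[db_id].references(store.schema):
                if target in store.instances:
                    nxt.add(target)
        if nxt == current:
            return current
        current = nxt


def reference_value_count(store: ObjectStore, db_ids: set[int]) -> int:
    """Total number of reference slot values over the given instances."""
    return sum(len(store.instances[i].references(store.schema)) for i in db_ids)


def reaction_io_store(store: ObjectStore, reaction_id: int) -> tuple[list[int], list[int]]:
    inst = store.instances[reaction_id]
    return _many(inst, "input"), _many(inst, "output")


def events_store(store: ObjectStore, pathway_id: int, recursive: bool = True) -> set[int]:
    """Fixed-point closure over ``hasEvent`` slots."""
    frontier = set(_many(store.instances[pathway_id], "hasEvent"))
    if not recursive:
        return frontier
    closure: set[int] = set()
    while frontier:
        closure |= frontier
        frontier = {
            c
            for e in frontier
            if e in store.instances
            for c in _many(store.instances[e], "hasEvent")
        } - closure
    return closure


def decompose_store(store: ObjectStore, entity_id: int, include_candidates: bool = False) -> set[int]:
    """Naive recursive slot expansion down to leaf molecules."""
    slots = COMPOSITION_SLOTS + (("hasCandidate",) if include_candidates else ())

    def children(db_id: int) -> list[int]:
        inst = store.instances[db_id]
        return [c for s in slots for c in _many(inst, s)]

    leaves: set[int] = set()
    seen: set[int] = set()

    def expand(db_id: int) -> None:
        if db_id in seen:
            return
        seen.add(db_id)
        kids = children(db_id)
        if not kids:
            leaves.add(db_id)
        for kid in kids:
            expand(kid)

    expand(entity_id)
    return leaves


def _rles_of_pathway(store: ObjectStore, pathway_id: int) -> list[int]:
    return sorted(e for e in events_store(store, pathway_id, True) if _is_a(store, e, "ReactionLikeEvent"))


def participants_store(
    store: ObjectStore,
    pathway_id: int,
    include_catalysts: bool = True,
    include_regulators: bool = True,
    decompose: bool = False,
    include_candidates: bool = False,
) -> dict[int, dict[str, set]]:
    """``{entity: {"roles": set, "via": set}}`` by direct enumeration."""
    out: dict[int, dict[str, set]] = {}

    def record(entity: int, role: str, rxn: int) -> None:
        targets = decompose_store(store, entity, include_candidates) if decompose else {entity}
        for t in targets:
            rec = out.setdefault(t, {"roles": set(), "via": set()})
            rec["roles"].add(role)
            rec["via"].add(rxn)

    for rle_id in _rles_of_pathway(store, pathway_id):
        inst = store.instances[rle_id]
        for e in _many(inst, "input"):
            record(e, "input", rle_id)
        for e in _many(inst, "output"):
            record(e, "output", rle_id)
        if include_catalysts:
            for ca in _many(inst, "catalystActivity"):
                pe = _one(store.instances[ca], "physicalEntity")
                if pe is not None:
                    record(pe, "catalyst", rle_id)
        if include_regulators:
            for reg in _many(inst, "regulatedBy"):
                pe = _one(store.instances[reg], "regulator")
                if pe is not None:
                    record(pe, "regulator", rle_id)
    return out


def pathways_for_entity_store(store: ObjectStore, entity_id: int, leaf_match: bool = True) -> set[int]:
    """Literal inverse image: scan every pathway's participant set."""
    result: set[int] = set()
    for inst in store.instances.values():
        if not store.schema.is_a(inst.class_name, "Pathway"):
            continue
        participants = participants_store(
            store, inst.db_id, include_catalysts=True, include_regulators=True, decompose=leaf_match
        )
        if entity_id in participants:
            result.add(inst.db_id)
    return result


def _parent_map(store: ObjectStore) -> dict[int, list[int]]:
    parents: dict[int, list[int]] = {}
    for inst in store.instances.values():
        for child in _many(inst, "hasEvent"):
            parents.setdefault(child, []).append(inst.db_id)
    return parents


def ancestors_store(store: ObjectStore, event_id: int) -> list[list[int]]:
    """Root-first chains by DFS over reversed ``hasEvent`` slots."""
    parents = _parent_map(store)
    chains: list[tuple[int, ...]] = []

    def climb(current: int, path: tuple[int, ...]) -> None:
        ups = [p for p in parents.get(current, []) if p not in path]
        if not ups:
            chains.append(tuple(reversed(path)))
            return
        for p in ups:
            climb(p, path + (p,))

    climb(event_id, (event_id,))
    return [list(c) for c in sorted(set(chains))]


def chains_store(
    store: ObjectStore, entity_id: int, max_length: int = 5, link_mode: str = "shared_entity"
) -> list[tuple[int, ...]]:
    """Exhaustive enumeration of acyclic reaction chains ending at the
    reactions that output the entity."""
    rles = [i for i in store.instances.values() if _is_a(store, i.db_id, "ReactionLikeEvent")]
    producers_of: dict[int, set[int]] = {}
    for r in rles:
        for out in set(_many(r, "output")):
            producers_of.setdefault(out, set()).add(r.db_id)

    def predecessors(rid: int) -> set[int]:
        inst = store.instances[rid]
        if link_mode == "shared_entity":
            preds: set[int] = set()
            for ent in set(_many(inst, "input")):
                preds |= producers_of.get(ent, set())
            return preds
        return {p for p in _many(inst, "precedingEvent") if _is_a(store, p, "ReactionLikeEvent")}

    found: set[tuple[int, ...]] = set()

    def back(chain: tuple[int, ...]) -> None:
        found.add(chain)
        if len(chain) >= max_length:
            return
        for pred in predecessors(chain[0]):
            if pred not in chain:
                back((pred,) + chain)

    for producer in producers_of.get(entity_id, set()):
        back((producer,))
    return sorted(found, key=lambda c: (len(c), c))


def marshal_store(store: ObjectStore, db_id: int, path: tuple[int, ...] = ()) -> dict[str, Any]:
    """Eager nested marshalling straight from slot values, in the plain
    form :meth:`pathkb.query.ObjectView.to_plain` produces."""
    inst = store.instances[db_id]
    schema = store.schema
    props: dict[str, Any] = {"stId": inst.st_id, "displayName": inst.display_name}
    eff = schema.effective_slots(inst.class_name)
    for slot_name, raw in inst.slot_values.items():
        slot = eff.get(slot_name)
        if slot is not None and not slot.is_reference:
            props[slot_name] = raw
    new_path = path + (db_id,)
    refs: dict[str, list] = {}
    for slot_name, slot in eff.items():
        if not slot.is_reference or slot_name not in inst.slot_values:
            continue
        values = []
        for _s, _o, target in [r for r in inst.references(schema) if r[0] == slot_name]:
            if target in new_path:
                values.append({"ref": target})
            else:
                values.append(marshal_store(store, target, new_path))
        refs[slot_name] = values
    return {
        "dbId": db_id,
        "labels": list(schema.ancestors(inst.class_name)),
        "properties": dict(sorted(props.items())),
        "refs": {k: refs[k] for k in sorted(refs)},
    }
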