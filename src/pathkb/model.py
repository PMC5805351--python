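"""Frame-based knowledge representation for pathway knowledgebases.

The model follows the frame paradigm used by curated pathway
resources: a schema of *classes* (frames) arranged in a single
inheritance tree, each class carrying typed *slots* whose values are
either primitives (string / number / boolean) or references to instances
of other classes.  Knowledge is captured as :class:`Instance` objects
filling those slots, collected in an :class:`ObjectStore` together with
the list of top-level pathways that root the event hierarchy.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Mapping

__all__ = [
    "SlotDefinition",
    "SchemaClass",
    "Schema",
    "SchemaError",
    "Instance",
    "ObjectStore",
    "Violation",
    "ValidationReport",
    "builtin_schema",
    "validate_instance",
    "validate_store",
    "ROOT_CLASS",
]

ROOT_CLASS = "DatabaseObject"

PRIMITIVE_KINDS = ("string", "number", "boolean")

_PY_KINDS = {
    "string": (str,),
    "number": (int, float),
    "boolean": (bool,),
}


class SchemaError(ValueError):
    """A schema definition violates the well-formedness rules."""


@dataclass(frozen=True)
class SlotDefinition:
    """A typed attribute of a schema class.

    ``value_kind`` is one of ``string`` / ``number`` / ``boolean`` for
    primitive slots, or ``"reference"`` with ``target`` naming the class
    whose instances (or subclasses thereof) may fill the slot.  Ordered
    multi-valued reference slots preserve insertion order, which the
    graph importer materialises as an ``order`` edge property.
    """

    name: str
    cardinality: str = "one"  # "one" | "many"
    value_kind: str = "string"
    target: str | None = None
    ordered: bool = False

    def __post_init__(self) -> None:
        if self.cardinality not in ("one", "many"):
            raise SchemaError(f"slot {self.name}: bad cardinality {self.cardinality!r}")
        if self.value_kind == "reference":
            if not self.target:
                raise SchemaError(f"slot {self.name}: reference slot needs a target class")
        elif self.value_kind in PRIMITIVE_KINDS:
            if self.target is not None:
                raise SchemaError(f"slot {self.name}: primitive slot cannot have a target")
        else:
            raise SchemaError(f"slot {self.name}: unknown value_kind {self.value_kind!r}")

    @property
    def is_reference(self) -> bool:
        return self.value_kind == "reference"


@dataclass(frozen=True)
class SchemaClass:
    """A frame: a named class with an optional parent and its own slots."""

    name: str
    parent: str | None = None
    slots: tuple[SlotDefinition, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "slots", tuple(self.slots))
        names = [s.name for s in self.slots]
        if len(names) != len(set(names)):
            raise SchemaError(f"class {self.name}: duplicate slot names")


class Schema:
    """A collection of classes forming a single-rooted inheritance tree."""

    def __init__(self, classes: Iterable[SchemaClass] = ()) -> None:
        self._classes: dict[str, SchemaClass] = {}
        self._frozen_names: frozenset[str] = frozenset()
        for cls in classes:
            self.add_class(cls)

    # -- construction -------------------------------------------------

    def add_class(self, cls: SchemaClass) -> None:
        """Register a class.  Built-in classes cannot be replaced."""
        if cls.name in self._classes:
            raise SchemaError(f"class {cls.name} already defined")
        if cls.parent is not None and cls.parent not in self._classes:
            raise SchemaError(f"class {cls.name}: unknown parent {cls.parent}")
        if cls.parent is None and any(c.parent is None for c in self._classes.values()):
            raise SchemaError("schema already has a root class")
        inherited = self.effective_slots(cls.parent) if cls.parent else {}
        for slot in cls.slots:
            if slot.name in inherited:
                raise SchemaError(f"class {cls.name}: slot {slot.name} shadows an inherited slot")
        self._classes[cls.name] = cls

    def freeze_builtins(self) -> None:
        self._frozen_names = frozenset(self._classes)

    def check(self) -> list[str]:
        """Well-formedness problems: unresolved slot targets (reference
        targets may be declared after the class that uses them, so this
        runs after construction)."""
        problems: list[str] = []
        for cls in self._classes.values():
            for slot in cls.slots:
                if slot.is_reference and slot.target not in self._classes:
                    problems.append(f"class {cls.name}: slot {slot.name} targets unknown class {slot.target}")
        return problems

    # -- lookup -------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._classes

    def __getitem__(self, name: str) -> SchemaClass:
        return self._classes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._classes)

    @property
    def classes(self) -> Mapping[str, SchemaClass]:
        return dict(self._classes)

    def ancestors(self, name: str) -> list[str]:
        """Class names from ``name`` up to the root, inclusive."""
        chain: list[str] = []
        cur: str | None = name
        while cur is not None:
            if cur in chain:
                raise SchemaError(f"inheritance cycle at {cur}")
            chain.append(cur)
            cur = self._classes[cur].parent
        return chain

    def is_a(self, name: str, ancestor: str) -> bool:
        return ancestor in self.ancestors(name)

    def descendants(self, name: str) -> set[str]:
        out = {name}
        changed = True
        while changed:
            changed = False
            for cls in self._classes.values():
                if cls.parent in out and cls.name not in out:
                    out.add(cls.name)
                    changed = True
        return out

    def effective_slots(self, name: str) -> dict[str, SlotDefinition]:
        """Own plus inherited slots, root-first so order is deterministic."""
        slots: dict[str, SlotDefinition] = {}
        for cls_name in reversed(self.ancestors(name)):
            for slot in self._classes[cls_name].slots:
                slots[slot.name] = slot
        return slots

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "classes": [
                {
                    "name": c.name,
                    "parent": c.parent,
                    "slots": [
                        {
                            "name": s.name,
                            "cardinality": s.cardinality,
                            "value_kind": s.value_kind,
                            "target": s.target,
                            "ordered": s.ordered,
                        }
                        for s in c.slots
                    ],
                }
                for c in self._classes.values()
            ]
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Schema":
        doc = json.loads(text)
        schema = cls()
        # classes may be serialized in any order; insert parents first
        pending = {c["name"]: c for c in doc["classes"]}
        while pending:
            progressed = False
            for name in list(pending):
                c = pending[name]
                if c["parent"] is None or c["parent"] in schema:
                    schema.add_class(
                        SchemaClass(
                            name=c["name"],
                            parent=c["parent"],
                            slots=tuple(
                                SlotDefinition(
                                    name=s["name"],
                                    cardinality=s["cardinality"],
                                    value_kind=s["value_kind"],
                                    target=s.get("target"),
                                    ordered=s.get("ordered", False),
                                )
                                for s in c["slots"]
                            ),
                        )
                    )
                    del pending[name]
                    progressed = True
            if not progressed:
                raise SchemaError(f"unresolvable parents for classes: {sorted(pending)}")
        return schema

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Schema):
            return NotImplemented
        return self._classes == other._classes


def builtin_schema() -> Schema:
    """The built-in pathway schema.

    The hierarchy roots at ``DatabaseObject`` and mirrors the core of
    curated pathway knowledgebases: ``Event`` splits into ``Pathway``
    (ordered containers of events via ``hasEvent``) and
    ``ReactionLikeEvent`` (single-step transformations with ``input`` /
    ``output`` / ``catalystActivity`` / ``regulatedBy`` /
    ``precedingEvent`` slots), while ``PhysicalEntity`` covers chemicals
    (``SimpleEntity``), proteins (``EntityWithAccessionedSequence``),
    multi-molecular ``Complex`` structures and functional ``EntitySet``
    groupings.  Catalysis and regulation go through the intermediate
    ``CatalystActivity`` and ``Regulation`` classes.
    """
    ref = lambda n, t, ordered=False: SlotDefinition(  # noqa: E731
        n, cardinality="many", value_kind="reference", target=t, ordered=ordered
    )
    schema = Schema()
    schema.add_class(
        SchemaClass(
            ROOT_CLASS,
            None,
            (
                SlotDefinition("displayName", "one", "string"),
                SlotDefinition("stId", "one", "string"),
                SlotDefinition("speciesName", "one", "string"),
            ),
        )
    )
    schema.add_class(SchemaClass("Event", ROOT_CLASS))
    schema.add_class(SchemaClass("Pathway", "Event", (ref("hasEvent", "Event", ordered=True),)))
    schema.add_class(
        SchemaClass(
            "ReactionLikeEvent",
            "Event",
            (
                ref("input", "PhysicalEntity", ordered=True),
                ref("output", "PhysicalEntity", ordered=True),
                ref("catalystActivity", "CatalystActivity"),
                ref("precedingEvent", "Event"),
                ref("regulatedBy", "Regulation"),
            ),
        )
    )
    schema.add_class(SchemaClass("PhysicalEntity", ROOT_CLASS))
    schema.add_class(
        SchemaClass(
            "CatalystActivity",
            ROOT_CLASS,
            (SlotDefinition("physicalEntity", "one", "reference", "PhysicalEntity"),),
        )
    )
    schema.add_class(
        SchemaClass(
            "Regulation",
            ROOT_CLASS,
            (SlotDefinition("regulator", "one", "reference", "PhysicalEntity"),),
        )
    )
    for rle_sub in ("Reaction", "FailedReaction", "Polymerisation", "Depolymerisation", "BlackBoxEvent"):
        schema.add_class(SchemaClass(rle_sub, "ReactionLikeEvent"))
    schema.add_class(SchemaClass("SimpleEntity", "PhysicalEntity"))
    schema.add_class(SchemaClass("EntityWithAccessionedSequence", "PhysicalEntity"))
    schema.add_class(
        SchemaClass("Complex", "PhysicalEntity", (ref("hasComponent", "PhysicalEntity", ordered=True),))
    )
    schema.add_class(
        SchemaClass(
            "EntitySet",
            "PhysicalEntity",
            (ref("hasMember", "PhysicalEntity"), ref("hasCandidate", "PhysicalEntity")),
        )
    )
    problems = schema.check()
    assert not problems, problems
    schema.freeze_builtins()
    return schema


# Slot names whose values the composition queries traverse.
COMPOSITION_SLOTS = ("hasComponent", "hasMember", "hasCandidate")


@dataclass
class Instance:
    """One knowledgebase object: an instance of a schema class.

    ``slot_values`` maps slot names to a scalar (cardinality-one) or a
    list (cardinality-many); reference slots hold ``db_id`` integers.
    ``stId`` and ``displayName`` live on the instance itself, not in
    ``slot_values``.
    """

    db_id: int
    st_id: str
    class_name: str
    display_name: str = ""
    slot_values: dict[str, Any] = field(default_factory=dict)

    def references(self, schema: Schema) -> list[tuple[str, int, int]]:
        """All (slot_name, order_index, target_db_id) triples, slot order
        following the effective slot declaration order."""
        out: list[tuple[str, int, int]] = []
        eff = schema.effective_slots(self.class_name)
        for slot_name, slot in eff.items():
            if not slot.is_reference or slot_name not in self.slot_values:
                continue
            raw = self.slot_values[slot_name]
            values = raw if isinstance(raw, list) else [raw]
            for i, target in enumerate(values):
                out.append((slot_name, i, target))
        return out


@dataclass
class ObjectStore:
    """The object-side view of a knowledgebase: schema + instances +
    the top-level pathways that root the event forest."""

    schema: Schema
    instances: dict[int, Instance] = field(default_factory=dict)
    top_level_pathways: list[int] = field(default_factory=list)

    def add(self, inst: Instance) -> Instance:
        if inst.db_id in self.instances:
            raise ValueError(f"duplicate db_id {inst.db_id}")
        self.instances[inst.db_id] = inst
        return inst

    def by_st_id(self, st_id: str) -> Instance | None:
        for inst in self.instances.values():
            if inst.st_id == st_id:
                return inst
        return None

    def instances_of(self, class_name: str) -> list[Instance]:
        wanted = self.schema.descendants(class_name)
        return [i for i in self.instances.values() if i.class_name in wanted]


@dataclass(frozen=True)
class Violation:
    kind: str
    db_id: int | None
    slot: str | None
    message: str


@dataclass
class ValidationReport:
    n_instances: int
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(v.kind for v in self.violations))

    def summary(self) -> str:
        lines = [f"instances checked: {self.n_instances}", f"violations: {len(self.violations)}"]
        for kind, n in sorted(self.counts.items()):
            lines.append(f"  {kind}: {n}")
        return "\n".join(lines)


def validate_instance(inst: Instance, schema: Schema, store: ObjectStore | None = None) -> list[Violation]:
    """Check one instance against the schema (and, if a store is given,
    against the referenced instances).  Violations are reported, never
    raised: an unknown class is a violation, not an exception."""
    out: list[Violation] = []
    if inst.class_name not in schema:
        out.append(Violation("unknown-class", inst.db_id, None, f"class {inst.class_name!r} not in schema"))
        return out
    if inst.db_id <= 0:
        out.append(Violation("bad-db-id", inst.db_id, None, "db_id must be positive"))
    eff = schema.effective_slots(inst.class_name)
    for slot_name, raw in inst.slot_values.items():
        slot = eff.get(slot_name)
        if slot is None:
            out.append(
                Violation("unknown-slot", inst.db_id, slot_name, f"slot {slot_name!r} not on class {inst.class_name}")
            )
            continue
        values = raw if isinstance(raw, list) else [raw]
        if slot.cardinality == "one" and len(values) > 1:
            out.append(Violation("cardinality", inst.db_id, slot_name, f"cardinality-one slot holds {len(values)} values"))
        for value in values:
            if slot.is_reference:
                if not isinstance(value, int) or isinstance(value, bool):
                    out.append(Violation("bad-reference", inst.db_id, slot_name, f"non-integer reference {value!r}"))
                elif store is not None:
                    target = store.instances.get(value)
                    if target is None:
                        out.append(Violation("dangling-reference", inst.db_id, slot_name, f"db_id {value} missing"))
                    elif not schema.is_a(target.class_name, slot.target or ""):
                        out.append(
                            Violation(
                                "reference-class-mismatch",
                                inst.db_id,
                                slot_name,
                                f"db_id {value} is {target.class_name}, expected {slot.target}",
                            )
                        )
            else:
                if not isinstance(value, _PY_KINDS[slot.value_kind]) or (
                    slot.value_kind == "number" and isinstance(value, bool)
                ):
                    out.append(
                        Violation("bad-primitive", inst.db_id, slot_name, f"{value!r} is not a {slot.value_kind}")
                    )
    return out


def validate_store(store: ObjectStore) -> ValidationReport:
    """Aggregate instance validation plus store-level checks: duplicate
    stable identifiers and the top-level-pathway class constraint.
    Side-effect free and idempotent."""
    violations: list[Violation] = []
    for inst in store.instances.values():
        violations.extend(validate_instance(inst, store.schema, store))
    st_counts = Counter(i.st_id for i in store.instances.values())
    for st_id, n in sorted(st_counts.items()):
        if n > 1:
            violations.append(Violation("duplicate-st-id", None, None, f"stId {st_id!r} used {n} times"))
    for db_id in store.top_level_pathways:
        inst = store.instances.get(db_id)
        if inst is None:
            violations.append(Violation("dangling-top-level", db_id, None, f"top-level db_id {db_id} missing"))
        elif not (inst.class_name in store.schema and store.schema.is_a(inst.class_name, "Pathway")):
            violations.append(
                Violation("top-level-not-pathway", db_id, None, f"top-level db_id {db_id} is {inst.class_name}")
            )
    return ValidationReport(n_instances=len(store.instances), violations=violations)
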