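"""Conversion between relational/object-store dumps and the property graph.

The relational layout mirrors how pathway knowledgebases are persisted in
SQL: one entity table per class (``db_id``, ``st_id``, ``display_name``,
one column per primitive slot, one foreign-key column per cardinality-one
reference slot) plus one junction table per many-valued reference slot
(``source_db_id``, ``target_db_id``, ``order_index``), named
``<class>_<slot>`` after the class that declares the slot.  Table and
column names are snake_case of the class/slot names.  A
``top_level_pathway`` table (``position``, ``db_id``) roots the event
forest, and ``schema_json`` carries the schema so a dump round-trips even
for extended schemas.

The graph conversion follows the migration discipline of production
pathway graph databases: a depth-first walk from the top-level pathways
in which every object is processed exactly once — primitive slots become
node properties, reference slots become typed edges carrying their order
index — so a shared physical entity yields one node no matter how many
references point at it.
"""

from __future__ import annotations

import json
import re
import sqlite3
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .graphstore import GraphEdge, GraphNode, PropertyGraph
from .model import Instance, ObjectStore, Schema, builtin_schema

__all__ = [
    "ImportReport",
    "ImportError_",
    "DumpFormatError",
    "import_knowledgebase",
    "read_relational_dump",
    "write_relational_dump",
    "read_json_store",
    "write_json_store",
    "reachable_instances",
]


class DumpFormatError(ValueError):
    """The relational dump does not follow the expected table layout."""


class ImportError_(ValueError):
    """A slot references a db_id absent from the store."""


def snake_case(name: str) -> str:
    return re.sub(r"(?<=[a-z0-9])(?=[A-Z])", "_", name).lower()


@dataclass
class ImportReport:
    instances_seen: int = 0
    nodes_created: int = 0
    edges_created: int = 0
    orphan_instances: list[int] = field(default_factory=list)
    per_class_nodes: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "instances_seen": self.instances_seen,
                "nodes_created": self.nodes_created,
                "edges_created": self.edges_created,
                "orphan_instances": self.orphan_instances,
                "per_class_nodes": dict(sorted(self.per_class_nodes.items())),
            },
            indent=1,
        )


def reachable_instances(store: ObjectStore) -> set[int]:
    """db_ids reachable from the top-level pathways over any reference slot."""
    seen: set[int] = set()
    stack = [i for i in store.top_level_pathways if i in store.instances]
    while stack:
        db_id = stack.pop()
        if db_id in seen:
            continue
        seen.add(db_id)
        inst = store.instances[db_id]
        for _slot, _order, target in inst.references(store.schema):
            if target in store.instances and target not in seen:
                stack.append(target)
    return seen


def _node_from_instance(inst: Instance, schema: Schema) -> GraphNode:
    props: dict[str, Any] = {"stId": inst.st_id, "displayName": inst.display_name}
    eff = schema.effective_slots(inst.class_name)
    for slot_name, raw in inst.slot_values.items():
        slot = eff.get(slot_name)
        if slot is not None and not slot.is_reference:
            props[slot_name] = raw
    return GraphNode(inst.db_id, tuple(schema.ancestors(inst.class_name)), props)


def import_knowledgebase(
    store: ObjectStore, include_orphans: bool = False
) -> tuple[PropertyGraph, ImportReport]:
    """Depth-first, visit-once conversion of a store into a property graph.

    Node labels carry the full ancestor class chain (concrete class
    first); every reference slot value becomes one typed edge with its
    order index.  A target node is always created before the edge that
    points at it, so the graph never holds a dangling edge.  Instances
    unreachable from the top-level pathways are reported as orphans and
    imported only when ``include_orphans`` is set.
    """
    schema = store.schema
    graph = PropertyGraph()
    report = ImportReport(instances_seen=len(store.instances))

    def ensure_node(db_id: int) -> None:
        if db_id in graph:
            return
        inst = store.instances[db_id]
        graph.add_node(_node_from_instance(inst, schema))
        report.nodes_created += 1
        report.per_class_nodes[inst.class_name] = report.per_class_nodes.get(inst.class_name, 0) + 1

    processed: set[int] = set()

    def walk(roots: list[int]) -> None:
        for root in roots:
            if root not in store.instances:
                raise ImportError_(f"top-level/orphan root {root} not in store")
            ensure_node(root)
        stack = list(reversed(roots))
        while stack:
            db_id = stack.pop()
            if db_id in processed:
                continue
            processed.add(db_id)
            inst = store.instances[db_id]
            to_visit: list[int] = []
            for slot_name, order, target in inst.references(schema):
                if target not in store.instances:
                    raise ImportError_(
                        f"instance {db_id} slot {slot_name!r} references missing db_id {target}"
                    )
                ensure_node(target)
                graph.add_edge(GraphEdge(db_id, target, slot_name, {"order": order}))
                report.edges_created += 1
                if target not in processed:
                    to_visit.append(target)
            stack.extend(reversed(to_visit))

    walk(list(store.top_level_pathways))
    reachable = set(processed)
    report.orphan_instances = sorted(set(store.instances) - reachable)
    if include_orphans and report.orphan_instances:
        walk(list(report.orphan_instances))
    return graph, report


# ---------------------------------------------------------------------------
# JSON object-store dump


def write_json_store(store: ObjectStore, destination) -> None:
    doc = {
        "schema": json.loads(store.schema.to_json()),
        "top_level_pathways": list(store.top_level_pathways),
        "instances": [
            {
                "db_id": i.db_id,
                "st_id": i.st_id,
                "class_name": i.class_name,
                "display_name": i.display_name,
                "slot_values": i.slot_values,
            }
            for i in sorted(store.instances.values(), key=lambda x: x.db_id)
        ],
    }
    Path(destination).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_json_store(source) -> ObjectStore:
    doc = json.loads(Path(source).read_text())
    schema = Schema.from_json(json.dumps(doc["schema"]))
    store = ObjectStore(schema=schema, top_level_pathways=list(doc["top_level_pathways"]))
    for rec in doc["instances"]:
        store.add(
            Instance(
                db_id=rec["db_id"],
                st_id=rec["st_id"],
                class_name=rec["class_name"],
                display_name=rec.get("display_name", ""),
                slot_values=dict(rec.get("slot_values", {})),
            )
        )
    return store


# ---------------------------------------------------------------------------
# Relational dump (SQLite file or CSV directory)

_MANDATORY = ("db_id", "st_id", "display_name")


def _class_frame(store: ObjectStore, class_name: str) -> pd.DataFrame:
    schema = store.schema
    eff = schema.effective_slots(class_name)
    prim_cols = [s.name for s in eff.values() if not s.is_reference and s.name not in ("stId", "displayName")]
    one_refs = [s.name for s in eff.values() if s.is_reference and s.cardinality == "one"]
    rows = []
    for inst in sorted(store.instances.values(), key=lambda i: i.db_id):
        if inst.class_name != class_name:
            continue
        row: dict[str, Any] = {"db_id": inst.db_id, "st_id": inst.st_id, "display_name": inst.display_name}
        for col in prim_cols:
            row[snake_case(col)] = inst.slot_values.get(col)
        for col in one_refs:
            row[f"{snake_case(col)}_db_id"] = inst.slot_values.get(col)
        rows.append(row)
    columns = (
        list(_MANDATORY)
        + [snake_case(c) for c in prim_cols]
        + [f"{snake_case(c)}_db_id" for c in one_refs]
    )
    return pd.DataFrame(rows, columns=columns)


def _junction_frames(store: ObjectStore) -> dict[str, pd.DataFrame]:
    """One frame per (declaring class, many-valued reference slot)."""
    schema = store.schema
    frames: dict[str, list[dict]] = {}
    slot_owner: dict[str, str] = {}  # slot name -> declaring class
    for cls_name in schema:
        for slot in schema[cls_name].slots:
            if slot.is_reference and slot.cardinality == "many":
                slot_owner[slot.name] = cls_name
                frames[f"{snake_case(cls_name)}_{snake_case(slot.name)}"] = []
    for inst in sorted(store.instances.values(), key=lambda i: i.db_id):
        eff = schema.effective_slots(inst.class_name)
        for slot_name, order, target in inst.references(schema):
            slot = eff[slot_name]
            if slot.cardinality != "many":
                continue
            table = f"{snake_case(slot_owner[slot_name])}_{snake_case(slot_name)}"
            frames[table].append(
                {"source_db_id": inst.db_id, "target_db_id": target, "order_index": order}
            )
    return {
        name: pd.DataFrame(rows, columns=["source_db_id", "target_db_id", "order_index"])
        for name, rows in frames.items()
    }


def write_relational_dump(store: ObjectStore, destination) -> None:
    """Emit the table layout :func:`read_relational_dump` accepts.

    ``destination`` ending in ``.sqlite`` / ``.db`` / ``.sqlite3`` writes
    a SQLite file; anything else is treated as a CSV directory.
    """
    destination = Path(destination)
    tables: dict[str, pd.DataFrame] = {}
    for cls_name in store.schema:
        tables[snake_case(cls_name)] = _class_frame(store, cls_name)
    tables.update(_junction_frames(store))
    tables["top_level_pathway"] = pd.DataFrame(
        [{"position": i, "db_id": d} for i, d in enumerate(store.top_level_pathways)],
        columns=["position", "db_id"],
    )
    schema_json = store.schema.to_json()
    if destination.suffix in (".sqlite", ".db", ".sqlite3"):
        if destination.exists():
            destination.unlink()
        with sqlite3.connect(destination) as conn:
            for name, frame in tables.items():
                frame.to_sql(name, conn, index=False)
            conn.execute("CREATE TABLE schema_json (doc TEXT)")
            conn.execute("INSERT INTO schema_json VALUES (?)", (schema_json,))
    else:
        destination.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(destination / f"{name}.csv", index=False)
        (destination / "schema.json").write_text(schema_json)


def _clean(value: Any) -> Any:
    """Normalize pandas cell values to plain Python (None for NA)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if pd.api.types.is_integer(value):
        return int(value)
    if isinstance(value, float):
        return value
    return value


def _read_tables(source: Path) -> tuple[dict[str, pd.DataFrame], Schema]:
    if source.is_dir():
        tables = {
            p.stem: pd.read_csv(p, dtype={"st_id": str, "display_name": str})
            for p in sorted(source.glob("*.csv"))
        }
        schema_path = source / "schema.json"
        schema = Schema.from_json(schema_path.read_text()) if schema_path.exists() else builtin_schema()
    elif source.is_file():
        with sqlite3.connect(source) as conn:
            names = [
                r[0]
                for r in conn.execute("SELECT name FROM sqlite_master WHERE type='table'").fetchall()
            ]
            tables = {
                n: pd.read_sql_query(f'SELECT * FROM "{n}"', conn) for n in names if n != "schema_json"
            }
            if "schema_json" in names:
                schema = Schema.from_json(conn.execute("SELECT doc FROM schema_json").fetchone()[0])
            else:
                schema = builtin_schema()
    else:
        raise DumpFormatError(f"no such dump: {source}")
    return tables, schema


def read_relational_dump(source) -> ObjectStore:
    """Load a SQLite file or CSV directory into an :class:`ObjectStore`.

    Foreign keys to absent rows are kept as slot values so that
    :func:`pathkb.model.validate_store` surfaces them as dangling
    references rather than raising here.
    """
    source = Path(source)
    tables, schema = _read_tables(source)
    store = ObjectStore(schema=schema)

    class_by_table = {snake_case(name): name for name in schema}
    junction: dict[str, tuple[str, str]] = {}  # table name -> (class, slot)
    for cls_name in schema:
        for slot in schema[cls_name].slots:
            if slot.is_reference and slot.cardinality == "many":
                junction[f"{snake_case(cls_name)}_{snake_case(slot.name)}"] = (cls_name, slot.name)

    for table_name, frame in tables.items():
        cls_name = class_by_table.get(table_name)
        if cls_name is None:
            continue
        missing = [c for c in _MANDATORY if c not in frame.columns]
        if missing:
            raise DumpFormatError(f"table {table_name}: missing mandatory columns {missing}")
        eff = schema.effective_slots(cls_name)
        prim_by_col = {
            snake_case(s.name): s.name
            for s in eff.values()
            if not s.is_reference and s.name not in ("stId", "displayName")
        }
        ref_by_col = {
            f"{snake_case(s.name)}_db_id": s.name
            for s in eff.values()
            if s.is_reference and s.cardinality == "one"
        }
        for rec in frame.to_dict("records"):
            slot_values: dict[str, Any] = {}
            for col, slot_name in prim_by_col.items():
                value = _clean(rec.get(col))
                if value is not None:
                    slot_values[slot_name] = value
            for col, slot_name in ref_by_col.items():
                value = _clean(rec.get(col))
                if value is not None:
                    slot_values[slot_name] = int(value)
            store.add(
                Instance(
                    db_id=int(rec["db_id"]),
                    st_id=str(rec["st_id"]),
                    class_name=cls_name,
                    display_name="" if _clean(rec.get("display_name")) is None else str(rec["display_name"]),
                    slot_values=slot_values,
                )
            )

    for table_name, (cls_name, slot_name) in junction.items():
        frame = tables.get(table_name)
        if frame is None:
            continue
        for col in ("source_db_id", "target_db_id", "order_index"):
            if col not in frame.columns:
                raise DumpFormatError(f"junction table {table_name}: missing column {col}")
        frame = frame.sort_values(["source_db_id", "order_index"])
        for rec in frame.to_dict("records"):
            src = store.instances.get(int(rec["source_db_id"]))
            if src is None:
                continue  # dangling source row; validation will not see it, the slot is simply absent
            src.slot_values.setdefault(slot_name, []).append(int(rec["target_db_id"]))

    if "top_level_pathway" in tables:
        frame = tables["top_level_pathway"]
        if "db_id" not in frame.columns:
            raise DumpFormatError("top_level_pathway: missing column db_id")
        if "position" in frame.columns:
            frame = frame.sort_values("position")
        store.top_level_pathways = [int(r["db_id"]) for r in frame.to_dict("records")]
    return store
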