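"""Stress-test harness: join-style relational access vs graph traversal.

Two retrieval backends answer the same requests — marshalling a full
reaction object and listing a reaction's inputs/outputs — one by SQL
joins over the relational dump, the other by traversing the property
graph.  Two scenarios mirror the classic comparison design: a single
user querying n distinct reactions sequentially (each object queried at
most once, so caching gives no backend an advantage) and an increasing
number of concurrent users sharing the same workload.

Latency and throughput are *reported*, never asserted against
thresholds: absolute timings are hardware-bound.  What the harness does
guarantee, and what the tests check, is that both backends and all
concurrency levels return identical marshalled objects.
"""

from __future__ import annotations

import random
import resource
import sqlite3
import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean, stdev
from typing import Any, Sequence

from .graphstore import PropertyGraph
from .importer import snake_case
from .model import Schema, builtin_schema
from . import query

__all__ = ["BenchResult", "GraphBackend", "RelationalBackend", "run_sequential", "run_concurrent", "workload"]


@dataclass
class BenchResult:
    """Latency/throughput record for one scenario execution."""

    backend: str
    scenario: str  # "sequential" | "concurrent"
    n_queries: int
    n_workers: int
    latencies: list[float]  # seconds, one per query
    elapsed: float  # wall-clock seconds for the whole run
    memory_rss_kb: int = 0

    @property
    def mean_latency_ms(self) -> float:
        return fmean(self.latencies) * 1000.0 if self.latencies else 0.0

    @property
    def sd_latency_ms(self) -> float:
        return stdev(self.latencies) * 1000.0 if len(self.latencies) > 1 else 0.0

    @property
    def tps(self) -> float:
        return self.n_queries / self.elapsed if self.elapsed > 0 else 0.0

    def validate(self) -> None:
        assert self.n_queries == len(self.latencies)

    def to_row(self) -> dict[str, Any]:
        """Plot-ready long-format record."""
        return {
            "backend": self.backend,
            "scenario": self.scenario,
            "n_queries": self.n_queries,
            "n_workers": self.n_workers,
            "mean_latency_ms": self.mean_latency_ms,
            "sd_latency_ms": self.sd_latency_ms,
            "tps": self.tps,
            "elapsed_s": self.elapsed,
            "memory_rss_kb": self.memory_rss_kb,
        }


class GraphBackend:
    """Answers requests by traversing a :class:`PropertyGraph`."""

    label = "graph"

    def __init__(self, graph: PropertyGraph) -> None:
        self.graph = graph

    def get_reaction(self, db_id: int) -> dict:
        return query.fetch(self.graph, db_id, depth="full").to_plain()

    def reaction_io(self, db_id: int) -> tuple[list[int], list[int]]:
        return query.reaction_io(self.graph, db_id)

    def reaction_ids(self) -> list[int]:
        return sorted(n.node_id for n in self.graph.find("label", "ReactionLikeEvent"))


class RelationalBackend:
    """Answers requests with SQL over the relational SQLite dump.

    Marshalling a reaction issues one SELECT per object row plus one per
    junction table touched — the join-heavy access pattern that graph
    storage is meant to replace.  Connections are per-thread, so
    concurrent read access is safe.
    """

    label = "relational"

    def __init__(self, sqlite_path, schema: Schema | None = None) -> None:
        self.path = str(Path(sqlite_path))
        self.schema = schema or self._load_schema()
        self._local = threading.local()
        self._class_of: dict[int, str] = {}
        self._load_id_index()

    def _connect(self) -> sqlite3.Connection:
        conn = getattr(self._local, "conn", None)
        if conn is None:
            conn = sqlite3.connect(self.path)
            conn.row_factory = sqlite3.Row
            self._local.conn = conn
        return conn

    def _load_schema(self) -> Schema:
        with sqlite3.connect(self.path) as conn:
            row = conn.execute("SELECT doc FROM schema_json").fetchone()
        return Schema.from_json(row[0]) if row else builtin_schema()

    def _load_id_index(self) -> None:
        conn = self._connect()
        for cls_name in self.schema:
            table = snake_case(cls_name)
            try:
                rows = conn.execute(f'SELECT db_id FROM "{table}"').fetchall()
            except sqlite3.OperationalError:
                continue
            for row in rows:
                self._class_of[int(row["db_id"])] = cls_name

    def reaction_ids(self) -> list[int]:
        rle_classes = self.schema.descendants("ReactionLikeEvent")
        return sorted(i for i, c in self._class_of.items() if c in rle_classes)

    def _junction_values(self, conn, cls_name: str, slot_name: str, db_id: int) -> list[int]:
        # the junction table lives under the class that declares the slot
        owner = None
        for ancestor in self.schema.ancestors(cls_name):
            if any(s.name == slot_name for s in self.schema[ancestor].slots):
                owner = ancestor
        table = f"{snake_case(owner)}_{snake_case(slot_name)}"
        rows = conn.execute(
            f'SELECT target_db_id FROM "{table}" WHERE source_db_id=? ORDER BY order_index',
            (db_id,),
        ).fetchall()
        return [int(r["target_db_id"]) for r in rows]

    def reaction_io(self, db_id: int) -> tuple[list[int], list[int]]:
        """Input/output retrieval as a join over junction + entity tables."""
        conn = self._connect()
        cls_name = self._class_of[db_id]
        out: list[list[int]] = []
        for slot in ("input", "output"):
            owner = None
            for ancestor in self.schema.ancestors(cls_name):
                if any(s.name == slot for s in self.schema[ancestor].slots):
                    owner = ancestor
            junction = f"{snake_case(owner)}_{snake_case(slot)}"
            # join against every PE table to mirror the entity lookup cost
            pe_tables = sorted(snake_case(c) for c in self.schema.descendants("PhysicalEntity")
                               if c != "PhysicalEntity")
            union = " UNION ALL ".join(f'SELECT db_id FROM "{t}"' for t in pe_tables)
            rows = conn.execute(
                f'SELECT j.target_db_id AS t FROM "{junction}" j '
                f"JOIN ({union}) pe ON pe.db_id = j.target_db_id "
                f"WHERE j.source_db_id=? ORDER BY j.order_index",
                (db_id,),
            ).fetchall()
            out.append([int(r["t"]) for r in rows])
        return out[0], out[1]

    def get_reaction(self, db_id: int) -> dict:
        return self._marshal(self._connect(), db_id, ())

    def _marshal(self, conn, db_id: int, path: tuple[int, ...]) -> dict:
        cls_name = self._class_of[db_id]
        eff = self.schema.effective_slots(cls_name)
        row = conn.execute(
            f'SELECT * FROM "{snake_case(cls_name)}" WHERE db_id=?', (db_id,)
        ).fetchone()
        props: dict[str, Any] = {"stId": row["st_id"], "displayName": row["display_name"] or ""}
        new_path = path + (db_id,)
        refs: dict[str, list] = {}
        for slot_name, slot in eff.items():
            if not slot.is_reference:
                if slot_name in ("stId", "displayName"):
                    continue
                value = row[snake_case(slot_name)] if snake_case(slot_name) in row.keys() else None
                if value is not None:
                    props[slot_name] = value
                continue
            if slot.cardinality == "one":
                col = f"{snake_case(slot_name)}_db_id"
                value = row[col] if col in row.keys() else None
                targets = [int(value)] if value is not None else []
            else:
                targets = self._junction_values(conn, cls_name, slot_name, db_id)
            if not targets:
                continue
            refs[slot_name] = [
                {"ref": t} if t in new_path else self._marshal(conn, t, new_path) for t in targets
            ]
        return {
            "dbId": db_id,
            "labels": list(self.schema.ancestors(cls_name)),
            "properties": dict(sorted(props.items())),
            "refs": {k: refs[k] for k in sorted(refs)},
        }


def workload(reaction_ids: Sequence[int], n: int, seed: int = 0) -> list[int]:
    """A fixed sequence of n distinct reaction ids: each object is
    queried exactly once, so caching cannot help either backend."""
    ids = sorted(set(reaction_ids))
    if len(ids) < n:
        raise ValueError(f"need {n} distinct reactions, have {len(ids)}")
    return random.Random(seed).sample(ids, n)


def _rss_kb() -> int:
    return int(resource.getrusage(resource.RUSAGE_SELF).ru_maxrss)


def run_sequential(
    backend,
    reaction_ids: Sequence[int],
    n: int,
    seed: int = 0,
    collect_results: bool = False,
) -> BenchResult | tuple[BenchResult, dict[int, dict]]:
    """One user querying n distinct reactions in a fixed sequence,
    marshalling each full reaction object."""
    sequence = workload(reaction_ids, n, seed)
    latencies: list[float] = []
    results: dict[int, dict] = {}
    t0 = time.perf_counter()
    for rid in sequence:
        q0 = time.perf_counter()
        obj = backend.get_reaction(rid)
        latencies.append(time.perf_counter() - q0)
        if collect_results:
            results[rid] = obj
    elapsed = time.perf_counter() - t0
    result = BenchResult(backend.label, "sequential", n, 1, latencies, elapsed, _rss_kb())
    return (result, results) if collect_results else result


def run_concurrent(
    backend,
    reaction_ids: Sequence[int],
    n_queries: int,
    workers: Sequence[int] = (1, 2, 4, 8),
    seed: int = 0,
    collect_results: bool = False,
):
    """The sequential workload shared among an increasing number of
    concurrent users; the workload is partitioned without repeats.

    Returns one :class:`BenchResult` per worker count (and, when
    ``collect_results``, one ``{id: object}`` dict per worker count).
    """
    sequence = workload(reaction_ids, n_queries, seed)
    out: list[BenchResult] = []
    collected: list[dict[int, dict]] = []
    for k in workers:
        shares = [sequence[i::k] for i in range(k)]
        latencies_per: list[list[float]] = [[] for _ in range(k)]
        results: dict[int, dict] = {}
        lock = threading.Lock()

        def work(idx: int) -> None:
            for rid in shares[idx]:
                q0 = time.perf_counter()
                obj = backend.get_reaction(rid)
                dt = time.perf_counter() - q0
                latencies_per[idx].append(dt)
                if collect_results:
                    with lock:
                        results[rid] = obj

        t0 = time.perf_counter()
        with ThreadPoolExecutor(max_workers=k) as pool:
            list(pool.map(work, range(k)))
        elapsed = time.perf_counter() - t0
        latencies = [dt for per in latencies_per for dt in per]
        out.append(BenchResult(backend.label, "concurrent", n_queries, k, latencies, elapsed, _rss_kb()))
        if collect_results:
            collected.append(results)
    return (out, collected) if collect_results else out
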