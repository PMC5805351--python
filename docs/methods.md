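# Methods

## The data model

`pathkb` models a curated pathway knowledgebase as a frame system: a
single-rooted tree of classes, each with typed slots. The built-in
schema fixes the minimal core needed by every supported query:

- `DatabaseObject` (root): `displayName`, `stId`, `speciesName`
  (primitives).
- `Event → Pathway` with `hasEvent` (many, ordered, → Event) and
  `Event → ReactionLikeEvent` with `input`/`output` (many, ordered,
  → PhysicalEntity), `catalystActivity` (→ CatalystActivity),
  `precedingEvent` (→ Event), `regulatedBy` (→ Regulation).
  `ReactionLikeEvent` subclasses `Reaction`, `FailedReaction`,
  `Polymerisation`, `Depolymerisation`, `BlackBoxEvent` add no slots;
  all are handled identically through inheritance.
- `PhysicalEntity → {SimpleEntity, EntityWithAccessionedSequence,
  Complex (hasComponent, ordered), EntitySet (hasMember, hasCandidate)}`.
- Catalysis and regulation go through the intermediate
  `CatalystActivity.physicalEntity` and `Regulation.regulator`
  (cardinality one) rather than direct entity edges, mirroring how
  curated resources attach evidence to those relationships.

Real production schemas run to ~90 classes; the core here is
deliberately minimal but runtime-extensible (new classes/slots may be
registered; built-ins cannot be replaced, and a child class cannot
shadow an inherited slot). Stable identifiers are opaque unique strings
— no checksum semantics.

## Migration

The importer walks depth-first from the top-level pathways with an
explicit stack (no recursion limit) and a visit-once set keyed on
`db_id`. On first visit an instance becomes one node whose labels are
its ancestor class chain (concrete class first) and whose properties are
exactly its primitive slot values plus `stId`/`displayName`; each
reference slot value becomes one typed edge carrying its `order` index.
A target node is always created before any edge pointing at it, so the
graph holds no dangling edge at any intermediate point. Revisited
instances contribute edges only. Repeated stoichiometry is represented
as repeated ordered edges (same source/type/target at distinct orders);
consumers wanting a counter can aggregate the `order` multiplicity.

Instances unreachable from the top-level pathways ("orphans") are
excluded by default but recorded in the import report, and importable
with a flag — silent loss would otherwise be invisible. Reachability is
defined solely from the top-level pathways, so instances referenced only
by orphans are orphans too.

The relational dialect is snake_case: one table per class (`db_id`,
`st_id`, `display_name`, one column per primitive slot, one
`<slot>_db_id` column per cardinality-one reference slot), one junction
table `<declaring_class>_<slot>` per many-valued slot (`source_db_id`,
`target_db_id`, `order_index`), a `top_level_pathway` table with an
explicit `position`, and the schema itself embedded as JSON so extended
schemas round-trip.

## Queries

All traversals are breadth-first with a visited set (a node's depth is
its minimum depth), so they terminate on cyclic input; node sets are
returned sorted by `db_id` and chains by (length, id sequence) — a
deterministic order in place of any storage-dependent "natural" one.
Results are functions of graph content only: importing a permuted store
yields identical answers.

Decisions where the ecosystem's behaviour was genuinely open:

- *Participants.* "Participating molecules" of a pathway includes
  inputs, outputs, catalyst physical entities and regulators by default;
  flags allow each narrower reading. Participants are reported either as
  the stated entities (`decompose=False`) or expanded to leaf molecules
  with role/reaction provenance merged per leaf (`decompose=True`, the
  CLI default — "molecules" means leaves).
- *Candidates.* `EntitySet.hasCandidate` members are uncertain members;
  they are excluded from decomposition by default and includable by
  flag. A leaf is a node with no outgoing composition edge *of the
  traversed kinds*, so a set holding only candidates is itself a leaf
  when candidates are excluded.
- *Entity-to-pathways.* `pathways_for_entity` is specified as the exact
  inverse image of `pathway_participants` and implemented by upward
  traversal: composition edges inward (when `leaf_match`), then the four
  role attachments inward, then `hasEvent` closure inward. Because
  decomposed participant lists contain only leaves, a non-leaf entity
  has no leaf matches by definition; the upward implementation enforces
  the same guard so the two directions stay duals.
- *Reaction chains.* The linkage between consecutive reactions is not
  uniquely determined by the use case ("chains of consecutive reactions
  leading to a complex"); the default links rᵢ → rᵢ₊₁ when an output of
  rᵢ is an input of rᵢ₊₁, with explicit `precedingEvent` edges available
  as an alternative mode. Chains are acyclic (no repeated reaction), and
  every suffix of a chain is itself a chain.
- *Ancestors.* `event_ancestors` climbs `hasEvent` inward; on (corrupt
  or adversarial) cyclic hierarchies a chain ends when no off-path
  parent remains, which keeps the operation total and deterministic.
- *Lazy loading.* `fetch` returns an object view at `shallow`, bounded-n
  or `full` depth; unresolved references are placeholders that resolve
  on demand to exactly what eager retrieval would have produced. Cycles
  are cut path-locally with permanent placeholders, which makes the
  bounded view a strict truncation of the full view.

## Integrity verification

`verify_all` runs the three content checks — top-level pathway count,
ancestor chains per pathway, complex/set content (compared both as leaf
molecules with candidates excluded *and* included, and as direct
children) — each computed independently on the graph (traversal) and on
the store (brute-force slot enumeration in `pathkb.oracles`). A
conservation check compares the graph's node-id set and the full
(source, type, target, order) edge multiset against the store's
reference slot values; multisets rather than bare counts, because a
count comparison cannot detect a retargeted edge. Orphans excluded by
the import flag are reported, not failed. With `sample=n` the per-object
checks run on a seeded deterministic sample; conservation always runs in
full.

## The synthetic generator

`synthdata.generate` emulates the structure such a knowledgebase
actually has, not its biology: a forest of pathways (depth ≤
`max_pathway_depth`, default 3; 0–2 subpathways per level;
`reactions_per_pathway` default 2–5) over a pool of proteins (default
40) and chemicals (default 15); entity sets (`set_fraction` 0.15,
2–4 members, half the sets get one candidate member) and nested
complexes (`complex_fraction` 0.25, 2–4 children, nesting ≤
`max_complex_nesting` = 3) built as DAGs — containment cycles are
biologically impossible and would make "leaf molecule" undefined.
Reactions take 1–3 inputs and outputs; entity reuse across reactions is
driven by `shared_entity_probability` (0.3) to exercise visit-once
deduplication; catalysts (p = 0.3) and regulators (p = 0.2) attach via
their intermediate objects. `precedingEvent` links consecutive reactions
(p = 0.5) and, with `cycle_probability` (0.1), closes a feedback loop —
the one place the domain admits cycles. Entities left unused after
pathway construction are attached to random reactions so that
orphanhood is always deliberate: `orphan_count` extra unreferenced
proteins, exactly.

Ground truth (reachable/orphan partition, per-entity decompositions for
both candidate flags, per-event ancestor chains, per-pathway participant
tables for all eight flag combinations) is computed during construction
by bottom-up bookkeeping over the slot structures just built — never by
the importer, graph or query engine — and is cross-checked in tests
against a second, independently coded brute-force route
(`pathkb.oracles`). What the generator does *not* emulate: kinetics,
species projection, literature references, realistic naming, and
events shared between pathways (each generated event has one parent, so
ancestor chains are unique; the diamond case is covered by hand-built
fixtures). Passing tests therefore demonstrate structural correctness
of migration and queries, not biological fidelity.

Everything is driven by one `random.Random(seed)`: identical config ⇒
byte-identical dumps.

## Benchmark design

Two backends answer identical requests: the graph backend traverses the
property graph; the relational backend issues SQL against the SQLite
dump (per-row SELECTs plus junction-table joins — the access pattern
graph storage replaces). The workload is a seeded sample of *n* distinct
reactions, each marshalled as a full object (path-local cycle cutting),
queried once so caching cannot favour either side; the concurrent
scenario partitions the same workload over 1–8 threads (thread-local
SQLite connections; the graph is read-only). Scale is desk-sized by
design: 500 sequential queries and 1–8 workers. Reports carry per-query
latencies, mean ± sd, TPS, wall-clock and process RSS (memory parity is
recorded, not enforced). Correctness is the contract — both backends and
all concurrency levels must return identical objects; latency and
throughput are reported only, since absolute timings are
hardware-bound.

## Numerical and testing choices

- Determinism everywhere: seeded RNGs, sorted iteration, canonical
  export ordering; no tolerance parameters exist — every comparison in
  the package is exact (sets, multisets, ordered lists).
- Edge identity is (source, type, target, order); within one
  (source, type) the importer produces orders 0..k−1 with no gaps.
  `stId` index lookups return the lowest node id if duplicates are ever
  injected by hand.
- GraphML typing: per-key attribute types are inferred from values
  (boolean/long/double/string); labels serialize as a `|`-joined string.
- Test sizes: twenty seeded knowledgebases of 100–500 instances across
  four structural variants; the benchmark knowledgebase is larger
  (~1,000 instances, ≥500 reactions) so the sequential scenario can use
  500 distinct queries. The full suite runs in well under a minute.

## Known limitations

- The relational reader trusts the embedded schema JSON; junction rows
  whose source row is missing are silently dropped (the slot is simply
  absent) rather than surfaced as dangling-source violations.
- `pathways_for_entity(leaf_match=True)` returns the empty set for
  non-leaf entities by definition of the inverse image; callers wanting
  "pathways using this complex anywhere" should use `leaf_match=False`.
- The store's `st_id` lookup is a linear scan (stores are small); the
  graph maintains a proper index.
- No transactions, no concurrency control on writes, no incremental
  re-import between releases; a service/REST layer is an extension
  point, not shipped.
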