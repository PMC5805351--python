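"""Synthetic pathway knowledgebases with machine-readable ground truth.

The generator emulates the structure of a curated pathway resource: a
forest of pathways containing reaction-like events whose participants
are physical entities — proteins and chemicals, nested complexes and
entity sets over them — plus catalyst and regulation objects, optional
feedback cycles on ``precedingEvent``, and deliberately unreachable
orphan instances.  Composition structures are DAGs (a complex can never
contain itself); cycles are only ever injected into ``precedingEvent``,
where biological feedback makes them meaningful.

Alongside the store, :func:`generate` emits a :class:`GroundTruth`
computed bottom-up during construction — participant sets per flag
combination, entity decompositions, ancestor chains, the
reachable/orphan partition — so tests can judge the importer and query
engine against answers the modules under test never produced.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from itertools import product

from .model import Instance, ObjectStore, builtin_schema

__all__ = ["SynthConfig", "GroundTruth", "ConfigError", "generate", "worked_toy"]

FlagCombo = tuple[bool, bool, bool]  # (include_catalysts, include_regulators, decompose)


class ConfigError(ValueError):
    """The generator configuration is inconsistent or infeasible."""


@dataclass(frozen=True)
class SynthConfig:
    """Knob set for one synthetic knowledgebase.

    Defaults give a mid-sized knowledgebase (~120 instances) with the
    structural features the migration must survive: shared entities,
    nested complexes, entity sets with candidate members, catalysts,
    regulators and precedingEvent feedback.
    """

    seed: int = 0
    n_top_pathways: int = 3
    max_pathway_depth: int = 3
    reactions_per_pathway: tuple[int, int] = (2, 5)
    n_proteins: int = 40
    n_chemicals: int = 15
    complex_fraction: float = 0.25
    max_complex_nesting: int = 3
    set_fraction: float = 0.15
    members_per_set: tuple[int, int] = (2, 4)
    catalyst_probability: float = 0.3
    regulator_probability: float = 0.2
    shared_entity_probability: float = 0.3
    cycle_probability: float = 0.1
    orphan_count: int = 0

    def validate(self) -> None:
        counts = (
            self.n_top_pathways, self.max_pathway_depth, self.n_proteins,
            self.n_chemicals, self.max_complex_nesting, self.orphan_count,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("counts must be non-negative")
        probs = (
            self.complex_fraction, self.set_fraction, self.catalyst_probability,
            self.regulator_probability, self.shared_entity_probability, self.cycle_probability,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("probabilities/fractions must lie in [0, 1]")
        if self.reactions_per_pathway[0] > self.reactions_per_pathway[1] or self.reactions_per_pathway[0] < 0:
            raise ConfigError("bad reactions_per_pathway range")
        if self.members_per_set[0] > self.members_per_set[1] or self.members_per_set[0] < 1:
            raise ConfigError("bad members_per_set range")
        n_molecules = self.n_proteins + self.n_chemicals
        if n_molecules == 0 and self.n_top_pathways > 0:
            raise ConfigError("reactions need at least one molecule")
        if (self.complex_fraction > 0 or self.set_fraction > 0) and n_molecules == 0:
            raise ConfigError("complexes/sets need molecules to build on")


@dataclass
class GroundTruth:
    """Known-correct answers recorded while the store was constructed."""

    reachable: set[int] = field(default_factory=set)
    orphans: set[int] = field(default_factory=set)
    # entity -> {False/True (include_candidates): leaf set}
    decompositions: dict[int, dict[bool, set[int]]] = field(default_factory=dict)
    # event -> root-first ancestor chains
    ancestor_chains: dict[int, list[list[int]]] = field(default_factory=dict)
    # pathway -> (cat, reg, dec) -> entity -> {"roles", "via"}
    participants: dict[int, dict[FlagCombo, dict[int, dict[str, set]]]] = field(default_factory=dict)


class _Builder:
    def __init__(self, seed: int) -> None:
        self.rng = random.Random(seed)
        self.schema = builtin_schema()
        self.store = ObjectStore(schema=self.schema)
        self._next = 1

    def new(self, class_name: str, display_name: str, **slots) -> Instance:
        db_id = self._next
        self._next += 1
        inst = Instance(
            db_id=db_id,
            st_id=f"R-SYN-{db_id:06d}",
            class_name=class_name,
            display_name=display_name,
            slot_values={k: v for k, v in slots.items() if v not in (None, [], {})},
        )
        return self.store.add(inst)


def _many(inst: Instance, slot: str) -> list[int]:
    raw = inst.slot_values.get(slot, [])
    return list(raw) if isinstance(raw, list) else [raw]


def _compute_ground_truth(store: ObjectStore) -> GroundTruth:
    """Bottom-up bookkeeping over the freshly built store.

    Memoized post-order recursions over the slot structures the builder
    just wrote — not the importer, graph or query engine.
    """
    gt = GroundTruth()
    schema = store.schema

    # reachable / orphans
    stack = list(store.top_level_pathways)
    while stack:
        db_id = stack.pop()
        if db_id in gt.reachable:
            continue
        gt.reachable.add(db_id)
        for _s, _o, target in store.instances[db_id].references(schema):
            stack.append(target)
    gt.orphans = set(store.instances) - gt.reachable

    # decompositions, bottom-up with memoization (composition is a DAG)
    pes = [i for i in store.instances.values() if schema.is_a(i.class_name, "PhysicalEntity")]
    for include_candidates in (False, True):
        memo: dict[int, set[int]] = {}

        def leaves(db_id: int) -> set[int]:
            if db_id in memo:
                return memo[db_id]
            inst = store.instances[db_id]
            slots = ["hasComponent", "hasMember"] + (["hasCandidate"] if include_candidates else [])
            kids = [c for s in slots for c in _many(inst, s)]
            result = {db_id} if not kids else set().union(*(leaves(k) for k in kids))
            memo[db_id] = result
            return result

        for pe in pes:
            gt.decompositions.setdefault(pe.db_id, {})[include_candidates] = leaves(pe.db_id)

    # ancestor chains over the event forest (events have a unique parent
    # by construction, so each chain is the unique path from its root)
    parent: dict[int, int] = {}
    for inst in store.instances.values():
        for child in _many(inst, "hasEvent"):
            parent[child] = inst.db_id
    for inst in store.instances.values():
        if not schema.is_a(inst.class_name, "Event"):
            continue
        chain = [inst.db_id]
        while chain[0] in parent:
            chain.insert(0, parent[chain[0]])
        gt.ancestor_chains[inst.db_id] = [chain]

    # participants per pathway and flag combination
    def subtree_rles(pid: int) -> list[int]:
        out: list[int] = []
        for child in _many(store.instances[pid], "hasEvent"):
            if schema.is_a(store.instances[child].class_name, "Pathway"):
                out.extend(subtree_rles(child))
            else:
                out.append(child)
        return out

    for inst in store.instances.values():
        if not schema.is_a(inst.class_name, "Pathway"):
            continue
        combos: dict[FlagCombo, dict[int, dict[str, set]]] = {}
        rles = subtree_rles(inst.db_id)
        for cat, reg, dec in product((False, True), repeat=3):
            table: dict[int, dict[str, set]] = {}

            def record(entity: int, role: str, rxn: int) -> None:
                targets = gt.decompositions[entity][False] if dec else {entity}
                for t in targets:
                    rec = table.setdefault(t, {"roles": set(), "via": set()})
                    rec["roles"].add(role)
                    rec["via"].add(rxn)

            for rid in rles:
                r = store.instances[rid]
                for e in _many(r, "input"):
                    record(e, "input", rid)
                for e in _many(r, "output"):
                    record(e, "output", rid)
                if cat:
                    for ca in _many(r, "catalystActivity"):
                        record(store.instances[ca].slot_values["physicalEntity"], "catalyst", rid)
                if reg:
                    for rg in _many(r, "regulatedBy"):
                        record(store.instances[rg].slot_values["regulator"], "regulator", rid)
            combos[(cat, reg, dec)] = table
        gt.participants[inst.db_id] = combos
    return gt


def generate(config: SynthConfig) -> tuple[ObjectStore, GroundTruth]:
    """Build one synthetic knowledgebase.  Deterministic in the config
    (the seed is part of it): the same config yields a byte-identical
    store dump."""
    config.validate()
    b = _Builder(config.seed)
    rng = b.rng

    proteins = [b.new("EntityWithAccessionedSequence", f"protein {i + 1}", speciesName="Synthetic organism")
                for i in range(config.n_proteins)]
    chemicals = [b.new("SimpleEntity", f"chemical {i + 1}") for i in range(config.n_chemicals)]
    molecules = proteins + chemicals

    sets_: list[Instance] = []
    n_sets = round(config.set_fraction * len(molecules))
    for i in range(n_sets):
        k = rng.randint(*config.members_per_set)
        members = rng.sample(molecules, min(k, len(molecules)))
        candidates = rng.sample(molecules, 1) if rng.random() < 0.5 else []
        sets_.append(b.new("EntitySet", f"set {i + 1}",
                           hasMember=[m.db_id for m in members],
                           hasCandidate=[c.db_id for c in candidates]))

    depth = {m.db_id: 0 for m in molecules}
    for s in sets_:
        depth[s.db_id] = 1
    complexes: list[Instance] = []
    n_complexes = round(config.complex_fraction * len(molecules))
    for i in range(n_complexes):
        pool = [e for e in molecules + sets_ + complexes if depth[e.db_id] < config.max_complex_nesting]
        k = min(rng.randint(2, 4), len(pool))
        children = rng.sample(pool, k)
        cx = b.new("Complex", f"complex {i + 1}", hasComponent=[c.db_id for c in children])
        depth[cx.db_id] = 1 + max(depth[c.db_id] for c in children)
        complexes.append(cx)

    entities = molecules + sets_ + complexes
    used: list[Instance] = []
    unused = list(entities)

    def pick_entity() -> Instance:
        if used and (not unused or rng.random() < config.shared_entity_probability):
            choice = rng.choice(used)
        else:
            choice = unused[rng.randrange(len(unused))]
        if choice in unused:
            unused.remove(choice)
            used.append(choice)
        return choice

    all_reactions: list[Instance] = []
    pathway_counter = [0]

    def build_pathway(depth_left: int) -> Instance:
        pathway_counter[0] += 1
        name = f"pathway {pathway_counter[0]}"
        subs = [build_pathway(depth_left - 1) for _ in range(rng.randint(0, 2))] if depth_left > 1 else []
        n_rxn = rng.randint(*config.reactions_per_pathway)
        if not subs and n_rxn == 0:
            n_rxn = 1
        reactions: list[Instance] = []
        for _ in range(n_rxn):
            inputs = [pick_entity().db_id for _ in range(rng.randint(1, 3))]
            outputs = [pick_entity().db_id for _ in range(rng.randint(1, 3))]
            slots: dict = {"input": inputs, "output": outputs}
            if rng.random() < config.catalyst_probability:
                ca = b.new("CatalystActivity", "catalysis", physicalEntity=pick_entity().db_id)
                slots["catalystActivity"] = [ca.db_id]
            if rng.random() < config.regulator_probability:
                rg = b.new("Regulation", "regulation", regulator=pick_entity().db_id)
                slots["regulatedBy"] = [rg.db_id]
            reactions.append(b.new("Reaction", f"reaction {len(all_reactions) + len(reactions) + 1}", **slots))
        for prev, cur in zip(reactions, reactions[1:]):
            if rng.random() < 0.5:
                cur.slot_values.setdefault("precedingEvent", []).append(prev.db_id)
        if len(reactions) >= 2 and rng.random() < config.cycle_probability:
            reactions[0].slot_values.setdefault("precedingEvent", []).append(reactions[-1].db_id)
        all_reactions.extend(reactions)
        return b.new("Pathway", name, hasEvent=[e.db_id for e in subs + reactions])

    tops = [build_pathway(config.max_pathway_depth) for _ in range(config.n_top_pathways)]
    b.store.top_level_pathways = [t.db_id for t in tops]

    # Every built entity must be reachable (orphanhood is deliberate, not
    # incidental): attach still-unused entities to random reactions.
    if all_reactions:
        while unused:
            entity = unused[0]
            rxn = rng.choice(all_reactions)
            slot = rng.choice(("input", "output"))
            rxn.slot_values[slot].append(entity.db_id)
            unused.remove(entity)
            used.append(entity)

    for i in range(config.orphan_count):
        b.new("EntityWithAccessionedSequence", f"orphan protein {i + 1}")

    return b.store, _compute_ground_truth(b.store)


def worked_toy() -> tuple[ObjectStore, GroundTruth]:
    """A fixed hand-written knowledgebase exercising every edge type.

    One top-level pathway holding a subpathway and a final reaction; a
    three-reaction cascade assembling a two-level complex over an entity
    set; one catalyst and one regulator.  Used in the docs and in golden
    tests.
    """
    b = _Builder(seed=0)
    p1 = b.new("EntityWithAccessionedSequence", "protein alpha", speciesName="Synthetic organism")
    p2 = b.new("EntityWithAccessionedSequence", "protein beta", speciesName="Synthetic organism")
    p3 = b.new("EntityWithAccessionedSequence", "protein gamma", speciesName="Synthetic organism")
    ch = b.new("SimpleEntity", "small molecule")
    s = b.new("EntitySet", "gamma-like set", hasMember=[p3.db_id], hasCandidate=[ch.db_id])
    inner = b.new("Complex", "alpha:beta complex", hasComponent=[p1.db_id, p2.db_id])
    outer = b.new("Complex", "signalling complex", hasComponent=[inner.db_id, s.db_id])
    r1 = b.new("Reaction", "alpha binds beta", input=[p1.db_id, p2.db_id], output=[inner.db_id])
    ca = b.new("CatalystActivity", "assembly catalysis", physicalEntity=ch.db_id)
    r2 = b.new("Reaction", "complex assembly",
               input=[inner.db_id, s.db_id], output=[outer.db_id],
               precedingEvent=[r1.db_id], catalystActivity=[ca.db_id])
    rg = b.new("Regulation", "alpha-mediated regulation", regulator=p1.db_id)
    r3 = b.new("Reaction", "complex turnover",
               input=[outer.db_id], output=[ch.db_id],
               precedingEvent=[r2.db_id], regulatedBy=[rg.db_id])
    sub = b.new("Pathway", "assembly subpathway", hasEvent=[r1.db_id, r2.db_id])
    top = b.new("Pathway", "signalling pathway", hasEvent=[sub.db_id, r3.db_id])
    b.store.top_level_pathways = [top.db_id]
    return b.store, _compute_ground_truth(b.store)
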