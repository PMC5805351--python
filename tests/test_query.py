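"""Traversal queries: toy golden values, hand-built edge cases, oracle spot checks."""

import json
from pathlib import Path

import pytest

from pathkb import oracles, query
from pathkb.graphstore import GraphEdge, GraphNode, PropertyGraph
from pathkb.importer import import_knowledgebase
from pathkb.model import ObjectStore

EXPECTED = json.loads((Path(__file__).parent / "data" / "worked_toy_expected.json").read_text())


def participants_as_dict(records):
    return {r.entity: {"roles": sorted(r.roles), "via": sorted(r.via_reactions)} for r in records}


class TestReactionIO:
    def test_toy_golden_values(self, toy):
        _store, _truth, graph, _report = toy
        for rid, expected in EXPECTED["reaction_io"].items():
            inputs, outputs = query.reaction_io(graph, int(rid))
            assert inputs == expected["inputs"] and outputs == expected["outputs"]

    def test_accepts_st_id(self, toy):
        _store, _truth, graph, _report = toy
        assert query.reaction_io(graph, "R-SYN-000008") == ([1, 2], [6])

    def test_no_inputs_allowed(self):
        g = PropertyGraph()
        g.add_node(GraphNode(1, ("Reaction", "ReactionLikeEvent", "Event")))
        g.add_node(GraphNode(2, ("SimpleEntity", "PhysicalEntity")))
        g.add_edge(GraphEdge(1, 2, "output", {"order": 0}))
        assert query.reaction_io(g, 1) == ([], [2])

    def test_repeated_stoichiometry_appears_repeatedly(self):
        g = PropertyGraph()
        g.add_node(GraphNode(1, ("Reaction", "ReactionLikeEvent", "Event")))
        g.add_node(GraphNode(2, ("SimpleEntity", "PhysicalEntity")))
        g.add_edge(GraphEdge(1, 2, "input", {"order": 0}))
        g.add_edge(GraphEdge(1, 2, "input", {"order": 1}))
        assert query.reaction_io(g, 1) == ([2, 2], [])

    def test_type_and_not_found_errors(self, toy):
        _store, _truth, graph, _report = toy
        with pytest.raises(query.TypeMismatchError):
            query.reaction_io(graph, 14)  # a pathway
        with pytest.raises(query.NotFoundError):
            query.reaction_io(graph, 999)

    def test_matches_store_slots_on_synthetic_kb(self, seeded_kbs):
        _config, store, _truth, graph, _report = seeded_kbs[3]
        for inst in store.instances.values():
            if store.schema.is_a(inst.class_name, "ReactionLikeEvent"):
                assert query.reaction_io(graph, inst.db_id) == oracles.reaction_io_store(store, inst.db_id)


class TestPathwayEvents:
    def test_direct_children_only(self, toy):
        _store, _truth, graph, _report = toy
        assert query.pathway_events(graph, 14, recursive=False) == {13, 12}

    def test_recursive_closure(self, toy):
        _store, _truth, graph, _report = toy
        assert query.pathway_events(graph, 14, recursive=True) == {13, 12, 8, 10}

    def test_type_error_on_entity(self, toy):
        _store, _truth, graph, _report = toy
        with pytest.raises(query.TypeMismatchError):
            query.pathway_events(graph, 7)


class TestDecompose:
    def test_toy_golden_values(self, toy):
        _store, _truth, graph, _report = toy
        for eid, expected in EXPECTED["decompositions"].items():
            assert query.decompose_entity(graph, int(eid)) == set(expected["without_candidates"])
            assert query.decompose_entity(graph, int(eid), include_candidates=True) == set(
                expected["with_candidates"]
            )

    def test_leaf_returns_itself(self, toy):
        _store, _truth, graph, _report = toy
        assert query.decompose_entity(graph, 1) == {1}

    def test_shared_substructure(self):
        # two complexes sharing a sub-complex: decomposition visits it once
        g = PropertyGraph()
        labels = ("Complex", "PhysicalEntity")
        for i in (1, 2, 3):
            g.add_node(GraphNode(i, labels))
        for i in (4, 5):
            g.add_node(GraphNode(i, ("EntityWithAccessionedSequence", "PhysicalEntity")))
        g.add_edge(GraphEdge(1, 2, "hasComponent", {"order": 0}))
        g.add_edge(GraphEdge(1, 3, "hasComponent", {"order": 1}))
        g.add_edge(GraphEdge(2, 3, "hasComponent", {"order": 0}))
        g.add_edge(GraphEdge(3, 4, "hasComponent", {"order": 0}))
        g.add_edge(GraphEdge(3, 5, "hasComponent", {"order": 1}))
        assert query.decompose_entity(g, 1) == {4, 5}

    def test_set_with_only_candidates_is_leaf_when_excluded(self):
        g = PropertyGraph()
        g.add_node(GraphNode(1, ("EntitySet", "PhysicalEntity")))
        g.add_node(GraphNode(2, ("SimpleEntity", "PhysicalEntity")))
        g.add_edge(GraphEdge(1, 2, "hasCandidate", {"order": 0}))
        assert query.decompose_entity(g, 1) == {1}
        assert query.decompose_entity(g, 1, include_candidates=True) == {2}


class TestParticipants:
    def test_stated_participants_of_top_pathway(self, toy):
        _store, _truth, graph, _report = toy
        records = query.pathway_participants(graph, 14, decompose=False)
        assert participants_as_dict(records) == {
            int(k): v for k, v in EXPECTED["top_pathway_participants_stated"].items()
        }

    def test_decomposed_participants_merge_per_leaf(self, toy):
        _store, _truth, graph, _report = toy
        records = query.pathway_participants(graph, 14, decompose=True)
        assert participants_as_dict(records) == {
            int(k): v for k, v in EXPECTED["top_pathway_participants_decomposed"].items()
        }

    def test_catalyst_flag(self, toy):
        _store, _truth, graph, _report = toy
        with_cat = participants_as_dict(query.pathway_participants(graph, 13, include_regulators=False))
        without = participants_as_dict(
            query.pathway_participants(graph, 13, include_catalysts=False, include_regulators=False)
        )
        assert "catalyst" in with_cat[4]["roles"]
        assert 4 not in without or "catalyst" not in without[4]["roles"]

    def test_matches_ground_truth_all_flag_combinations(self, seeded_kbs):
        _config, store, truth, graph, _report = seeded_kbs[1]
        for pid, combos in truth.participants.items():
            for (cat, reg, dec), table in combos.items():
                records = query.pathway_participants(graph, pid, cat, reg, dec)
                got = {r.entity: (frozenset(r.roles), frozenset(r.via_reactions)) for r in records}
                want = {e: (frozenset(v["roles"]), frozenset(v["via"])) for e, v in table.items()}
                assert got == want


class TestPathwaysForEntity:
    def test_direct_input_finds_pathway_and_ancestors(self, toy):
        _store, _truth, graph, _report = toy
        # protein beta is an input of r1 inside the subpathway
        assert query.pathways_for_entity(graph, 2, leaf_match=False) == {13, 14}

    def test_leaf_match_reaches_through_complexes(self, toy):
        _store, _truth, graph, _report = toy
        # protein gamma only participates inside the set / outer complex
        assert query.pathways_for_entity(graph, 3, leaf_match=False) == set()
        assert query.pathways_for_entity(graph, 3, leaf_match=True) == {13, 14}

    def test_non_leaf_entity_has_no_leaf_matches(self, toy):
        _store, _truth, graph, _report = toy
        assert query.pathways_for_entity(graph, 7, leaf_match=True) == set()
        assert query.pathways_for_entity(graph, 7, leaf_match=False) == {13, 14}

    def test_candidate_membership_does_not_leak(self, toy):
        _store, _truth, graph, _report = toy
        # the small molecule is only a candidate of the set, so its leaf
        # matches come from its catalyst/output roles, not set membership
        assert query.pathways_for_entity(graph, 4, leaf_match=True) == {13, 14}


class TestEventAncestors:
    def test_toy_chains(self, toy):
        _store, _truth, graph, _report = toy
        for eid, chains in EXPECTED["ancestor_chains"].items():
            assert query.event_ancestors(graph, int(eid)) == chains

    def test_diamond_yields_two_chains(self):
        g = PropertyGraph()
        for i, name in ((1, "Pathway"), (2, "Pathway"), (3, "Pathway"), (4, "Reaction")):
            labels = (name, "ReactionLikeEvent", "Event") if name == "Reaction" else (name, "Event")
            g.add_node(GraphNode(i, labels))
        g.add_edge(GraphEdge(1, 2, "hasEvent", {"order": 0}))
        g.add_edge(GraphEdge(1, 3, "hasEvent", {"order": 1}))
        g.add_edge(GraphEdge(2, 4, "hasEvent", {"order": 0}))
        g.add_edge(GraphEdge(3, 4, "hasEvent", {"order": 0}))
        assert query.event_ancestors(g, 4) == [[1, 2, 4], [1, 3, 4]]

    def test_matches_store_oracle(self, seeded_kbs):
        _config, store, _truth, graph, _report = seeded_kbs[2]
        for inst in store.instances.values():
            if store.schema.is_a(inst.class_name, "Event"):
                assert query.event_ancestors(graph, inst.db_id) == oracles.ancestors_store(store, inst.db_id)


class TestReactionChains:
    def test_single_producer_no_predecessor(self, toy):
        _store, _truth, graph, _report = toy
        chains = query.reaction_chains_to(graph, 6, max_length=3)
        assert [list(c.reactions) for c in chains] == [[8]]

    def test_linear_cascade_includes_suffixes(self, toy):
        _store, _truth, graph, _report = toy
        chains = query.reaction_chains_to(graph, 7, max_length=2)
        assert [list(c.reactions) for c in chains] == EXPECTED["chains_to_signalling_complex"]

    def test_never_produced_entity_gives_empty_list(self, toy):
        _store, _truth, graph, _report = toy
        assert query.reaction_chains_to(graph, 1) == []

    def test_preceding_event_linkage_mode(self, toy):
        _store, _truth, graph, _report = toy
        chains = query.reaction_chains_to(graph, 4, max_length=3, link_mode="preceding_event")
        assert [list(c.reactions) for c in chains] == [[12], [10, 12], [8, 10, 12]]

    def test_brute_force_match_on_fifteen_reaction_cascade(self):
        # r_i consumes e_{i-1}, produces e_i; every suffix is a chain
        from pathkb.model import Instance, builtin_schema

        schema = builtin_schema()
        store = ObjectStore(schema=schema, top_level_pathways=[1])
        n = 15
        events = []
        for i in range(n + 1):
            store.add(Instance(100 + i, f"R-E-{i}", "SimpleEntity"))
        for i in range(1, n + 1):
            store.add(
                Instance(
                    200 + i, f"R-R-{i}", "Reaction",
                    slot_values={"input": [100 + i - 1], "output": [100 + i]},
                )
            )
            events.append(200 + i)
        store.add(Instance(1, "R-P-1", "Pathway", slot_values={"hasEvent": events}))
        graph, _ = import_knowledgebase(store)
        for target in (100 + n, 100 + n // 2):
            got = [list(c.reactions) for c in query.reaction_chains_to(graph, target, max_length=6)]
            want = [list(c) for c in oracles.chains_store(store, target, max_length=6)]
            assert got == want

    def test_cycle_in_linkage_terminates(self):
        from pathkb.model import Instance, builtin_schema

        schema = builtin_schema()
        store = ObjectStore(schema=schema, top_level_pathways=[1])
        store.add(Instance(10, "R-A", "SimpleEntity"))
        store.add(Instance(11, "R-B", "SimpleEntity"))
        store.add(Instance(20, "R-R1", "Reaction", slot_values={"input": [10], "output": [11]}))
        store.add(Instance(21, "R-R2", "Reaction", slot_values={"input": [11], "output": [10]}))
        store.add(Instance(1, "R-P", "Pathway", slot_values={"hasEvent": [20, 21]}))
        graph, _ = import_knowledgebase(store)
        chains = query.reaction_chains_to(graph, 10, max_length=10)
        assert [list(c.reactions) for c in chains] == [[21], [20, 21]]


class TestFetch:
    def test_shallow_exposes_properties_and_placeholders(self, toy):
        _store, _truth, graph, _report = toy
        view = query.fetch(graph, 10, depth="shallow")
        assert view.properties["displayName"] == "complex assembly"
        assert all(isinstance(v, query.Placeholder) for values in view.refs.values() for v in values)

    def test_lazy_resolution_equals_eager(self, toy):
        _store, _truth, graph, _report = toy
        shallow = query.fetch(graph, 10, "shallow")
        resolved = shallow.refs["input"][0].resolve("shallow")
        full = query.fetch(graph, 10, "full")
        assert resolved.properties["displayName"] == full.refs["input"][0].properties["displayName"]
        assert shallow.to_plain(materialize=True) == full.to_plain()

    def test_bounded_depth_equals_truncated_full(self, seeded_kbs):
        def truncate(plain: dict, depth: int) -> dict:
            out = dict(plain)
            out["refs"] = {
                slot: [
                    v if "dbId" not in v else ({"ref": v["dbId"]} if depth == 0 else truncate(v, depth - 1))
                    for v in values
                ]
                for slot, values in plain["refs"].items()
            }
            return out

        _config, store, _truth, graph, _report = seeded_kbs[0]
        rxns = [i.db_id for i in store.instances.values() if i.class_name == "Reaction"][:10]
        for rid in rxns:
            full = query.fetch(graph, rid, "full").to_plain()
            bounded = query.fetch(graph, rid, 2).to_plain()
            assert bounded == truncate(full, 2)

    def test_marshal_matches_store_oracle(self, seeded_kbs):
        _config, store, _truth, graph, _report = seeded_kbs[0]
        rxns = [i.db_id for i in store.instances.values() if i.class_name == "Reaction"][:10]
        for rid in rxns:
            assert query.fetch(graph, rid, "full").to_plain() == oracles.marshal_store(store, rid)


def test_results_independent_of_insertion_order(seeded_kbs):
    """Importing a permuted store yields identical query answers."""
    _config, store, _truth, graph, _report = seeded_kbs[0]
    permuted = ObjectStore(
        schema=store.schema,
        instances=dict(sorted(store.instances.items(), reverse=True)),
        top_level_pathways=list(reversed(store.top_level_pathways)),
    )
    graph2, _ = import_knowledgebase(permuted)
    for pid in store.top_level_pathways:
        assert query.pathway_events(graph, pid) == query.pathway_events(graph2, pid)
        a = query.pathway_participants(graph, pid, decompose=True)
        b = query.pathway_participants(graph2, pid, decompose=True)
        assert [r.as_tuple() for r in a] == [r.as_tuple() for r in b]
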