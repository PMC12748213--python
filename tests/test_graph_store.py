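"""Property-graph schema, traversal, and serialization behavior."""

import random

import networkx as nx
import pytest

from hepagraph import (Entity, PropertyGraph, Relation, default_schema,
                       export_cypher_script, export_graphml, load_schema,
                       read_jsonl, write_jsonl)
from hepagraph.errors import IntegrityError, LinkingError, SchemaError
from hepagraph.schema import DISEASE, DRUG

from conftest import make_random_digraph


class TestSchema:
    def test_default_cardinalities(self, schema):
        assert len(schema.entity_types) == 8
        assert len(schema.relation_types) == 11

    def test_each_relation_maps_to_one_category_pair(self, schema):
        for name, pair in schema.relation_types.items():
            assert len(pair) == 2
            assert set(pair) <= schema.entity_types

    def test_recommends_drug_direction(self, schema):
        assert schema.relation_types["RECOMMENDS_DRUG"] == (DISEASE, DRUG)

    def test_yaml_roundtrip(self, schema, tmp_path):
        path = tmp_path / "schema.yaml"
        schema.to_yaml(path)
        loaded = load_schema(path)
        assert loaded.entity_types == schema.entity_types
        assert loaded.relation_types == schema.relation_types

    def test_empty_relation_map_is_valid(self, tmp_path):
        path = tmp_path / "schema.yaml"
        path.write_text("entity_types: [Disease]\nrelation_types: {}\n")
        loaded = load_schema(path)
        assert loaded.relation_types == {}

    def test_malformed_definition_names_offending_field(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("relation_types: {}\n")
        with pytest.raises(SchemaError, match="entity_types"):
            load_schema(path)


class TestMutation:
    def test_add_entity_returns_id_and_grows_graph(self, schema):
        g = PropertyGraph(schema)
        eid = g.add_entity(Entity(id="d1", name="cirrhosis", category=DISEASE))
        assert eid == "d1" and len(g) == 1

    def test_wrong_direction_is_schema_violation(self, schema):
        g = PropertyGraph(schema)
        g.add_entity(Entity(id="d1", name="cirrhosis", category=DISEASE))
        g.add_entity(Entity(id="m1", name="entecavir", category=DRUG))
        # RECOMMENDS_DRUG is Disease -> Drug; Drug as source must fail
        with pytest.raises(SchemaError):
            g.add_relation(Relation("m1", "d1", "RECOMMENDS_DRUG"))

    def test_dangling_endpoint_is_integrity_error(self, schema):
        g = PropertyGraph(schema)
        g.add_entity(Entity(id="d1", name="cirrhosis", category=DISEASE))
        with pytest.raises(IntegrityError):
            g.add_relation(Relation("d1", "ghost", "PROGRESSES_TO"))

    def test_weight_outside_unit_interval_rejected(self, schema):
        g = PropertyGraph(schema)
        g.add_entity(Entity(id="a", name="a", category=DISEASE))
        g.add_entity(Entity(id="b", name="b", category=DISEASE))
        with pytest.raises(SchemaError):
            g.add_relation(Relation("a", "b", "PROGRESSES_TO",
                                    {"weight": 1.5}))

    def test_random_records_validated_against_direction_table(self, schema):
        """Every endpoint-category combination is accepted iff it matches
        the schema's declared pair."""
        rng = random.Random(0)
        cats = sorted(schema.entity_types)
        for _ in range(200):
            rtype = rng.choice(sorted(schema.relation_types))
            src_cat, tgt_cat = rng.choice(cats), rng.choice(cats)
            g = PropertyGraph(schema)
            g.add_entity(Entity(id="s", name="s", category=src_cat))
            g.add_entity(Entity(id="t", name="t", category=tgt_cat))
            expected_ok = schema.relation_types[rtype] == (src_cat, tgt_cat)
            if expected_ok:
                g.add_relation(Relation("s", "t", rtype))
            else:
                with pytest.raises(SchemaError):
                    g.add_relation(Relation("s", "t", rtype))


class TestBFS:
    def test_path_graph_depth_two(self, path_graph):
        sub = path_graph.bfs_neighborhood(["a"], k=2)
        assert set(sub.node_ids) == {"a", "b", "c"}
        assert sub.distances == {"a": 0, "b": 1, "c": 2}

    def test_depth_zero_is_seed_set(self, path_graph):
        sub = path_graph.bfs_neighborhood(["b"], k=0)
        assert sub.node_ids == ["b"]

    def test_star_truncation_keeps_center_first(self, star_graph):
        sub = star_graph.bfs_neighborhood(["center"], k=1, node_limit=3)
        assert len(sub.node_ids) == 3
        assert sub.node_ids[0] == "center"
        assert sub.node_ids[1:] == ["leaf0", "leaf1"]  # insertion order

    def test_unknown_seed_is_linking_failure(self, path_graph):
        with pytest.raises(LinkingError):
            path_graph.bfs_neighborhood(["zz"], k=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_shortest_path_oracle(self, seed):
        """BFS neighborhood equals {e : dist(seeds, e) <= k} computed by
        networkx shortest paths on random graphs of up to 30 nodes."""
        rng = random.Random(seed)
        g = make_random_digraph(rng, rng.randint(5, 30))
        nxg = nx.DiGraph()
        nxg.add_nodes_from(g.entities)
        nxg.add_edges_from((r.source_id, r.target_id) for r in g.relations)
        seeds = rng.sample(sorted(g.entities), rng.randint(1, 3))
        for k in (0, 1, 2, 4):
            expected = set()
            for node in nxg.nodes:
                d = min((nx.shortest_path_length(nxg, s, node)
                         for s in seeds if nx.has_path(nxg, s, node)),
                        default=None)
                if d is not None and d <= k:
                    expected.add(node)
            sub = g.bfs_neighborhood(seeds, k)
            assert set(sub.node_ids) == expected
            for node, dist in sub.distances.items():
                assert dist == min(nx.shortest_path_length(nxg, s, node)
                                   for s in seeds if nx.has_path(nxg, s, node))

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_depth(self, seed):
        rng = random.Random(100 + seed)
        g = make_random_digraph(rng, 20)
        seeds = [sorted(g.entities)[0]]
        for k in range(4):
            smaller = set(g.bfs_neighborhood(seeds, k).node_ids)
            larger = set(g.bfs_neighborhood(seeds, k + 1).node_ids)
            assert smaller <= larger


class TestDFS:
    def test_progression_chain_paths(self, path_graph):
        ps = path_graph.dfs_paths(["a"], k=2,
                                  relation_filter=["PROGRESSES_TO"])
        assert [p.nodes for p in ps.paths] == [("a", "b"), ("a", "b", "c")]
        assert all(t == "PROGRESSES_TO" for p in ps.paths
                   for t in p.relation_types)

    def test_isolated_node_has_no_paths(self, schema):
        g = PropertyGraph(schema)
        g.add_entity(Entity(id="solo", name="solo", category=DISEASE))
        assert g.dfs_paths(["solo"], k=1).paths == []

    def test_cycle_never_revisits_a_node(self, triangle_graph):
        ps = triangle_graph.dfs_paths(["a"], k=5)
        for path in ps.paths:
            assert len(set(path.nodes)) == len(path.nodes)
        assert max(len(p) for p in ps.paths) == 2  # simple paths cap out

    def test_relation_filter_excludes_other_types(self, fixture_kg):
        ps = fixture_kg.dfs_paths(["d_fatty"], k=2,
                                  relation_filter=["PROGRESSES_TO"])
        assert ps.paths  # fatty liver -> cirrhosis -> carcinoma exists
        assert {t for p in ps.paths for t in p.relation_types} == \
            {"PROGRESSES_TO"}

    def test_path_limit_truncates_lexicographically(self, star_graph):
        ps = star_graph.dfs_paths(["center"], k=1, path_limit=2)
        assert [p.nodes for p in ps.paths] == [("center", "leaf0"),
                                               ("center", "leaf1")]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_simple_path_enumeration_oracle(self, seed):
        """dfs_paths equals networkx all_simple_paths (cutoff k) on random
        graphs of up to 15 nodes."""
        rng = random.Random(200 + seed)
        g = make_random_digraph(rng, rng.randint(4, 15), edge_prob=0.25)
        nxg = nx.DiGraph()
        nxg.add_nodes_from(g.entities)
        nxg.add_edges_from((r.source_id, r.target_id) for r in g.relations)
        seeds = rng.sample(sorted(g.entities), 2)
        for k in (1, 2, 3):
            expected = set()
            for s in seeds:
                for target in nxg.nodes:
                    if target == s:
                        continue
                    for nodes in nx.all_simple_paths(nxg, s, target, cutoff=k):
                        expected.add(tuple(nodes))
            got = {p.nodes for p in g.dfs_paths(seeds, k).paths}
            assert got == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_depth(self, seed):
        rng = random.Random(300 + seed)
        g = make_random_digraph(rng, 10, edge_prob=0.3)
        seeds = [sorted(g.entities)[0]]
        for k in range(1, 4):
            smaller = {p.nodes for p in g.dfs_paths(seeds, k).paths}
            larger = {p.nodes for p in g.dfs_paths(seeds, k + 1).paths}
            assert smaller <= larger


class TestIO:
    def test_jsonl_roundtrip_identity(self, fixture_kg, tmp_path):
        write_jsonl(fixture_kg, tmp_path / "e.jsonl", tmp_path / "r.jsonl")
        loaded = read_jsonl(tmp_path / "e.jsonl", tmp_path / "r.jsonl")
        assert {(e.id, e.name, e.category, e.cui)
                for e in loaded.entities.values()} == \
            {(e.id, e.name, e.category, e.cui)
             for e in fixture_kg.entities.values()}
        assert sorted((r.source_id, r.target_id, r.type)
                      for r in loaded.relations) == \
            sorted((r.source_id, r.target_id, r.type)
                   for r in fixture_kg.relations)

    def test_empty_graph_roundtrip(self, schema, tmp_path):
        g = PropertyGraph(schema)
        write_jsonl(g, tmp_path / "e.jsonl", tmp_path / "r.jsonl")
        loaded = read_jsonl(tmp_path / "e.jsonl", tmp_path / "r.jsonl")
        assert len(loaded) == 0 and loaded.relations == []

    def test_invalid_record_reports_line_number(self, schema, tmp_path):
        (tmp_path / "e.jsonl").write_text(
            '{"id": "a", "name": "a", "category": "Disease"}\n'
            '{"id": "b", "name": "b", "category": "NotACategory"}\n')
        (tmp_path / "r.jsonl").write_text("")
        with pytest.raises(SchemaError, match=":2:"):
            read_jsonl(tmp_path / "e.jsonl", tmp_path / "r.jsonl", schema)

    def test_cypher_export_carries_weight_property(self, fixture_kg, tmp_path):
        script = export_cypher_script(fixture_kg, tmp_path / "g.cypher")
        assert "RECOMMENDS_DRUG" in script
        assert "weight: 0.9" in script
        assert script.count("CREATE") == \
            len(fixture_kg.entities) + len(fixture_kg.relations)

    def test_graphml_export_is_readable(self, fixture_kg, tmp_path):
        export_graphml(fixture_kg, tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_nodes() == len(fixture_kg.entities)
        assert back.number_of_edges() == len(fixture_kg.relations)
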