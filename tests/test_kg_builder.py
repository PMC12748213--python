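"""KG construction: chunking, payload validation, dedup, fusion, review."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepagraph import Entity, PropertyGraph, Relation, qc_report
from hepagraph.builder import (ReviewLedger, RawEntity, RawRelation,
                               apply_review, build_graph, chunk_text,
                               dedup_entities, fuse_relations,
                               parse_extraction, reassemble)
from hepagraph.errors import FusionError
from hepagraph.schema import DISEASE, DRUG, default_schema


def make_doc(n_sentences: int) -> str:
    return " ".join(f"Sentence number {i} discusses the liver."
                    for i in range(n_sentences))


class TestChunking:
    def test_every_sentence_appears_in_some_chunk(self):
        chunks = chunk_text(make_doc(10), max_units=4, overlap=1)
        seen = {s for c in chunks for s in c.sentences}
        assert len({s.strip() for s in seen}) == 10

    def test_short_document_is_single_chunk(self):
        doc = "Only one sentence here."
        chunks = chunk_text(doc, max_units=8, overlap=1)
        assert len(chunks) == 1 and chunks[0].text == doc

    def test_empty_document_gives_empty_list(self):
        assert chunk_text("", max_units=4, overlap=1) == []

    def test_consecutive_chunks_share_overlap_sentences(self):
        chunks = chunk_text(make_doc(12), max_units=5, overlap=2)
        for left, right in zip(chunks, chunks[1:]):
            assert left.sentences[-2:] == right.sentences[:2]

    @pytest.mark.parametrize("n,max_units,overlap",
                             [(100, 8, 1), (100, 5, 2), (7, 3, 0)])
    def test_reassembly_reproduces_document(self, n, max_units, overlap):
        doc = make_doc(n)
        chunks = chunk_text(doc, max_units=max_units, overlap=overlap)
        assert reassemble(chunks, overlap) == doc

    def test_rejects_overlap_not_smaller_than_window(self):
        with pytest.raises(ValueError):
            chunk_text("a. b.", max_units=2, overlap=2)


class TestParseExtraction:
    def test_unknown_category_rejected_with_reason(self, schema):
        payload = json.dumps({"entities": [
            {"surface": "cirrhosis", "category": "Disease"},
            {"surface": "entecavir", "category": "Drug"},
            {"surface": "mystery", "category": "Potion"},
        ]})
        out = parse_extraction(payload, schema)
        assert len(out.entities) == 2
        assert len(out.errors) == 1 and "Potion" in out.errors[0]

    def test_empty_object_is_empty_extraction(self, schema):
        out = parse_extraction("{}", schema)
        assert out.entities == [] and out.relations == [] and out.errors == []

    def test_non_json_payload_is_recoverable(self, schema):
        out = parse_extraction("not json at all", schema)
        assert out.entities == [] and out.errors

    def test_direction_mismatched_relation_rejected(self, schema):
        payload = json.dumps({
            "entities": [{"surface": "cirrhosis", "category": "Disease"},
                         {"surface": "entecavir", "category": "Drug"}],
            "relations": [{"source": "entecavir", "target": "cirrhosis",
                           "type": "RECOMMENDS_DRUG"}],
        })
        out = parse_extraction(payload, schema)
        assert out.relations == []
        assert any("RECOMMENDS_DRUG" in e for e in out.errors)


class TestDedup:
    def test_same_cui_different_names_merge(self):
        res = dedup_entities([
            RawEntity("fatty liver", DISEASE, cui="C0015695"),
            RawEntity("hepatic steatosis", DISEASE, cui="C0015695"),
        ])
        assert len(res.entities) == 1

    def test_name_normalization_merges_case_and_whitespace(self):
        res = dedup_entities([
            RawEntity("Cirrhosis ", DISEASE),
            RawEntity("cirrhosis", DISEASE),
        ])
        assert len(res.entities) == 1
        assert res.entities[0].name == "cirrhosis"

    def test_cui_outranks_identical_names(self):
        res = dedup_entities([
            RawEntity("viral hepatitis", DISEASE, cui="C1"),
            RawEntity("viral hepatitis", DISEASE, cui="C2"),
        ])
        assert len(res.entities) == 2

    def test_attribute_conflicts_keep_first_and_log(self):
        res = dedup_entities([
            RawEntity("cirrhosis", DISEASE, attributes={"stage": "early"}),
            RawEntity("cirrhosis", DISEASE, attributes={"stage": "late"}),
        ])
        assert res.entities[0].attributes["stage"] == "early"
        assert res.conflicts

    @given(st.lists(st.tuples(st.sampled_from(["a", "b", "c", "B ", " a"]),
                              st.sampled_from([None, "C1", "C2"])),
                    max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, raw):
        records = [RawEntity(surface, DISEASE, cui=cui)
                   for surface, cui in raw if surface.strip()]
        once = dedup_entities(records)
        again = dedup_entities([
            RawEntity(e.raw_name, e.category, cui=e.cui,
                      attributes=dict(e.attributes))
            for e in once.entities])
        assert len(again.entities) == len(once.entities)


class TestFusion:
    def _merge_map(self):
        return {"cirrhosis": "e0", "entecavir": "e1"}

    def test_weight_is_arithmetic_mean(self):
        fused, _ = fuse_relations([
            RawRelation("cirrhosis", "entecavir", "RECOMMENDS_DRUG",
                        {"weight": 0.8}, chunk_id="c1"),
            RawRelation("cirrhosis", "entecavir", "RECOMMENDS_DRUG",
                        {"weight": 0.6}, chunk_id="c2"),
        ], self._merge_map())
        assert len(fused) == 1
        assert fused[0].attributes["weight"] == pytest.approx(0.7)
        assert fused[0].provenance == ["c1", "c2"]

    def test_strongest_recommendation_wins(self):
        fused, _ = fuse_relations([
            RawRelation("cirrhosis", "entecavir", "RECOMMENDS_DRUG",
                        {"recommendation_strength": "conditional"}),
            RawRelation("cirrhosis", "entecavir", "RECOMMENDS_DRUG",
                        {"recommendation_strength": "strong"}),
        ], self._merge_map())
        assert fused[0].attributes["recommendation_strength"] == "strong"

    def test_single_relation_unchanged(self):
        fused, _ = fuse_relations(
            [RawRelation("cirrhosis", "entecavir", "RECOMMENDS_DRUG",
                         {"weight": 0.5})], self._merge_map())
        assert len(fused) == 1
        assert fused[0].attributes["weight"] == pytest.approx(0.5)

    def test_unknown_strength_label_raises(self):
        with pytest.raises(FusionError, match="overwhelming"):
            fuse_relations([
                RawRelation("cirrhosis", "entecavir", "RECOMMENDS_DRUG",
                            {"recommendation_strength": "overwhelming"}),
            ], self._merge_map())

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_fused_weight_within_member_bounds(self, weights):
        fused, _ = fuse_relations([
            RawRelation("cirrhosis", "entecavir", "RECOMMENDS_DRUG",
                        {"weight": w}) for w in weights], self._merge_map())
        assert len(fused) == 1
        eps = 1e-12  # fmean may round one ulp past the bounds
        assert min(weights) - eps <= fused[0].attributes["weight"] \
            <= max(weights) + eps


class TestReview:
    def _entities(self, ids):
        return [Entity(id=i, name=i, category=DISEASE) for i in ids]

    def test_remove_and_add(self):
        ledger = ReviewLedger(remove={"b"}, add=self._entities(["d"]))
        final, _ = apply_review(self._entities(["a", "b", "c"]), ledger)
        assert {e.id for e in final} == {"a", "c", "d"}

    def test_empty_ledger_is_identity(self):
        final, warnings = apply_review(self._entities(["a", "b"]),
                                       ReviewLedger())
        assert {e.id for e in final} == {"a", "b"} and not warnings

    def test_adding_present_entity_keeps_set_semantics(self):
        ledger = ReviewLedger(add=self._entities(["a"]))
        final, _ = apply_review(self._entities(["a", "b"]), ledger)
        assert sorted(e.id for e in final) == ["a", "b"]

    def test_missing_removal_key_warns_not_fails(self):
        ledger = ReviewLedger(remove={"zzz"})
        final, warnings = apply_review(self._entities(["a"]), ledger)
        assert {e.id for e in final} == {"a"}
        assert warnings and "zzz" in warnings[0]

    def test_ledger_rejects_conflicting_remove_and_add(self):
        with pytest.raises(ValueError):
            ReviewLedger(remove={"a"}, add=self._entities(["a"]))

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)),
           st.sets(st.integers(0, 20)))
    @settings(max_examples=100, deadline=None)
    def test_matches_set_algebra_oracle(self, extracted, removed, added):
        added = added - removed  # ledger invariant
        ledger = ReviewLedger(
            remove={str(i) for i in removed},
            add=self._entities([str(i) for i in added]))
        final, _ = apply_review(self._entities([str(i) for i in extracted]),
                                ledger)
        assert {e.id for e in final} == \
            {str(i) for i in (extracted - removed) | added}


class TestQCReport:
    def test_counts_match_fixture(self, schema):
        g = PropertyGraph(schema)
        for i in range(10):
            g.add_entity(Entity(id=f"d{i}", name=f"disease {i}",
                                category=DISEASE))
        for i in range(5):
            g.add_relation(Relation(f"d{i}", f"d{i+1}", "PROGRESSES_TO"))
        report = qc_report(g)
        assert report.entity_count == 10 and report.relation_count == 5
        assert report.relations_per_type == {"PROGRESSES_TO": 5}
        json.loads(report.to_json())  # serializable

    def test_missing_required_attribute_drops_completeness(self, schema):
        g = PropertyGraph(schema)
        g.add_entity(Entity(id="d", name="d", category=DISEASE))
        g.add_entity(Entity(id="m", name="m", category=DRUG))
        g.add_relation(Relation("d", "m", "RECOMMENDS_DRUG",
                                {"weight": 0.5}))
        report = qc_report(g)
        comp = report.attribute_completeness["RECOMMENDS_DRUG"]
        assert comp["evidence_level"] == 0.0
        assert comp["weight"] == 1.0

    def test_empty_graph_is_all_zero(self, schema):
        report = qc_report(PropertyGraph(schema))
        assert report.entity_count == 0 and report.relation_count == 0
        assert report.attribute_completeness == {}


class TestPipeline:
    def test_build_graph_is_deterministic(self, schema, tmp_path):
        from hepagraph import write_jsonl
        payload = json.dumps({
            "entities": [{"surface": "Cirrhosis", "category": "Disease",
                          "cui": "C0023890"},
                         {"surface": "entecavir", "category": "Drug"}],
            "relations": [{"source": "cirrhosis", "target": "entecavir",
                           "type": "RECOMMENDS_DRUG",
                           "attributes": {"weight": 0.8}}],
        })
        outputs = []
        for run_dir in ("one", "two"):
            d = tmp_path / run_dir
            d.mkdir()
            g = build_graph([parse_extraction(payload, schema, "chunk0")],
                            schema)
            write_jsonl(g, d / "e.jsonl", d / "r.jsonl")
            outputs.append((d / "e.jsonl").read_bytes()
                           + (d / "r.jsonl").read_bytes())
        assert outputs[0] == outputs[1]
        assert b"RECOMMENDS_DRUG" in outputs[0]
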