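"""Semi-automated knowledge-graph construction.

The pipeline mirrors a human-in-the-loop guideline-curation workflow:

1. :func:`chunk_text` segments cleaned guideline text into overlapping,
   sentence-aligned chunks sized for an extraction model's context window.
2. :func:`parse_extraction` validates the strict-JSON extraction payload a
   model returns for each chunk; invalid records are kept as typed errors,
   never silently dropped.
3. :func:`dedup_entities` performs hierarchical deduplication: concept id
   (CUI) first, then normalized name, then the raw surface form.
4. :func:`fuse_relations` merges parallel relations of the same
   (source, target, type), averaging numeric evidence weights and keeping
   the strongest recommendation level on an ordinal scale.
5. :func:`apply_review` applies an expert review ledger with exact set
   algebra: ``E_final = (E_LLM \\ E_remove) ∪ E_add``.
6. :func:`qc_report` summarizes the final graph for quality control.

Everything here is deterministic: identical inputs yield byte-identical
JSONL output.
"""

from __future__ import annotations

import json
import re
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import FusionError, SchemaError
from .graph import Entity, PropertyGraph, Relation
from .schema import Schema

#: strongest-last ordinal scale for recommendation strength
DEFAULT_STRENGTH_SCALE = ("expert-opinion", "weak", "conditional", "strong")


def normalize_name(surface: str) -> str:
    """Casefold, trim, and collapse internal whitespace.  No stemming."""
    return re.sub(r"\s+", " ", surface.casefold().strip())


# --------------------------------------------------------------------------
# chunking


@dataclass
class Chunk:
    chunk_id: str
    sentences: list[str]

    @property
    def text(self) -> str:
        return "".join(self.sentences)


_SENTENCE_END = re.compile(r"(?<=[.!?;])\s+")


def split_sentences(document: str) -> list[str]:
    """Sentence units whose concatenation reproduces the document exactly."""
    if not document:
        return []
    sentences: list[str] = []
    start = 0
    for match in _SENTENCE_END.finditer(document):
        sentences.append(document[start:match.end()])
        start = match.end()
    if start < len(document):
        sentences.append(document[start:])
    return sentences


def chunk_text(document: str, max_units: int = 8, overlap: int = 1,
               doc_id: str = "doc") -> list[Chunk]:
    """Split a document into sentence-aligned chunks.

    Consecutive chunks share ``overlap`` sentences; every sentence appears
    in at least one chunk.
    """
    if overlap < 0 or max_units <= overlap:
        raise ValueError("require max_units > overlap >= 0")
    sentences = split_sentences(document)
    if not sentences:
        return []
    step = max_units - overlap
    chunks: list[Chunk] = []
    i = 0
    while True:
        window = sentences[i:i + max_units]
        chunks.append(Chunk(chunk_id=f"{doc_id}-c{len(chunks)}", sentences=window))
        if i + max_units >= len(sentences):
            break
        i += step
    return chunks


def reassemble(chunks: Sequence[Chunk], overlap: int) -> str:
    """Inverse of :func:`chunk_text` (used as a round-trip check)."""
    parts: list[str] = []
    for j, chunk in enumerate(chunks):
        sents = chunk.sentences if j == 0 else chunk.sentences[overlap:]
        parts.extend(sents)
    return "".join(parts)


# --------------------------------------------------------------------------
# extraction payloads


@dataclass
class RawEntity:
    surface: str
    category: str
    cui: str | None = None
    attributes: dict = field(default_factory=dict)
    chunk_id: str = ""


@dataclass
class RawRelation:
    source: str
    target: str
    type: str
    attributes: dict = field(default_factory=dict)
    chunk_id: str = ""


@dataclass
class ChunkExtraction:
    """Validated extraction result for one chunk, with rejection reasons."""

    chunk_id: str
    entities: list[RawEntity] = field(default_factory=list)
    relations: list[RawRelation] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def parse_extraction(json_payload: str, schema: Schema,
                     chunk_id: str = "") -> ChunkExtraction:
    """Validate a strict-JSON extraction payload against the schema.

    The payload layout is ``{"entities": [{"surface", "category", "cui"?,
    "attributes"?}], "relations": [{"source", "target", "type",
    "attributes"?}]}``.  A non-JSON payload is recoverable: the result is
    an empty extraction whose ``errors`` records the parse failure.
    Relation endpoints are resolved against the payload's own entity list
    and checked against the schema's direction conventions.
    """
    out = ChunkExtraction(chunk_id=chunk_id)
    try:
        doc = json.loads(json_payload)
    except json.JSONDecodeError as exc:
        out.errors.append(f"payload is not valid JSON: {exc}")
        return out
    if not isinstance(doc, dict):
        out.errors.append("payload must be a JSON object")
        return out

    category_of: dict[str, str] = {}
    for i, rec in enumerate(doc.get("entities", [])):
        surface = (rec.get("surface") or "").strip() if isinstance(rec, dict) else ""
        category = rec.get("category") if isinstance(rec, dict) else None
        if not surface:
            out.errors.append(f"entities[{i}]: missing surface form")
            continue
        if category not in schema.entity_types:
            out.errors.append(
                f"entities[{i}] ({surface!r}): unknown category {category!r}")
            continue
        out.entities.append(RawEntity(
            surface=surface, category=category, cui=rec.get("cui"),
            attributes=rec.get("attributes", {}), chunk_id=chunk_id))
        category_of.setdefault(normalize_name(surface), category)

    for i, rec in enumerate(doc.get("relations", [])):
        if not isinstance(rec, dict):
            out.errors.append(f"relations[{i}]: not an object")
            continue
        rtype = rec.get("type")
        src, tgt = rec.get("source", ""), rec.get("target", "")
        if rtype not in schema.relation_types:
            out.errors.append(f"relations[{i}]: unknown type {rtype!r}")
            continue
        src_cat = category_of.get(normalize_name(src))
        tgt_cat = category_of.get(normalize_name(tgt))
        if src_cat is None or tgt_cat is None:
            out.errors.append(
                f"relations[{i}] ({rtype}): endpoint not among extracted entities")
            continue
        if (src_cat, tgt_cat) != schema.relation_types[rtype]:
            exp = schema.relation_types[rtype]
            out.errors.append(
                f"relations[{i}] ({rtype}): expects {exp[0]} -> {exp[1]}, "
                f"got {src_cat} -> {tgt_cat}")
            continue
        out.relations.append(RawRelation(
            source=src, target=tgt, type=rtype,
            attributes=rec.get("attributes", {}), chunk_id=chunk_id))
    return out


# --------------------------------------------------------------------------
# deduplication and fusion


@dataclass
class DedupResult:
    entities: list[Entity]
    #: normalized surface form (and cui) -> merged entity id
    merge_map: dict[str, str]
    conflicts: list[str] = field(default_factory=list)


def dedup_entities(records: Iterable[RawEntity]) -> DedupResult:
    """Hierarchical deduplication: CUI > normalized name > raw surface.

    Attributes merge first-seen-wins; conflicting later values are logged,
    not applied.  The merge map lets relations re-point their endpoint
    surfaces to merged entity ids.
    """
    entities: list[Entity] = []
    by_key: dict[tuple[str, str], Entity] = {}
    merge_map: dict[str, str] = {}
    conflicts: list[str] = []

    for rec in records:
        norm = normalize_name(rec.surface)
        if rec.cui:
            key = ("cui", rec.cui)
        elif norm:
            key = ("name", norm)
        else:
            key = ("raw", rec.surface)
        ent = by_key.get(key)
        if ent is None:
            ent = Entity(
                id=f"e{len(entities)}",
                name=norm or rec.surface,
                category=rec.category,
                cui=rec.cui,
                raw_name=rec.surface,
                attributes=dict(rec.attributes),
            )
            by_key[key] = ent
            entities.append(ent)
        else:
            for attr, value in rec.attributes.items():
                if attr not in ent.attributes:
                    ent.attributes[attr] = value
                elif ent.attributes[attr] != value:
                    conflicts.append(
                        f"{ent.id}: attribute {attr!r} conflict "
                        f"({ent.attributes[attr]!r} kept, {value!r} dropped)")
            if rec.category != ent.category:
                conflicts.append(
                    f"{ent.id}: category conflict "
                    f"({ent.category!r} kept, {rec.category!r} dropped)")
        if rec.cui:
            merge_map.setdefault(rec.cui, ent.id)
        merge_map.setdefault(norm or rec.surface, ent.id)
    return DedupResult(entities=entities, merge_map=merge_map, conflicts=conflicts)


def fuse_relations(records: Iterable[RawRelation], merge_map: dict[str, str],
                   strength_scale: Sequence[str] = DEFAULT_STRENGTH_SCALE,
                   ) -> tuple[list[Relation], list[str]]:
    """Group parallel relations and synthesize their evidence.

    Per (source, target, type) group: ``weight`` becomes the arithmetic
    mean of member weights, ``recommendation_strength`` the strongest
    label on ``strength_scale``, provenance the union.  Other attributes
    are first-seen-wins.  Returns (fused relations, skip log).
    """
    rank = {label: i for i, label in enumerate(strength_scale)}
    groups: dict[tuple[str, str, str], list[RawRelation]] = {}
    order: list[tuple[str, str, str]] = []
    skipped: list[str] = []
    for rec in records:
        src = merge_map.get(normalize_name(rec.source))
        tgt = merge_map.get(normalize_name(rec.target))
        if src is None or tgt is None:
            skipped.append(f"{rec.type}: endpoint {rec.source!r} or "
                           f"{rec.target!r} not in merge map")
            continue
        key = (src, tgt, rec.type)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    fused: list[Relation] = []
    for key in order:
        members = groups[key]
        attributes: dict = {}
        for rec in members:
            for attr, value in rec.attributes.items():
                attributes.setdefault(attr, value)
        weights = [float(r.attributes["weight"]) for r in members
                   if r.attributes.get("weight") is not None]
        if weights:
            attributes["weight"] = statistics.fmean(weights)
        strengths = [r.attributes["recommendation_strength"] for r in members
                     if r.attributes.get("recommendation_strength") is not None]
        if strengths:
            for label in strengths:
                if label not in rank:
                    raise FusionError(
                        f"unknown recommendation strength {label!r}; "
                        f"scale is {list(strength_scale)}")
            attributes["recommendation_strength"] = max(strengths,
                                                        key=rank.__getitem__)
        provenance: list[str] = []
        for rec in members:
            if rec.chunk_id and rec.chunk_id not in provenance:
                provenance.append(rec.chunk_id)
        fused.append(Relation(source_id=key[0], target_id=key[1], type=key[2],
                              attributes=attributes, provenance=provenance))
    return fused, skipped


# --------------------------------------------------------------------------
# expert review (set algebra)


@dataclass
class ReviewLedger:
    """Expert corrections: removals by entity key, additions as entities.

    Relation corrections mirror the entity set algebra by construction.
    """

    remove: set[str] = field(default_factory=set)
    add: list[Entity] = field(default_factory=list)
    relation_remove: set[tuple[str, str, str]] = field(default_factory=set)
    relation_add: list[Relation] = field(default_factory=list)

    def __post_init__(self) -> None:
        added = {e.id for e in self.add}
        if self.remove & added:
            raise ValueError("ledger removes and adds the same entity key")

    @classmethod
    def from_json(cls, path) -> "ReviewLedger":
        doc = json.loads(open(path, encoding="utf-8").read())
        return cls(
            remove=set(doc.get("remove", [])),
            add=[Entity(**rec) for rec in doc.get("add", [])],
            relation_remove={tuple(k) for k in doc.get("relation_remove", [])},
            relation_add=[Relation(**rec) for rec in doc.get("relation_add", [])],
        )


def apply_review(entities: Sequence[Entity], ledger: ReviewLedger,
                 ) -> tuple[list[Entity], list[str]]:
    """``E_final = (E_LLM \\ E_remove) ∪ E_add`` with set semantics on ids.

    Removal keys absent from the extracted set produce warnings, not
    failures.
    """
    warnings: list[str] = []
    present = {e.id for e in entities}
    for key in sorted(ledger.remove - present):
        warnings.append(f"removal key {key!r} not in extracted entity set")
    final = [e for e in entities if e.id not in ledger.remove]
    ids = {e.id for e in final}
    for ent in ledger.add:
        if ent.id in ids:
            continue  # set union: already present
        final.append(ent)
        ids.add(ent.id)
    return final, warnings


def apply_relation_review(relations: Sequence[Relation], ledger: ReviewLedger,
                          ) -> list[Relation]:
    final = [r for r in relations if r.key() not in ledger.relation_remove]
    keys = {r.key() for r in final}
    for rel in ledger.relation_add:
        if rel.key() in keys:
            continue
        final.append(rel)
        keys.add(rel.key())
    return final


# --------------------------------------------------------------------------
# quality control


@dataclass
class QCReport:
    entity_count: int
    relation_count: int
    entities_per_type: dict[str, int]
    relations_per_type: dict[str, int]
    dangling_reference_count: int
    duplicate_candidate_count: int
    attribute_completeness: dict[str, dict[str, float]]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.__dict__, indent=indent, sort_keys=True)


def qc_report(graph: PropertyGraph) -> QCReport:
    """Quantitative quality report for a built graph.

    ``attribute_completeness[rtype][attr]`` is the fraction of relations
    of that type carrying the schema-required attribute.  Duplicate
    candidates are distinct entities sharing a normalized name.
    """
    entities_per_type: dict[str, int] = {}
    for ent in graph.entities.values():
        entities_per_type[ent.category] = entities_per_type.get(ent.category, 0) + 1
    relations_per_type: dict[str, int] = {}
    for rel in graph.relations:
        relations_per_type[rel.type] = relations_per_type.get(rel.type, 0) + 1

    names: dict[str, int] = {}
    for ent in graph.entities.values():
        key = normalize_name(ent.name)
        names[key] = names.get(key, 0) + 1
    duplicates = sum(count - 1 for count in names.values() if count > 1)

    completeness: dict[str, dict[str, float]] = {}
    for rtype, attrs in graph.schema.required_attributes.items():
        members = [r for r in graph.relations if r.type == rtype]
        if not members:
            continue
        completeness[rtype] = {
            attr: sum(1 for r in members if attr in r.attributes) / len(members)
            for attr in attrs
        }

    return QCReport(
        entity_count=len(graph.entities),
        relation_count=len(graph.relations),
        entities_per_type=entities_per_type,
        relations_per_type=relations_per_type,
        dangling_reference_count=0,  # construction forbids dangling endpoints
        duplicate_candidate_count=duplicates,
        attribute_completeness=completeness,
    )


# --------------------------------------------------------------------------
# end-to-end build


def build_graph(extractions: Sequence[ChunkExtraction], schema: Schema,
                ledger: ReviewLedger | None = None) -> PropertyGraph:
    """Fuse chunk extractions (and optional expert review) into a graph."""
    all_entities = [e for x in extractions for e in x.entities]
    all_relations = [r for x in extractions for r in x.relations]
    dedup = dedup_entities(all_entities)
    fused, _skipped = fuse_relations(all_relations, dedup.merge_map)
    entities = dedup.entities
    if ledger is not None:
        entities, _warn = apply_review(entities, ledger)
        fused = apply_relation_review(fused, ledger)
    graph = PropertyGraph(schema)
    for ent in entities:
        graph.add_entity(ent)
    ids = set(graph.entities)
    for rel in fused:
        if rel.source_id in ids and rel.target_id in ids:
            graph.add_relation(rel)
    return graph
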