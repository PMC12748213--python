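"""Graph serialization: JSONL entities/relations, GraphML, openCypher.

The on-disk form is two UTF-8 JSON-lines files:

``entities.jsonl``  — ``{"id", "name", "category", "cui"?, "raw_name"?,
"attributes"?}`` per line;
``relations.jsonl`` — ``{"source_id", "target_id", "type", "attributes"?,
"provenance"?}`` per line.

``write_jsonl`` followed by ``read_jsonl`` is the identity on graph
content.  The openCypher export is a CREATE script suitable for loading
the graph into a property-graph database.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .errors import SchemaError
from .graph import Entity, PropertyGraph, Relation
from .schema import Schema


def write_jsonl(graph: PropertyGraph, entities_path: str | Path,
                relations_path: str | Path) -> None:
    with open(entities_path, "w", encoding="utf-8") as fh:
        for ent in graph.entities.values():
            rec = {"id": ent.id, "name": ent.name, "category": ent.category}
            if ent.cui:
                rec["cui"] = ent.cui
            if ent.raw_name:
                rec["raw_name"] = ent.raw_name
            if ent.attributes:
                rec["attributes"] = ent.attributes
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
    with open(relations_path, "w", encoding="utf-8") as fh:
        for rel in graph.relations:
            rec = {"source_id": rel.source_id, "target_id": rel.target_id,
                   "type": rel.type}
            if rel.attributes:
                rec["attributes"] = rel.attributes
            if rel.provenance:
                rec["provenance"] = rel.provenance
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")


def read_jsonl(entities_path: str | Path, relations_path: str | Path,
               schema: Schema | None = None) -> PropertyGraph:
    """Load a graph; schema violations report the offending line number."""
    graph = PropertyGraph(schema)
    for lineno, rec in _iter_records(entities_path):
        try:
            graph.add_entity(Entity(
                id=rec["id"], name=rec["name"], category=rec["category"],
                cui=rec.get("cui"), raw_name=rec.get("raw_name"),
                attributes=rec.get("attributes", {}),
            ))
        except Exception as exc:
            raise SchemaError(
                f"{entities_path}:{lineno}: invalid entity record: {exc}"
            ) from exc
    for lineno, rec in _iter_records(relations_path):
        try:
            graph.add_relation(Relation(
                source_id=rec["source_id"], target_id=rec["target_id"],
                type=rec["type"], attributes=rec.get("attributes", {}),
                provenance=rec.get("provenance", []),
            ))
        except Exception as exc:
            raise SchemaError(
                f"{relations_path}:{lineno}: invalid relation record: {exc}"
            ) from exc
    return graph


def _iter_records(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield lineno, json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: not valid JSON: {exc}") from exc


def export_graphml(graph: PropertyGraph, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), str(path))


def _cypher_label(category: str) -> str:
    """Category -> Cypher node label (alphanumeric only)."""
    return re.sub(r"[^0-9A-Za-z]", "", category.title())


def _cypher_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if value is None:
        return "null"
    escaped = str(value).replace("\\", "\\\\").replace("'", "\\'")
    return f"'{escaped}'"


def _cypher_props(props: dict) -> str:
    inner = ", ".join(f"{k}: {_cypher_value(v)}" for k, v in props.items()
                      if v is not None)
    return "{" + inner + "}"


def export_cypher_script(graph: PropertyGraph, path: str | Path) -> str:
    """Write (and return) an openCypher CREATE script for the graph."""
    lines: list[str] = []
    var_of: dict[str, str] = {}
    for i, ent in enumerate(graph.entities.values()):
        var = f"e{i}"
        var_of[ent.id] = var
        props = {"id": ent.id, "name": ent.name}
        if ent.cui:
            props["cui"] = ent.cui
        props.update(ent.attributes)
        lines.append(f"CREATE ({var}:{_cypher_label(ent.category)} "
                     f"{_cypher_props(props)})")
    for rel in graph.relations:
        props = dict(rel.attributes)
        if rel.provenance:
            props["provenance"] = "|".join(rel.provenance)
        pattern = (f"CREATE ({var_of[rel.source_id]})-[:{rel.type} "
                   f"{_cypher_props(props)}]->({var_of[rel.target_id]})")
        lines.append(pattern)
    script = ";\n".join(lines) + (";\n" if lines else "")
    Path(path).write_text(script, encoding="utf-8")
    return script
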