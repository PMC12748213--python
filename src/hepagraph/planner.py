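"""Intent classification, strategy selection, and graph-query planning.

A question plus its linked entities becomes an executable
:class:`GraphQuery` through four steps:

* :func:`classify_intent` — rule-based (or provider-backed) intent label;
* :func:`intent_to_strategy` — the fixed intent -> search-strategy map:
  shallow breadth-first retrieval (k = 2) for fact / diagnosis / symptom
  questions, deeper depth-first traversal for causal (k = 3) and
  multi-hop (k = 4) questions;
* :func:`generate_graph_query` — two providers independently emit a
  structured query payload; matching structural signatures give full
  generation consistency (C_cypher = 1.0), divergence gives 0.5 and the
  primary's query wins.  Signatures, not raw query text, are compared so
  cosmetic differences cannot fail the check;
* :func:`validate_semantics` — every (anchor category, relation type,
  direction) triple is checked against the schema's direction conventions
  before execution; an invalid query gets one rewrite attempt (drop the
  incompatible relation types, or flip the direction if that alone
  repairs it) and then fails to the fallback path.

:func:`render_cypher` emits a deterministic openCypher MATCH for audit
and database interop; it is never parsed back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

from .config import StrategyConfig
from .errors import PlanningError, QueryValidationError
from .graph import PropertyGraph
from .linking import LinkedEntity
from .providers import GeneratorContract, graph_query_prompt
from .schema import Schema

INTENTS = ("fact", "diagnosis", "symptom", "causal", "multi_hop", "ambiguous")


@dataclass
class SearchStrategy:
    """Mutable retrieval policy — the object the optimizer edits."""

    method: str = "BFS"              # "BFS" | "DFS"
    k: int = 2
    node_limit: int = 50
    switched: bool = False           # a BFS<->DFS toggle already happened

    def copy(self) -> "SearchStrategy":
        return replace(self)


@dataclass(frozen=True)
class GraphQuery:
    anchors: tuple[str, ...]         # graph entity ids
    anchor_names: tuple[str, ...]
    relation_types: tuple[str, ...]  # empty = unconstrained
    direction: str = "out"           # "out" | "undirected"
    intent: str = "fact"

    def signature(self) -> tuple:
        """Canonical structural form used for the consistency check."""
        return (tuple(sorted(self.anchors)),
                tuple(sorted(self.relation_types)),
                self.direction)


@dataclass
class ValidationResult:
    ok: bool
    violations: list[tuple[str, str]] = field(default_factory=list)


# --------------------------------------------------------------------------
# intent


_CAUSAL_KEYS = ("why", "cause", "caused", "causes", "lead to", "leads to",
                "result in", "results in", "etiolog", "risk factor",
                "progress")
_MULTIHOP_KEYS = ("for which", "which of the", "via", "through which",
                  "and then")
_DIAGNOSIS_KEYS = ("diagnos", "criteria", "test for", "confirm", "staging",
                   "score")
_SYMPTOM_KEYS = ("symptom", "sign of", "signs of", "manifest", "present with")
_AMBIGUOUS_KEYS = ("feels", "feel ", "something", "stuff", "kind of",
                   "kinda", "thing")


def classify_intent(question: str, classifier=None) -> str:
    """Label the question's intent.

    With no ``classifier``, deterministic keyword rules apply (the mock
    path); a provider-backed classifier, if given, is trusted unless it
    fails or returns an unknown label, in which case the default ``fact``
    is used.
    """
    if classifier is not None:
        try:
            label = classifier(question).strip()
            if label in INTENTS:
                return label
        except Exception:
            pass
        return "fact"
    q = " " + question.casefold() + " "
    if any(key in q for key in _MULTIHOP_KEYS):
        return "multi_hop"
    if any(key in q for key in _CAUSAL_KEYS):
        return "causal"
    if any(key in q for key in _DIAGNOSIS_KEYS):
        return "diagnosis"
    if any(key in q for key in _SYMPTOM_KEYS):
        return "symptom"
    if any(key in q for key in _AMBIGUOUS_KEYS):
        return "ambiguous"
    return "fact"


def intent_to_strategy(intent: str,
                       config: StrategyConfig | None = None) -> SearchStrategy:
    """The pre-defined intent -> search strategy mapping.

    fact / diagnosis / symptom / ambiguous -> BFS at depth 2;
    causal -> DFS at depth 3; multi-hop -> DFS at depth 4.
    """
    config = config or StrategyConfig()
    limit = config.default_node_limit
    if intent in ("fact", "diagnosis", "symptom", "ambiguous"):
        return SearchStrategy("BFS", 2, limit)
    if intent == "causal":
        return SearchStrategy("DFS", 3, limit)
    if intent == "multi_hop":
        return SearchStrategy("DFS", 4, limit)
    raise PlanningError(f"unknown intent label {intent!r}")


# --------------------------------------------------------------------------
# dual-generation query planning


def _parse_payload(text: str, intent: str) -> GraphQuery | None:
    try:
        doc = json.loads(text)
        return GraphQuery(
            anchors=tuple(doc["anchors"]),
            anchor_names=tuple(doc.get("anchor_names", ())),
            relation_types=tuple(doc.get("relations", ())),
            direction=doc.get("direction", "out"),
            intent=intent,
        )
    except (json.JSONDecodeError, KeyError, TypeError):
        return None


def generate_graph_query(
    question: str,
    linked_entities: Sequence[LinkedEntity],
    generator_primary: GeneratorContract,
    generator_secondary: GeneratorContract,
    intent: str | None = None,
    temperature: float = 0.1,
) -> tuple[GraphQuery, float]:
    """Dual-model query generation with a structural consistency check.

    Returns ``(query, C_cypher)`` where C_cypher is 1.0 when both
    providers produced structurally identical queries and 0.5 otherwise
    (the primary's query is used on divergence).
    """
    if not linked_entities:
        raise PlanningError("no linked entities to anchor a graph query")
    intent = intent or classify_intent(question)
    entities_json = json.dumps(
        [{"entity_id": e.entity_id or e.concept_id, "name": e.name,
          "category": e.category} for e in linked_entities],
        sort_keys=True)
    prompt = graph_query_prompt(question, intent, entities_json)
    primary = _parse_payload(
        generator_primary.generate(prompt, temperature), intent)
    secondary = _parse_payload(
        generator_secondary.generate(prompt, temperature), intent)
    if primary is None and secondary is None:
        raise PlanningError("both query generators returned unparseable payloads")
    if primary is None:
        return secondary, 0.5
    if secondary is None:
        return primary, 0.5
    c_cypher = 1.0 if primary.signature() == secondary.signature() else 0.5
    return primary, c_cypher


# --------------------------------------------------------------------------
# semantic validation


def validate_semantics(query: GraphQuery, schema: Schema,
                       graph: PropertyGraph) -> ValidationResult:
    """Check anchor categories against relation direction conventions.

    For the outgoing direction each anchor must be a legal *source* of
    every relation type in the filter; undirected queries accept either
    endpoint role.  An empty relation filter is an unconstrained
    traversal and always validates.
    """
    violations: list[tuple[str, str]] = []
    for anchor in query.anchors:
        ent = graph.entities.get(anchor)
        if ent is None:
            violations.append((anchor, "anchor not present in graph"))
            continue
        for rtype in query.relation_types:
            pair = schema.relation_types.get(rtype)
            if pair is None:
                violations.append((rtype, "unknown relation type"))
                continue
            src, tgt = pair
            if query.direction == "undirected":
                if ent.category not in (src, tgt):
                    violations.append(
                        (rtype, f"anchor category {ent.category!r} is neither "
                                f"source {src!r} nor target {tgt!r}"))
            elif ent.category != src:
                violations.append(
                    (rtype, f"anchor category {ent.category!r} cannot be the "
                            f"source of {rtype} ({src} -> {tgt})"))
    return ValidationResult(ok=not violations, violations=violations)


def validate_and_repair(query: GraphQuery, schema: Schema,
                        graph: PropertyGraph) -> tuple[GraphQuery, ValidationResult]:
    """One rewrite attempt after a semantic-validation failure.

    If flipping to an undirected traversal alone repairs the query (every
    violating relation has the anchor as its *target*), flip; otherwise
    drop the incompatible relation types.  A second failure raises.
    """
    result = validate_semantics(query, schema, graph)
    if result.ok:
        return query, result
    bad_types = {name for name, _ in result.violations
                 if name in schema.relation_types}
    if any(name not in schema.relation_types for name, _ in result.violations):
        raise QueryValidationError(f"unrepairable query: {result.violations}")

    flipped = GraphQuery(query.anchors, query.anchor_names,
                         query.relation_types, "undirected", query.intent)
    if validate_semantics(flipped, schema, graph).ok:
        return flipped, ValidationResult(ok=True)

    kept = tuple(t for t in query.relation_types if t not in bad_types)
    rewritten = GraphQuery(query.anchors, query.anchor_names, kept,
                           query.direction, query.intent)
    final = validate_semantics(rewritten, schema, graph)
    if not final.ok:
        raise QueryValidationError(f"unrepairable query: {final.violations}")
    return rewritten, final


# --------------------------------------------------------------------------
# openCypher rendering


def render_cypher(query: GraphQuery, strategy: SearchStrategy) -> str:
    """Deterministic openCypher text for the validated query.

    The variable-length pattern is bounded by the strategy depth and the
    result set by its node limit; byte-identical across runs.
    """
    rel = "|".join(sorted(query.relation_types))
    reltag = f":{rel}" if rel else ""
    arrow_l, arrow_r = ("-", "-") if query.direction == "undirected" \
        else ("-", "->")
    names = sorted(query.anchor_names)
    if len(names) == 1:
        where = f'n.name = "{names[0]}"'
    else:
        quoted = ", ".join(f'"{n}"' for n in names)
        where = f"n.name IN [{quoted}]"
    return (
        f"MATCH p = (n){arrow_l}[r{reltag}*..{strategy.k}]{arrow_r}(m)\n"
        f"WHERE {where}\n"
        f"RETURN p\n"
        f"LIMIT {strategy.node_limit}"
    )
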