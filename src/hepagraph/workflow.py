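"""The self-correcting agent workflow.

One run of :func:`run` executes the full retrieve-evaluate-refine loop:

1. link the question's entities against the terminology dictionary;
2. plan a graph query with dual-generation consistency checking and
   pre-execution semantic validation (one rewrite attempt);
3. retrieve a context with the intent-selected strategy;
4. loop up to T (default 3) times: dual-model self-consistency voting
   plus objective metrics decide sufficiency; Sufficient ends the loop,
   Insufficient invokes the deterministic strategy optimizer and
   re-executes the *original validated query* with the updated strategy;
5. synthesize an answer with inline [Fn] citations from the retrieved
   facts, or — when linking, planning or retrieval produced nothing
   usable — fall back to a parametric-knowledge answer carrying an
   explicit not-graph-verified warning.

The final confidence combines query-generation consistency, decision
confidence, entity coverage, and mean link confidence, minus an
iteration penalty P = (k - 1) * 0.05 for k evaluate/refine iterations,
clipped to [0, 1].  With mock providers the whole run is byte-for-byte
deterministic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .config import Config
from .decision import (RETRY_SEARCH, USE_CURRENT, ContextMetrics,
                       adjudicate, compute_metrics, optimize_strategy,
                       overall_score, run_votes)
from .errors import (ConfigurationError, HepagraphError, LinkingError,
                     PlanningError, QueryValidationError)
from .graph import PathSet, PropertyGraph, Subgraph
from .linking import Dictionary, LinkedEntity, link_entities
from .planner import (GraphQuery, SearchStrategy, classify_intent,
                      generate_graph_query, intent_to_strategy, render_cypher,
                      validate_and_repair)
from .providers import (GeneratorContract, ProviderSet, fallback_prompt,
                        synthesis_prompt)

_ANCHOR = re.compile(r"\[F\d+\]")


@dataclass
class RetrievedContext:
    """Subgraph and/or paths plus provenance, serializable to fact lines."""

    graph: PropertyGraph
    subgraph: Subgraph | None = None
    paths: PathSet | None = None
    _facts: list[tuple[str, str, str]] | None = field(default=None, repr=False)

    def _relations(self):
        seen: dict[str, object] = {}
        if self.subgraph is not None:
            for rel in self.subgraph.relations:
                seen.setdefault(rel.id, rel)
        if self.paths is not None:
            for path in self.paths.paths:
                for rid in path.relation_ids:
                    rel = self.graph.relation_by_id(rid)
                    if rel is not None:
                        seen.setdefault(rel.id, rel)
        return list(seen.values())

    def node_ids(self) -> set[str]:
        nodes: set[str] = set()
        if self.subgraph is not None:
            nodes.update(self.subgraph.node_ids)
        if self.paths is not None:
            for path in self.paths.paths:
                nodes.update(path.nodes)
        return nodes

    def is_empty(self) -> bool:
        return not self.node_ids()

    def mean_attribute_count(self) -> float:
        nodes = self.node_ids()
        if not nodes:
            return 0.0
        counts = [self.graph.entities[n].attribute_count()
                  for n in nodes if n in self.graph.entities]
        return sum(counts) / len(counts) if counts else 0.0

    def facts(self) -> list[tuple[str, str, str]]:
        """Deterministic fact list: (anchor, relation id, fact text).

        Ordered by (relation type, source id, target id); each fact line
        renders endpoint names, the relation type, and any attributes.
        """
        if self._facts is None:
            rels = sorted(self._relations(),
                          key=lambda r: (r.type, r.source_id, r.target_id, r.id))
            facts = []
            for i, rel in enumerate(rels, start=1):
                src = self.graph.entities[rel.source_id].name
                tgt = self.graph.entities[rel.target_id].name
                if rel.attributes:
                    attrs = ", ".join(f"{k}: {rel.attributes[k]}"
                                      for k in sorted(rel.attributes))
                    middle = f"-[{rel.type} {{{attrs}}}]->"
                else:
                    middle = f"-[{rel.type}]->"
                facts.append((f"[F{i}]", rel.id, f"{src} {middle} {tgt}"))
            self._facts = facts
        return self._facts

    def provenance(self) -> dict[str, str]:
        """anchor token -> relation id."""
        return {anchor: rid for anchor, rid, _ in self.facts()}

    def serialized(self) -> str:
        return "\n".join(f"{anchor} {text}" for anchor, _, text in self.facts())


@dataclass
class ConfidenceBreakdown:
    c_cypher: float
    c_decision: float
    s_coverage: float
    c_entity: float
    k: int
    p_iteration: float
    c_final: float


@dataclass
class FinalAnswer:
    text: str
    confidence: ConfidenceBreakdown
    is_fallback: bool = False
    warning: str = ""
    citations: list[str] = field(default_factory=list)
    context_text: str = ""
    trace: list[dict] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        doc = {
            "text": self.text,
            "confidence": self.confidence.__dict__,
            "is_fallback": self.is_fallback,
            "warning": self.warning,
            "citations": self.citations,
        }
        return json.dumps(doc, indent=indent, sort_keys=True)


# --------------------------------------------------------------------------
# retrieval execution


def execute_query(kg: PropertyGraph, query: GraphQuery,
                  strategy: SearchStrategy) -> RetrievedContext:
    """Run the validated query under the current strategy.

    BFS strategies retrieve the bounded neighborhood; DFS strategies
    enumerate bounded simple paths honoring the relation filter.  Anchors
    absent from the graph are skipped; no anchors at all yields an empty
    (still valid) context.
    """
    anchors = [a for a in query.anchors if a in kg]
    if not anchors:
        return RetrievedContext(graph=kg)
    undirected = query.direction == "undirected"
    rfilter = query.relation_types or None
    if strategy.method == "BFS":
        sub = kg.bfs_neighborhood(anchors, strategy.k, strategy.node_limit,
                                  relation_filter=rfilter, undirected=undirected)
        return RetrievedContext(graph=kg, subgraph=sub)
    paths = kg.dfs_paths(anchors, strategy.k, relation_filter=rfilter,
                         path_limit=strategy.node_limit, undirected=undirected)
    return RetrievedContext(graph=kg, paths=paths)


def integrate_context(context: RetrievedContext) -> str:
    """Serialized fact lines with [Fn] anchors (deterministic)."""
    return context.serialized()


# --------------------------------------------------------------------------
# synthesis and confidence


def synthesize_answer(question: str, context: RetrievedContext,
                      generator: GeneratorContract,
                      temperature: float = 0.1) -> tuple[str, list[str], list[str]]:
    """One generator call; returns (text, citations, stripped anchors).

    Anchors in the generated text that do not resolve to a context fact
    are stripped and reported.
    """
    serialized = context.serialized()
    if not serialized:
        raise PlanningError("cannot synthesize from an empty context")
    raw = generator.generate(synthesis_prompt(question, serialized), temperature)
    valid = set(context.provenance())
    stripped: list[str] = []

    def _keep(match: re.Match) -> str:
        anchor = match.group(0)
        if anchor in valid:
            return anchor
        stripped.append(anchor)
        return ""

    text = _ANCHOR.sub(_keep, raw)
    citations = sorted(set(_ANCHOR.findall(text)),
                       key=lambda a: int(a[2:-1]))
    return text, citations, stripped


def final_confidence(c_cypher: float, c_decision: float, s_coverage: float,
                     c_entity: float, k: int,
                     config: Config | None = None) -> ConfidenceBreakdown:
    """Weighted confidence minus the iteration penalty, clipped to [0, 1]."""
    cfg = (config or Config()).confidence
    cfg.check()
    for name, value in (("c_cypher", c_cypher), ("c_decision", c_decision),
                        ("s_coverage", s_coverage), ("c_entity", c_entity)):
        if not 0.0 <= value <= 1.0:
            raise ConfigurationError(f"{name}={value} outside [0, 1]")
    if k < 1:
        raise ConfigurationError("iteration count k must be >= 1")
    p_iteration = (k - 1) * cfg.iteration_penalty
    raw = (cfg.w_cypher * c_cypher + cfg.w_decision * c_decision
           + cfg.w_coverage * s_coverage + cfg.w_entity * c_entity
           - p_iteration)
    return ConfidenceBreakdown(
        c_cypher=c_cypher, c_decision=c_decision, s_coverage=s_coverage,
        c_entity=c_entity, k=k, p_iteration=p_iteration,
        c_final=min(1.0, max(0.0, raw)),
    )


def fallback_answer(question: str, generator: GeneratorContract,
                    reason: str = "no graph evidence",
                    trace: list[dict] | None = None) -> FinalAnswer:
    """Parametric-knowledge answer with a mandatory warning.

    All graph-evidence confidence components are zero; a generator
    failure degrades to a static apology text rather than raising.
    """
    try:
        text = generator.generate(fallback_prompt(question))
    except Exception:
        text = ("I could not produce a graph-verified answer to this "
                "question; please consult the relevant clinical guideline.")
    warning = ("WARNING: this answer is NOT verified against the knowledge "
               f"graph ({reason}); it relies on general model knowledge only.")
    breakdown = final_confidence(0.0, 0.0, 0.0, 0.0, k=1)
    return FinalAnswer(text=text, confidence=breakdown, is_fallback=True,
                       warning=warning, citations=[], trace=trace or [])


# --------------------------------------------------------------------------
# the state machine


def run(question: str, kg: PropertyGraph, dictionary: Dictionary,
        providers: ProviderSet, config: Config | None = None,
        trace_path: str | Path | None = None) -> FinalAnswer:
    """Execute the full agent loop for one question.  Never raises."""
    config = config or Config()
    trace: list[dict] = []

    def note(event: str, **payload) -> None:
        trace.append({"event": event, **payload})

    def finish(answer: FinalAnswer) -> FinalAnswer:
        answer.trace = trace
        if trace_path is not None:
            with open(trace_path, "w", encoding="utf-8") as fh:
                for entry in trace:
                    fh.write(json.dumps(entry, sort_keys=True, default=str)
                             + "\n")
        return answer

    note("question", text=question)

    # 1. entity linking
    try:
        linked = link_entities(question, dictionary, kg, providers.embedder,
                               config.linker)
    except LinkingError as exc:
        note("linking_failure", error=str(exc))
        return finish(fallback_answer(question, providers.generator_primary,
                                      reason="entity linking failed"))
    note("linked", entities=[{"span": e.query_span, "concept": e.concept_id,
                              "entity_id": e.entity_id,
                              "confidence": round(e.confidence, 4)}
                             for e in linked])
    if not linked:
        note("linking_failure", error="no span linked to any concept")
        return finish(fallback_answer(question, providers.generator_primary,
                                      reason="entity linking failed"))

    # 2. plan + validate
    intent = classify_intent(question)
    note("intent", label=intent)
    try:
        query, c_cypher = generate_graph_query(
            question, linked, providers.generator_primary,
            providers.generator_secondary, intent=intent,
            temperature=config.workflow.temperature)
        query, _validation = validate_and_repair(query, kg.schema, kg)
    except (PlanningError, QueryValidationError) as exc:
        note("planning_failure", error=str(exc))
        return finish(fallback_answer(question, providers.generator_primary,
                                      reason=f"query planning failed: {exc}"))
    strategy = intent_to_strategy(intent, config.strategy)
    note("planned", anchors=list(query.anchors),
         relations=list(query.relation_types), c_cypher=c_cypher,
         cypher=render_cypher(query, strategy))

    # 3. initial retrieval
    context = execute_query(kg, query, strategy)
    note("retrieved", n_nodes=len(context.node_ids()),
         n_facts=len(context.facts()))

    # 4. evaluate / refine loop
    base_seed = config.providers.seed
    decision = None
    metrics: ContextMetrics | None = None
    iterations = 0
    for t in range(1, config.workflow.max_iterations + 1):
        iterations = t
        serialized = context.serialized()
        vote_p = run_votes(question, serialized, providers.judge_primary,
                           n=config.decision.n_votes, seed=base_seed + 100 * t,
                           model_id="primary")
        vote_s = run_votes(question, serialized, providers.judge_secondary,
                           n=config.decision.n_votes,
                           seed=base_seed + 100 * t + 50, model_id="secondary")
        metrics = compute_metrics(question, context, linked,
                                  providers.embedder, config.decision)
        score = overall_score(metrics, config.decision)
        decision = adjudicate(vote_p, vote_s, score, config.decision)
        note("decision", iteration=t, action=decision.action,
             score=round(score, 4), c_decision=round(decision.c_decision, 4),
             votes=[vote_p.votes, vote_s.votes], rationale=decision.rationale)
        if decision.action == USE_CURRENT:
            break
        strategy, otrace = optimize_strategy(strategy, metrics,
                                             config.decision, config.strategy,
                                             iteration=t)
        note("optimized", iteration=t, rule=otrace.rule,
             field=otrace.field_changed, old=otrace.old_value,
             new=otrace.new_value)
        context = execute_query(kg, query, strategy)
        note("retrieved", n_nodes=len(context.node_ids()),
             n_facts=len(context.facts()))

    # 5. synthesis or fallback
    if context.is_empty():
        note("empty_context")
        return finish(fallback_answer(question, providers.generator_primary,
                                      reason="retrieval returned no context"))
    text, citations, stripped = synthesize_answer(
        question, context, providers.generator_primary,
        temperature=config.workflow.temperature)
    if stripped:
        note("stripped_anchors", anchors=stripped)
    c_entity = sum(e.confidence for e in linked) / len(linked)
    breakdown = final_confidence(
        c_cypher=c_cypher,
        c_decision=decision.c_decision if decision else 0.0,
        s_coverage=metrics.coverage if metrics else 0.0,
        c_entity=min(1.0, c_entity),
        k=iterations,
        config=config,
    )
    note("answer", c_final=round(breakdown.c_final, 4),
         citations=citations, k=iterations)
    return finish(FinalAnswer(text=text, confidence=breakdown,
                              is_fallback=False, warning="",
                              citations=citations,
                              context_text=context.serialized()))
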