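"""Context-sufficiency decision and deterministic strategy refinement.

Two judge models each cast ``n`` (default 3) independent self-consistency
votes on whether the retrieved context suffices to answer the question;
each model's majority forms its preliminary decision with internal
consistency

    C_internal = max(N_sufficient, N_insufficient) / N_total.

In parallel, objective context metrics are computed — entity coverage,
node count, information density (mean attributes per node) and semantic
relevance (cosine of query vs serialized context) — and combined into

    Score_overall = w_sem * S_sem + w_cov * Norm(N_nodes) + w_den * Norm(D_avg)

with default weights 0.4 / 0.3 / 0.3 and fixed-reference clipping
Norm(x) = min(x / x_ref, 1).  When the two models agree, their shared
verdict stands; on disagreement the score arbitrates: above tau_high the
context is Sufficient, below tau_low Insufficient, and in between the
conservative choice (Insufficient) is taken.

An Insufficient verdict triggers the deterministic strategy optimizer, a
first-match rule tree over the metrics: low coverage deepens the search,
low semantic relevance switches BFS<->DFS (once) or widens the node
limit, low density widens the node limit.  Exactly one rule fires per
iteration, so every refinement is minimal and attributable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .config import DecisionConfig, StrategyConfig
from .errors import ConfigurationError
from .linking import LinkedEntity
from .planner import SearchStrategy
from .providers import EmbedderContract, JudgeContract, cosine

USE_CURRENT = "USE_CURRENT"
RETRY_SEARCH = "RETRY_SEARCH"
FALLBACK = "FALLBACK"


@dataclass
class VoteRecord:
    model_id: str
    votes: list[str]                 # "sufficient" | "insufficient"
    decision: str                    # majority verdict
    c_internal: float                # max(N_s, N_i) / N_total
    errors: list[str] = field(default_factory=list)


@dataclass
class ContextMetrics:
    coverage: float                  # linked entities present in context
    n_nodes: int
    density: float                   # mean attribute count per node
    s_sem: float                     # clamped cosine(question, context)
    norm_nodes: float
    norm_density: float


@dataclass
class DecisionResult:
    action: str                      # USE_CURRENT | RETRY_SEARCH
    vote_primary: VoteRecord
    vote_secondary: VoteRecord
    score_overall: float
    c_decision: float
    rationale: str


@dataclass
class OptimizeTrace:
    iteration: int
    rule: str                        # "coverage" | "semantic" | "density" | "none"
    field_changed: str
    old_value: object
    new_value: object


def run_votes(question: str, context_text: str, judge: JudgeContract,
              n: int = 3, seed: int = 0, model_id: str = "judge") -> VoteRecord:
    """``n`` independent seeded votes, majority decision, C_internal.

    A judge failure on an individual call is logged and counted as an
    insufficient vote.
    """
    if n % 2 == 0:
        raise ConfigurationError("vote count must be odd")
    votes: list[str] = []
    errors: list[str] = []
    for i in range(n):
        try:
            votes.append(judge.vote(question, context_text, seed=seed + i))
        except Exception as exc:
            votes.append(JudgeContract.INSUFFICIENT)
            errors.append(f"vote {i}: {exc}")
    n_suff = votes.count(JudgeContract.SUFFICIENT)
    n_insuff = n - n_suff
    decision = JudgeContract.SUFFICIENT if n_suff > n_insuff \
        else JudgeContract.INSUFFICIENT
    return VoteRecord(model_id=model_id, votes=votes, decision=decision,
                      c_internal=max(n_suff, n_insuff) / n, errors=errors)


def compute_metrics(question: str, context, linked_entities: Sequence[LinkedEntity],
                    embedder: EmbedderContract,
                    config: DecisionConfig | None = None) -> ContextMetrics:
    """Objective context metrics for a retrieved context.

    ``context`` is any object exposing ``node_ids()``-like content via
    the workflow's RetrievedContext (``subgraph_nodes`` and
    ``serialized``); an empty context yields all-zero metrics.  With no
    linked entities at all, coverage degenerates to 1.0.
    """
    config = config or DecisionConfig()
    node_ids = context.node_ids()
    n_nodes = len(node_ids)
    if n_nodes == 0:
        return ContextMetrics(0.0, 0, 0.0, 0.0, 0.0, 0.0)
    if linked_entities:
        resolved = [e.entity_id for e in linked_entities if e.entity_id]
        covered = sum(1 for eid in resolved if eid in node_ids)
        coverage = covered / len(linked_entities)
    else:
        coverage = 1.0  # degenerate: nothing to cover
    density = context.mean_attribute_count()
    s_sem = max(0.0, cosine(embedder.embed(question),
                            embedder.embed(context.serialized())))
    return ContextMetrics(
        coverage=coverage,
        n_nodes=n_nodes,
        density=density,
        s_sem=s_sem,
        norm_nodes=min(n_nodes / config.norm_nodes_ref, 1.0),
        norm_density=min(density / config.norm_density_ref, 1.0),
    )


def overall_score(metrics: ContextMetrics,
                  config: DecisionConfig | None = None) -> float:
    """The weighted sufficiency score (defaults 0.4 / 0.3 / 0.3)."""
    config = config or DecisionConfig()
    config.check()
    return (config.w_sem * metrics.s_sem
            + config.w_cov * metrics.norm_nodes
            + config.w_den * metrics.norm_density)


def adjudicate(vote_primary: VoteRecord, vote_secondary: VoteRecord,
               score_overall: float,
               config: DecisionConfig | None = None) -> DecisionResult:
    """Combine the two model verdicts, arbitrating disagreement by score.

    Agreement: the shared verdict stands and the decision confidence is
    the mean of the two internal consistencies.  Disagreement: the
    objective score decides (> tau_high Sufficient, < tau_low
    Insufficient, between the two Insufficient by clinical conservatism);
    the decision confidence then grows with the score's distance from the
    threshold midpoint, scaled into [0.5, 1].
    """
    config = config or DecisionConfig()
    if vote_primary.decision == vote_secondary.decision:
        decision = vote_primary.decision
        c_decision = (vote_primary.c_internal + vote_secondary.c_internal) / 2
        rationale = f"models agree: {decision}"
    else:
        if score_overall > config.tau_high:
            decision = JudgeContract.SUFFICIENT
            rationale = (f"disagreement; score {score_overall:.3f} > "
                         f"tau_high {config.tau_high}")
        elif score_overall < config.tau_low:
            decision = JudgeContract.INSUFFICIENT
            rationale = (f"disagreement; score {score_overall:.3f} < "
                         f"tau_low {config.tau_low}")
        else:
            decision = JudgeContract.INSUFFICIENT
            rationale = (f"disagreement; score {score_overall:.3f} between "
                         "thresholds -> conservative Insufficient")
        midpoint = (config.tau_high + config.tau_low) / 2
        span = max(midpoint, 1.0 - midpoint)
        c_decision = 0.5 + 0.5 * min(abs(score_overall - midpoint) / span, 1.0)
    action = USE_CURRENT if decision == JudgeContract.SUFFICIENT else RETRY_SEARCH
    return DecisionResult(action=action, vote_primary=vote_primary,
                          vote_secondary=vote_secondary,
                          score_overall=score_overall,
                          c_decision=c_decision, rationale=rationale)


def optimize_strategy(strategy: SearchStrategy, metrics: ContextMetrics,
                      config: DecisionConfig | None = None,
                      limits: StrategyConfig | None = None,
                      iteration: int = 1) -> tuple[SearchStrategy, OptimizeTrace]:
    """Apply the first triggered refinement rule to a copy of the strategy.

    Rule order: (1) coverage below threshold and depth below its cap ->
    deepen by one; (2) semantic relevance below threshold -> toggle
    BFS<->DFS if not yet switched, else double the node limit (capped);
    (3) density below threshold -> double the node limit (capped).  No
    rule triggered -> identity with a "none" trace.
    """
    config = config or DecisionConfig()
    limits = limits or StrategyConfig()
    new = strategy.copy()

    if metrics.coverage < config.tau_coverage and strategy.k < limits.k_max:
        new.k = strategy.k + 1
        trace = OptimizeTrace(iteration, "coverage", "k", strategy.k, new.k)
    elif metrics.s_sem < config.tau_semantic:
        if not strategy.switched:
            new.method = "DFS" if strategy.method == "BFS" else "BFS"
            new.switched = True
            trace = OptimizeTrace(iteration, "semantic", "method",
                                  strategy.method, new.method)
        else:
            new.node_limit = min(strategy.node_limit * 2, limits.limit_max)
            trace = OptimizeTrace(iteration, "semantic", "node_limit",
                                  strategy.node_limit, new.node_limit)
    elif metrics.density < config.tau_density:
        new.node_limit = min(strategy.node_limit * 2, limits.limit_max)
        trace = OptimizeTrace(iteration, "density", "node_limit",
                              strategy.node_limit, new.node_limit)
    else:
        trace = OptimizeTrace(iteration, "none", "", None, None)
    return new, trace
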