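"""Configuration for the agentic workflow.

All weights, thresholds, and reference maxima live here with their
defaults and can be overridden from a single YAML document, e.g.::

    decision:
      tau_high: 0.7
      tau_low: 0.4
    confidence:
      w_cypher: 0.3
    providers:
      backend: mock
      seed: 7

Defaults follow the framework's published operating point: sufficiency
score weights 0.4/0.3/0.3 (semantic relevance / normalized node count /
normalized density), fuzzy-link threshold 0.8, shallow BFS depth 2 for
factual intents vs DFS depth 3–4 for causal/multi-hop intents, a
three-iteration refinement cap, and an iteration penalty of 0.05 per
extra retrieval pass in the final confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class LinkerConfig:
    threshold: float = 0.8           # strict: candidates need s_fuzzy > threshold
    w_fuzzy: float = 0.5
    w_semantic: float = 0.5
    disambiguation_margin: float = 0.05
    max_ngram: int = 5


@dataclass
class DecisionConfig:
    w_sem: float = 0.4
    w_cov: float = 0.3
    w_den: float = 0.3
    tau_high: float = 0.70
    tau_low: float = 0.40
    tau_coverage: float = 0.5
    tau_semantic: float = 0.5
    tau_density: float = 0.4
    norm_nodes_ref: float = 20.0     # Norm(N_nodes) = min(N / ref, 1)
    norm_density_ref: float = 5.0    # Norm(D_avg)   = min(D / ref, 1)
    n_votes: int = 3

    def check(self) -> None:
        total = self.w_sem + self.w_cov + self.w_den
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"decision weights must sum to 1, got {total}")
        if not self.tau_low < self.tau_high:
            raise ConfigurationError("require tau_low < tau_high")
        if self.n_votes % 2 == 0:
            raise ConfigurationError("n_votes must be odd")


@dataclass
class ConfidenceConfig:
    w_cypher: float = 0.3
    w_decision: float = 0.3
    w_coverage: float = 0.2
    w_entity: float = 0.2
    iteration_penalty: float = 0.05  # P_iteration = (k - 1) * penalty

    def check(self) -> None:
        total = self.w_cypher + self.w_decision + self.w_coverage + self.w_entity
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"confidence weights must sum to 1, got {total}")


@dataclass
class StrategyConfig:
    default_node_limit: int = 50
    k_max: int = 4
    limit_max: int = 200


@dataclass
class WorkflowConfig:
    max_iterations: int = 3          # refinement loop bound T
    temperature: float = 0.1         # passed to real providers; mocks ignore it


@dataclass
class ProviderConfig:
    backend: str = "mock"            # "mock" | "real"
    seed: int = 0
    judge_overlap_threshold: float = 0.2
    embed_dim: int = 64


@dataclass
class Config:
    linker: LinkerConfig = field(default_factory=LinkerConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    confidence: ConfidenceConfig = field(default_factory=ConfidenceConfig)
    strategy: StrategyConfig = field(default_factory=StrategyConfig)
    workflow: WorkflowConfig = field(default_factory=WorkflowConfig)
    providers: ProviderConfig = field(default_factory=ProviderConfig)

    def check(self) -> "Config":
        self.decision.check()
        self.confidence.check()
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "Config":
        cfg = cls()
        for section in fields(cls):
            block = doc.get(section.name)
            if block is None:
                continue
            target = getattr(cfg, section.name)
            allowed = {f.name for f in fields(target)}
            for key, value in block.items():
                if key not in allowed:
                    raise ConfigurationError(
                        f"unknown option {section.name}.{key}")
                setattr(target, key, value)
        return cfg.check()
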