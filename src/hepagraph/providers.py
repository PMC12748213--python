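"""Provider contracts and deterministic seeded mocks.

Three external capabilities back the framework: text generation, context
sufficiency judging, and text embedding.  Each is a small contract class;
the mock implementations below are fully deterministic (explicit hashing,
no reliance on Python hash randomization), so the entire agent loop and
evaluation suite run offline and reproducibly.

Prompts produced by this package start with a ``TASK: <name>`` line
(``synthesize``, ``graph_query``, ``extract_statements``,
``generate_questions``, ``fallback``) followed by labelled sections; the
mock generator dispatches on the task line, while a real chat-model
backend would receive the same prompt with full natural-language
instructions.  Test hooks (forced or scripted judges) are first-class:
without them the refinement branches of the agent loop cannot be reached
deterministically.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

import numpy as np

from .config import ProviderConfig
from .errors import ProviderError

_TOKEN = re.compile(r"[a-z0-9]+")

STOPWORDS = frozenset(
    "a an and are be by can do does for from has have how i in is it me my of "
    "off on or should that the this to was what when which who with".split()
)


def tokenize(text: str) -> list[str]:
    return _TOKEN.findall(text.casefold())


def content_tokens(text: str) -> set[str]:
    return {t for t in tokenize(text) if t not in STOPWORDS and len(t) >= 2}


# --------------------------------------------------------------------------
# contracts


class GeneratorContract:
    """Stateless text generation: same (prompt, seed) -> same text (mock)."""

    def generate(self, prompt: str, temperature: float = 0.1,
                 seed: int | None = None) -> str:
        raise NotImplementedError


class JudgeContract:
    """Binary sufficiency vote over (question, context)."""

    SUFFICIENT = "sufficient"
    INSUFFICIENT = "insufficient"

    def vote(self, question: str, context_text: str,
             seed: int | None = None) -> str:
        raise NotImplementedError


class EmbedderContract:
    """Deterministic fixed-length embeddings; identical text -> identical vector."""

    def embed(self, text: str) -> np.ndarray:
        raise NotImplementedError


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


# --------------------------------------------------------------------------
# prompt builders (shared by mock and real backends)


def synthesis_prompt(question: str, context_text: str) -> str:
    return (
        "TASK: synthesize\n"
        "Answer the clinical question strictly from the context facts; "
        "cite each fact with its inline [Fn] anchor.\n"
        f"QUESTION: {question}\n"
        f"CONTEXT:\n{context_text}"
    )


def graph_query_prompt(question: str, intent: str, entities_json: str) -> str:
    return (
        "TASK: graph_query\n"
        "Emit a JSON object {anchors, anchor_names, relations, direction, "
        "depth_hint} describing the graph query for this question.\n"
        f"INTENT: {intent}\n"
        f"ENTITIES: {entities_json}\n"
        f"QUESTION: {question}"
    )


def statement_prompt(answer: str) -> str:
    return (
        "TASK: extract_statements\n"
        "List the atomic factual statements in the answer as a JSON array "
        "of strings.\n"
        f"ANSWER: {answer}"
    )


def question_gen_prompt(answer: str, n: int) -> str:
    return (
        "TASK: generate_questions\n"
        f"Write {n} questions this answer would be a good answer to, as a "
        "JSON array of strings.\n"
        f"N: {n}\n"
        f"ANSWER: {answer}"
    )


def fallback_prompt(question: str) -> str:
    return (
        "TASK: fallback\n"
        "Answer from general medical knowledge only; the knowledge graph "
        "provided no usable evidence.\n"
        f"QUESTION: {question}"
    )


_SECTION = re.compile(r"^(QUESTION|CONTEXT|INTENT|ENTITIES|ANSWER|N):",
                      re.MULTILINE)


def _prompt_section(prompt: str, name: str) -> str:
    """Text of one labelled section of a package-built prompt."""
    marker = f"{name}:"
    start = prompt.find(marker)
    if start < 0:
        return ""
    start += len(marker)
    nxt = _SECTION.search(prompt, start)
    return prompt[start:nxt.start()] if nxt else prompt[start:]


# --------------------------------------------------------------------------
# mock implementations


_INTENT_RELATIONS = {
    "fact": (),
    "diagnosis": ("IS_DIAGNOSED_BY", "REQUIRES_CRITERIA"),
    "symptom": ("HAS_SYMPTOM",),
    "causal": ("IS_CAUSED_BY", "PROGRESSES_TO"),
    "multi_hop": (),
    "ambiguous": (),
}


@dataclass
class MockGenerator(GeneratorContract):
    """Deterministic template generator.

    ``query_variant`` perturbs graph-query payloads ("default" |
    "no_filter" | "undirected") so that dual-generation disagreement is
    reachable in tests.
    """

    seed: int = 0
    query_variant: str = "default"

    def generate(self, prompt: str, temperature: float = 0.1,
                 seed: int | None = None) -> str:
        task = prompt.splitlines()[0].removeprefix("TASK: ").strip()
        if task == "synthesize":
            return self._synthesize(prompt)
        if task == "graph_query":
            return self._graph_query(prompt)
        if task == "extract_statements":
            answer = _prompt_section(prompt, "ANSWER").strip()
            return json.dumps(_sentences(answer))
        if task == "generate_questions":
            return self._questions(prompt)
        if task == "fallback":
            question = _prompt_section(prompt, "QUESTION").strip()
            return ("General-knowledge response (not graph-verified): "
                    f"regarding '{question}', consult the relevant clinical "
                    "guideline; no graph evidence was available.")
        return f"[mock:{task}]"

    def _synthesize(self, prompt: str) -> str:
        context = _prompt_section(prompt, "CONTEXT")
        facts = [ln.strip() for ln in context.splitlines()
                 if ln.strip().startswith("[F")]
        if not facts:
            return "No supporting facts were retrieved."
        lines = []
        for fact in facts:
            anchor, _, text = fact.partition(" ")
            lines.append(f"{text.rstrip('.')} {anchor}.")
        return " ".join(lines)

    def _graph_query(self, prompt: str) -> str:
        intent = _prompt_section(prompt, "INTENT").strip()
        entities = json.loads(_prompt_section(prompt, "ENTITIES").strip() or "[]")
        relations = list(_INTENT_RELATIONS.get(intent, ()))
        direction = "out"
        if self.query_variant == "no_filter":
            relations = []
        elif self.query_variant == "undirected":
            direction = "undirected"
        payload = {
            "anchors": [e["entity_id"] for e in entities],
            "anchor_names": [e["name"] for e in entities],
            "relations": relations,
            "direction": direction,
            "depth_hint": None,
        }
        return json.dumps(payload, sort_keys=True)

    def _questions(self, prompt: str) -> str:
        n = int(_prompt_section(prompt, "N").strip() or "3")
        answer = _prompt_section(prompt, "ANSWER").strip()
        sentences = _sentences(answer) or [answer]
        out = [sentences[i % len(sentences)] for i in range(n)]
        return json.dumps(out)


def _sentences(text: str) -> list[str]:
    parts = re.split(r"(?<=[.!?])\s+", text.strip())
    return [p.strip() for p in parts if p.strip()]


@dataclass
class MockJudge(JudgeContract):
    """Token-overlap sufficiency judge with test hooks.

    ``mode``: "overlap" (default rule: sufficient iff the fraction of the
    question's content tokens present in the context is >= threshold),
    "always_sufficient", "always_insufficient", or "scripted" (cycles
    through ``script``).
    """

    overlap_threshold: float = 0.2
    mode: str = "overlap"
    script: list[str] = field(default_factory=list)
    _cursor: int = field(default=0, repr=False)

    def vote(self, question: str, context_text: str,
             seed: int | None = None) -> str:
        if self.mode == "always_sufficient":
            return self.SUFFICIENT
        if self.mode == "always_insufficient":
            return self.INSUFFICIENT
        if self.mode == "scripted":
            if not self.script:
                raise ProviderError("scripted judge has an empty script")
            vote = self.script[self._cursor % len(self.script)]
            self._cursor += 1
            return vote
        qtokens = content_tokens(question)
        if not qtokens:
            return self.INSUFFICIENT
        ctokens = content_tokens(context_text)
        overlap = len(qtokens & ctokens) / len(qtokens)
        return self.SUFFICIENT if overlap >= self.overlap_threshold \
            else self.INSUFFICIENT


@dataclass
class HashEmbedder(EmbedderContract):
    """Seeded hashed-token-count embeddings.

    Each token hashes (MD5 of ``"{seed}:{token}"``) to one of ``dim``
    signed coordinates; the vector is the signed token-count histogram.
    Identical texts embed identically, so cos(v, v) = 1, and texts with
    disjoint vocabularies are (near-)orthogonal.
    """

    dim: int = 64
    seed: int = 0

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=float)
        for token in tokenize(text):
            digest = hashlib.md5(f"{self.seed}:{token}".encode()).digest()
            idx = int.from_bytes(digest[:4], "big") % self.dim
            sign = 1.0 if digest[4] % 2 == 0 else -1.0
            vec[idx] += sign
        return vec


# --------------------------------------------------------------------------
# provider set


@dataclass
class ProviderSet:
    generator_primary: GeneratorContract
    generator_secondary: GeneratorContract
    judge_primary: JudgeContract
    judge_secondary: JudgeContract
    embedder: EmbedderContract


def make_provider_set(config: ProviderConfig | None = None) -> ProviderSet:
    """Build the five providers named by the configuration.

    The "mock" backend needs no network.  A "real" backend would wrap an
    OpenAI-compatible chat client reading credentials from the
    environment; it is not bundled, and requesting it raises a
    :class:`ProviderError` that the workflow converts into a warned
    fallback.
    """
    config = config or ProviderConfig()
    if config.backend == "mock":
        return ProviderSet(
            generator_primary=MockGenerator(seed=config.seed),
            generator_secondary=MockGenerator(seed=config.seed + 1),
            judge_primary=MockJudge(overlap_threshold=config.judge_overlap_threshold),
            judge_secondary=MockJudge(overlap_threshold=config.judge_overlap_threshold),
            embedder=HashEmbedder(dim=config.embed_dim, seed=config.seed),
        )
    if config.backend == "real":
        raise ProviderError(
            "no real LLM backend is bundled; install and configure an "
            "OpenAI-compatible client, or use backend='mock'")
    raise ProviderError(f"unknown provider backend {config.backend!r}")
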