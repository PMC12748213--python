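"""RAG evaluation metrics and batch reporting.

Three answer-quality metrics, all provider-backed so they run offline
under the deterministic mocks:

* **faithfulness** F = |V| / |S| — the fraction of the answer's atomic
  statements (extracted by a generator; the mock splits sentences) that a
  judge can verify against the retrieved context;
* **context recall** CR — the fraction of gold-answer sentences a judge
  can attribute to the retrieved context;
* **answer relevancy** AR — the mean embedding cosine between the
  original question and ``n`` questions regenerated from the answer.

:func:`evaluate_run` scores a batch of records and aggregates per
category and overall; :func:`linker_benchmark` computes the entity
linker's micro-averaged precision / recall / F1 against gold links.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .config import Config
from .errors import MetricError
from .fixtures import EvalRecord
from .graph import PropertyGraph
from .linking import Dictionary, link_entities
from .providers import (EmbedderContract, GeneratorContract, JudgeContract,
                        ProviderSet, cosine, question_gen_prompt,
                        statement_prompt, _sentences)
from . import workflow


@dataclass
class MetricResult:
    per_record: pd.DataFrame
    overall: dict[str, float]
    per_category: dict[str, dict[str, float]]
    errors: list[str] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({
            "overall": self.overall,
            "per_category": self.per_category,
            "n_records": int(len(self.per_record)),
            "errors": self.errors,
        }, indent=indent, sort_keys=True)

    def to_csv(self, path) -> None:
        self.per_record.to_csv(path, index=False)


def faithfulness(answer: str, context_text: str,
                 generator: GeneratorContract, judge: JudgeContract,
                 ) -> tuple[float, list[str], list[bool]]:
    """F = verified statements / total statements."""
    if not answer.strip():
        raise MetricError("faithfulness is undefined for an empty answer")
    raw = generator.generate(statement_prompt(answer))
    try:
        statements = [s for s in json.loads(raw) if isinstance(s, str) and s.strip()]
    except json.JSONDecodeError:
        statements = _sentences(raw)
    if not statements:
        raise MetricError("no statements could be extracted from the answer")
    verified = [judge.vote(stmt, context_text) == JudgeContract.SUFFICIENT
                for stmt in statements]
    return sum(verified) / len(statements), statements, verified


def context_recall(gold_answer: str, context_text: str,
                   judge: JudgeContract) -> float:
    """CR = gold sentences attributable to the context / total gold sentences."""
    if not gold_answer.strip():
        raise MetricError("context recall is undefined for an empty gold answer")
    sentences = _sentences(gold_answer) or [gold_answer]
    attributed = sum(
        1 for s in sentences
        if judge.vote(s, context_text) == JudgeContract.SUFFICIENT)
    return attributed / len(sentences)


def answer_relevancy(question: str, answer: str,
                     generator: GeneratorContract,
                     embedder: EmbedderContract, n: int = 3) -> float:
    """AR = mean cosine(question, regenerated question_i), i = 1..n."""
    if not answer.strip():
        raise MetricError("answer relevancy is undefined for an empty answer")
    if n < 1:
        raise MetricError("n must be >= 1")
    raw = generator.generate(question_gen_prompt(answer, n))
    try:
        generated = [q for q in json.loads(raw) if isinstance(q, str)]
    except json.JSONDecodeError as exc:
        raise MetricError(f"question generator returned non-JSON: {exc}") from exc
    if not generated:
        raise MetricError("question generator returned no questions")
    qvec = embedder.embed(question)
    sims = [cosine(qvec, embedder.embed(q)) for q in generated[:n]]
    return sum(sims) / len(sims)


def evaluate_run(records: Sequence[EvalRecord], providers: ProviderSet,
                 n_questions: int = 3) -> MetricResult:
    """Score every record; aggregate over records whose metrics are defined."""
    rows = []
    errors: list[str] = []
    for i, rec in enumerate(records):
        row: dict = {"index": i, "category": rec.category,
                     "question": rec.question}
        try:
            f, _, _ = faithfulness(rec.answer, rec.context_text,
                                   providers.generator_primary,
                                   providers.judge_primary)
            row["faithfulness"] = f
        except MetricError as exc:
            errors.append(f"record {i}: faithfulness: {exc}")
            row["faithfulness"] = float("nan")
        try:
            row["context_recall"] = context_recall(
                rec.gold, rec.context_text, providers.judge_primary)
        except MetricError as exc:
            errors.append(f"record {i}: context_recall: {exc}")
            row["context_recall"] = float("nan")
        try:
            row["answer_relevancy"] = answer_relevancy(
                rec.question, rec.answer, providers.generator_primary,
                providers.embedder, n=n_questions)
        except MetricError as exc:
            errors.append(f"record {i}: answer_relevancy: {exc}")
            row["answer_relevancy"] = float("nan")
        rows.append(row)
    frame = pd.DataFrame(rows)
    metric_cols = ["faithfulness", "context_recall", "answer_relevancy"]
    overall = {m: float(frame[m].mean(skipna=True)) for m in metric_cols}
    per_category = {
        str(cat): {m: float(sub[m].mean(skipna=True)) for m in metric_cols}
        for cat, sub in frame.groupby("category")
    }
    return MetricResult(per_record=frame, overall=overall,
                        per_category=per_category, errors=errors)


def answer_questions(records: Sequence[EvalRecord], kg: PropertyGraph,
                     dictionary: Dictionary, providers: ProviderSet,
                     config: Config | None = None) -> list[EvalRecord]:
    """Run the agent on every question, filling answers and contexts."""
    out = []
    for rec in records:
        answer = workflow.run(rec.question, kg, dictionary, providers, config)
        out.append(EvalRecord(
            question=rec.question, category=rec.category, gold=rec.gold,
            gold_links=list(rec.gold_links), answer=answer.text,
            context_text=answer.context_text))
    return out


def linker_benchmark(records: Sequence[EvalRecord], dictionary: Dictionary,
                     kg: PropertyGraph | None = None,
                     embedder: EmbedderContract | None = None,
                     ) -> dict[str, float]:
    """Micro-averaged precision / recall / F1 of the linker vs gold links."""
    tp = fp = fn = 0
    for rec in records:
        predicted = {l.concept_id
                     for l in link_entities(rec.question, dictionary, kg,
                                            embedder)}
        gold = set(rec.gold_links)
        tp += len(predicted & gold)
        fp += len(predicted - gold)
        fn += len(gold - predicted)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}
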