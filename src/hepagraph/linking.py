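"""Multi-stage entity linking.

Question spans are detected by a dictionary-driven longest-match scan over
token n-grams, then resolved in stages:

1. **exact** — casefolded lookup against every canonical name and synonym;
2. **fuzzy** — Levenshtein similarity ``S_fuzzy = 1 - dist / max(len)``,
   keeping entries whose score strictly exceeds the threshold (0.8);
3. **semantic** — cosine similarity between the query-span embedding and
   each candidate's canonical-name embedding;
4. **composite** — ``w_f * S_fuzzy + w_s * max(0, S_semantic)`` (defaults
   0.5 / 0.5; the clamp keeps the composite in [0, 1]), with a
   context-based disambiguation step: when the top two composites are
   within the margin (0.05), the candidate whose entity category matches
   the question's intent keywords is preferred.

The winning candidate's composite becomes the link confidence that later
feeds the final answer confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .builder import normalize_name
from .config import LinkerConfig
from .errors import LinkingError
from .graph import PropertyGraph
from .providers import EmbedderContract, cosine, tokenize
from .schema import CRITERIA, DISEASE, DRUG, ETIOLOGY, EXAM, GENE, SYMPTOM, TREATMENT


@dataclass(frozen=True)
class DictEntry:
    concept_id: str
    canonical: str
    synonyms: tuple[str, ...]
    category: str

    def surface_forms(self) -> tuple[str, ...]:
        return (self.canonical, *self.synonyms)


class Dictionary:
    """Terminology dictionary standing in for a UMLS subset.

    TSV layout: ``concept_id <TAB> canonical <TAB> pipe-separated synonyms
    <TAB> category``.
    """

    def __init__(self, entries: list[DictEntry]):
        seen = set()
        for entry in entries:
            if entry.concept_id in seen:
                raise ValueError(f"duplicate concept id {entry.concept_id}")
            if not entry.canonical:
                raise ValueError(f"{entry.concept_id}: empty canonical name")
            seen.add(entry.concept_id)
        self.entries = entries
        self._exact: dict[str, list[DictEntry]] = {}
        for entry in entries:
            for form in entry.surface_forms():
                self._exact.setdefault(normalize_name(form), []).append(entry)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Dictionary":
        entries = []
        for lineno, line in enumerate(
                Path(path).read_text(encoding="utf-8").splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated "
                                 f"fields, got {len(parts)}")
            cid, canonical, syns, category = parts
            synonyms = tuple(s for s in syns.split("|") if s)
            entries.append(DictEntry(cid, canonical, synonyms, category))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join((e.concept_id, e.canonical, "|".join(e.synonyms),
                            e.category)) for e in self.entries]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def exact_lookup(self, surface: str) -> list[DictEntry]:
        return list(self._exact.get(normalize_name(surface), ()))

    def has_surface(self, surface: str) -> bool:
        return normalize_name(surface) in self._exact

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LinkCandidate:
    query_span: str
    entry: DictEntry
    s_fuzzy: float
    s_semantic: float = 0.0
    composite: float = 0.0
    match_stage: str = "fuzzy"  # "exact" | "fuzzy"


@dataclass
class LinkedEntity:
    query_span: str
    concept_id: str
    name: str                    # canonical dictionary name
    category: str
    confidence: float            # winning candidate's composite score
    entity_id: str | None = None  # resolved graph node, when present
    match_stage: str = "fuzzy"


def fuzzy_similarity(s1: str, s2: str) -> float:
    """``1 - Levenshtein(s1, s2) / max(len(s1), len(s2))``, casefolded."""
    if not s1 or not s2:
        raise LinkingError("fuzzy similarity is undefined for empty strings")
    a, b = s1.casefold(), s2.casefold()
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def fuzzy_match(span: str, dictionary: Dictionary,
                threshold: float = 0.8) -> list[LinkCandidate]:
    """Dictionary entries whose best surface form scores strictly above
    the threshold, sorted by descending score (ties by concept id)."""
    candidates: list[LinkCandidate] = []
    for entry in dictionary.entries:
        best = max(fuzzy_similarity(span, form)
                   for form in entry.surface_forms())
        if best > threshold:
            stage = "exact" if best == 1.0 else "fuzzy"
            candidates.append(LinkCandidate(span, entry, best,
                                            match_stage=stage))
    candidates.sort(key=lambda c: (-c.s_fuzzy, c.entry.concept_id))
    return candidates


def semantic_rank(query: str, candidates: list[LinkCandidate],
                  embedder: EmbedderContract,
                  config: LinkerConfig | None = None) -> list[LinkCandidate]:
    """Annotate candidates with cosine similarity and composite score."""
    config = config or LinkerConfig()
    qvec = embedder.embed(query)
    import numpy as np
    if float(np.linalg.norm(qvec)) == 0.0:
        warnings.warn("zero-norm query embedding; semantic scores set to 0")
    for cand in candidates:
        cand.s_semantic = cosine(qvec, embedder.embed(cand.entry.canonical))
        cand.composite = (config.w_fuzzy * cand.s_fuzzy
                          + config.w_semantic * max(0.0, cand.s_semantic))
    candidates.sort(key=lambda c: (-c.composite, c.entry.concept_id))
    return candidates


#: intent keywords -> entity categories they make plausible, used only to
#: break near-ties between link candidates
_CATEGORY_HINTS: tuple[tuple[frozenset[str], frozenset[str]], ...] = (
    (frozenset({"treat", "treatment", "therapy", "drug", "medicine",
                "medication", "prescribe"}),
     frozenset({DRUG, TREATMENT, DISEASE})),
    (frozenset({"symptom", "symptoms", "sign", "signs", "feel", "feels"}),
     frozenset({SYMPTOM, DISEASE})),
    (frozenset({"cause", "causes", "caused", "why", "risk", "etiology",
                "etiologies"}),
     frozenset({ETIOLOGY, DISEASE})),
    (frozenset({"gene", "genes", "mutation"}), frozenset({GENE, DISEASE})),
    (frozenset({"test", "tests", "diagnose", "diagnosed", "diagnosis",
                "criteria", "score"}),
     frozenset({EXAM, CRITERIA, DISEASE})),
)


def _preferred_categories(question: str) -> frozenset[str]:
    qtokens = set(tokenize(question))
    preferred: set[str] = set()
    for keywords, categories in _CATEGORY_HINTS:
        if qtokens & keywords:
            preferred |= categories
    return frozenset(preferred)


def _detect_spans(question: str, dictionary: Dictionary,
                  config: LinkerConfig) -> list[str]:
    """Greedy longest-match scan over token n-grams (n <= max_ngram).

    A span is accepted if it has an exact dictionary hit, or (for grams
    of >= 4 characters with no exact hit at any length) a fuzzy hit above
    threshold.
    """
    tokens = tokenize(question)
    spans: list[str] = []
    i = 0
    while i < len(tokens):
        matched = 0
        for n in range(min(config.max_ngram, len(tokens) - i), 0, -1):
            gram = " ".join(tokens[i:i + n])
            if dictionary.has_surface(gram):
                spans.append(gram)
                matched = n
                break
        if not matched:
            for n in range(min(config.max_ngram, len(tokens) - i), 0, -1):
                gram = " ".join(tokens[i:i + n])
                if len(gram) >= 4 and fuzzy_match(gram, dictionary,
                                                  config.threshold):
                    spans.append(gram)
                    matched = n
                    break
        i += matched or 1
    return spans


def link_entities(question: str, dictionary: Dictionary,
                  kg: PropertyGraph | None = None,
                  embedder: EmbedderContract | None = None,
                  config: LinkerConfig | None = None) -> list[LinkedEntity]:
    """Link every detectable span of the question to a dictionary concept.

    Returns one :class:`LinkedEntity` per span (empty list when nothing
    links — the agent workflow then takes the warned fallback path).
    """
    if not question.strip():
        raise LinkingError("question is empty")
    config = config or LinkerConfig()
    linked: list[LinkedEntity] = []
    for span in _detect_spans(question, dictionary, config):
        candidates = fuzzy_match(span, dictionary, config.threshold)
        if not candidates:
            continue
        if embedder is not None:
            candidates = semantic_rank(question, candidates, embedder, config)
        else:
            for cand in candidates:
                cand.composite = config.w_fuzzy * cand.s_fuzzy
        winner = _disambiguate(question, candidates, config)
        entity_id = None
        if kg is not None:
            ent = kg.entity_by_cui(winner.entry.concept_id) \
                or kg.entity_by_name(winner.entry.canonical)
            entity_id = ent.id if ent else None
        linked.append(LinkedEntity(
            query_span=span,
            concept_id=winner.entry.concept_id,
            name=winner.entry.canonical,
            category=winner.entry.category,
            confidence=winner.composite,
            entity_id=entity_id,
            match_stage=winner.match_stage,
        ))
    # one link per concept: keep the highest-confidence span
    best: dict[str, LinkedEntity] = {}
    for link in linked:
        prev = best.get(link.concept_id)
        if prev is None or link.confidence > prev.confidence:
            best[link.concept_id] = link
    return [l for l in linked if best[l.concept_id] is l]


def _disambiguate(question: str, candidates: list[LinkCandidate],
                  config: LinkerConfig) -> LinkCandidate:
    """Near-tie break: prefer the candidate whose category fits the
    question's intent keywords when the top two composites are within the
    configured margin."""
    if len(candidates) < 2:
        return candidates[0]
    top, runner = candidates[0], candidates[1]
    if top.composite - runner.composite >= config.disambiguation_margin:
        return top
    preferred = _preferred_categories(question)
    if preferred:
        if top.entry.category in preferred:
            return top
        if runner.entry.category in preferred:
            return runner
    return top
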