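# hepagraph

Self-correcting agentic graph retrieval-augmented generation (Graph RAG)
over clinical property graphs, with hepatology as the packaged reference
domain.

## The problem

Clinical question answering needs answers that are *grounded*: every claim
traceable to curated guideline knowledge, with an explicit signal when the
knowledge base cannot help. A plain LLM hallucinates; a single-shot
retriever cannot tell whether what it fetched is actually enough to answer
the question. `hepagraph` implements an agent that retrieves from an
attribute-rich clinical knowledge graph, *judges* whether the retrieved
context suffices, and deterministically *refines* its search strategy when
it does not — falling back, with a conspicuous warning, to un-grounded
text only as a last resort.

It is intended for builders of clinical decision-support and biomedical QA
pipelines who want the retrieval loop, its decision rules, and its
evaluation metrics as a testable, offline-runnable library.

## What is inside

* **Clinical property graph** — 8 entity categories (Disease, Drug, Gene,
  Symptom/Sign, Examination/Test, Treatment, Etiology/Risk Factor,
  Clinical Criteria) and 11 directed relation types with evidence
  attributes (evidence level, recommendation strength, dosing, a
  confidence weight in [0, 1]). JSONL, GraphML and openCypher I/O.
* **Bounded traversal primitives** — breadth-first neighborhoods
  N_BFS(V₀, k) = {e : dist(V₀, e) ≤ k} and depth-first simple-path
  enumeration P_DFS(V₀, k), both with deterministic truncation.
* **KG construction pipeline** — sentence-aligned chunking, strict-JSON
  extraction-payload validation, hierarchical deduplication (CUI ▸
  normalized name ▸ raw surface), evidence-weighted relation fusion (mean
  weight, strongest recommendation level), and the expert-review set
  algebra E_final = (E_LLM \ E_remove) ∪ E_add, plus QC reporting.
* **Multi-stage entity linker** — exact dictionary match, then Levenshtein
  similarity S_fuzzy = 1 − dist/max(len) with a strict 0.8 threshold, then
  embedding-cosine ranking and a composite score with context
  disambiguation.
* **Query planner** — intent classification; the intent → strategy map
  (fact/diagnosis/symptom → BFS k = 2; causal → DFS k = 3; multi-hop →
  DFS k = 4); dual-model query generation with a structural consistency
  score C_cypher ∈ {0.5, 1.0}; pre-execution semantic validation against
  the schema's direction table with one rewrite attempt; deterministic
  openCypher rendering.
* **Decision module** — two judges × 3 self-consistency votes each, with
  C_internal = max(N_suff, N_insuff)/N_total; objective context metrics
  combined as Score = 0.4·S_sem + 0.3·Norm(N_nodes) + 0.3·Norm(D_avg);
  τ-threshold arbitration of disagreements; and a deterministic,
  first-match strategy optimizer (deepen / switch method / widen limit),
  capped at 3 refinement iterations.
* **Answer synthesis** — cited [Fn] fact anchors, and a final confidence
  C_final = 0.3·C_cypher + 0.3·C_decision + 0.2·S_coverage + 0.2·C_entity
  − (k−1)·0.05, clipped to [0, 1].
* **Evaluation suite** — faithfulness F = |V|/|S|, context recall, answer
  relevancy (mean cosine against regenerated questions), linker P/R/F1,
  and a seeded synthetic hepatology fixture: a schema-complete toy graph
  plus a 30-question set (10 factual / 10 multi-hop / 10
  ambiguous-with-misspellings).
* **Deterministic mock providers** for generation, judging, and embedding,
  so every code path runs and tests offline.

## Worked example

```bash
hepagraph make-fixtures --seed 7 --out fx
hepagraph ask --question "How to treat cirrosis?" --kg fx --dict fx/dictionary.tsv
```

The misspelled *cirrosis* links to **cirrhosis** through the fuzzy stage
(similarity 1 − 1/9 ≈ 0.889 > 0.8). The token-overlap judge initially
finds the shallow context insufficient, so the agent runs its refinement
loop to the 3-iteration cap, then answers from the accumulated context.
The answer cites 20 facts and reports:

```json
{
  "c_cypher": 1.0,
  "c_decision": 1.0,
  "c_entity": 0.4444444444444444,
  "c_final": 0.788888888888889,
  "k": 3,
  "p_iteration": 0.1,
  "s_coverage": 1.0
}
```

Read it as: both query generators agreed (C_cypher = 1.0), the final
sufficiency decision was unanimous (C_decision = 1.0), every linked entity
appeared in the context (S_coverage = 1.0), the fuzzy-stage link carried
moderate confidence (C_entity ≈ 0.44), and three retrieval iterations cost
a 0.10 penalty — net confidence ≈ 0.79. A question that cannot be linked
at all (e.g. *"What is 'liver gunk'?"*) instead returns a fallback answer
whose warning states it is **not** graph-verified and whose confidence is
0.

The same loop is available as a library call:

```python
import hepagraph as hg

kg = hg.generate_fixture_kg()
d = hg.build_fixture_dictionary(kg)
answer = hg.run("What drug is recommended for hepatitis b?", kg, d,
                hg.make_provider_set())
print(answer.text)            # "... entecavir [F1]. ... tenofovir [F2]."
print(answer.confidence.c_final)  # 0.963...
```

## Documentation

`docs/methods.md` describes the models, decision rules, parameter
defaults, the synthetic-data generator's scope, and known limitations.
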