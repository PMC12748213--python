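# Methods

## Model overview

`hepagraph` treats clinical question answering as an iterative control
problem over a property graph. The graph G = (E, R) stores entities with
typed attributes and directed, evidence-bearing relations. A run of the
agent is a bounded loop:

1. **Link.** Detect question spans by dictionary-driven longest match over
   token n-grams (n ≤ 5, casefolded) and resolve each through exact →
   fuzzy → semantic stages. Fuzzy similarity is
   S_fuzzy = 1 − Levenshtein(s₁, s₂)/max(len(s₁), len(s₂)); an entry
   qualifies only if S_fuzzy *strictly exceeds* the threshold (default
   0.8 — "exceeds" is read strictly). Candidates are ordered by a
   composite w_f·S_fuzzy + w_s·max(0, cos(V_q, V_c)) with w_f = w_s = 0.5;
   negative cosines are clamped so the composite stays in [0, 1]. When the
   top two composites differ by less than 0.05, the candidate whose
   category matches the question's intent keywords wins. The winning
   composite becomes the link confidence C_entity.
2. **Plan.** Intent is classified by deterministic keyword rules (a
   provider-backed classifier can be substituted); the intent selects the
   retrieval strategy: breadth-first at depth k = 2 for
   fact/diagnosis/symptom/ambiguous questions, depth-first at k = 3 for
   causal and k = 4 for multi-hop questions. Two generators independently
   emit a structured query payload (anchors, relation filter, direction);
   equality of canonical *structural signatures* — not of query text —
   yields C_cypher = 1.0, divergence yields 0.5 with the primary's query
   kept. Before execution every (anchor category, relation type,
   direction) triple is validated against the schema's direction table;
   an invalid query gets exactly one rewrite (flip to undirected if every
   violating relation points *into* the anchor, else drop the violating
   types) and otherwise fails to the fallback path.
3. **Retrieve.** BFS returns {e : dist(seeds, e) ≤ k} with distances;
   DFS returns all *simple* directed paths of ≤ k steps honoring the
   relation filter. Simplicity is enforced so progression cycles
   terminate. Truncation is deterministic: (distance, discovery order)
   under the node limit for BFS, lexicographic node-id order under the
   path limit for DFS. Traversal follows outgoing edges by default — the
   schema's directions are asymmetric — with an undirected mode for
   lookups where the clinically natural edge points into the anchor.
4. **Evaluate.** Each of two judges casts n = 3 independent votes;
   C_internal = max(N_suff, N_insuff)/N_total. Objective metrics:
   entity coverage (fraction of linked entities present in the context;
   degenerate 1.0 when nothing linked), node count, information density
   (mean attributes per node), and semantic relevance
   S_sem = max(0, cos(embed(question), embed(serialized context))). The
   combined score is Score = w_sem·S_sem + w_cov·Norm(N_nodes) +
   w_den·Norm(D_avg) with weights 0.4/0.3/0.3. Norm is fixed-reference
   clipping, Norm(x) = min(x/x_ref, 1) (references: 20 nodes,
   5 attributes/node) — a batch min–max would make one question's score
   depend on its neighbors, which an interactive agent cannot afford.
   Agreement between the models stands; disagreement is arbitrated by the
   score against τ_high = 0.70 and τ_low = 0.40, with the between-band
   case resolved to Insufficient (clinical conservatism: retrieving more
   is cheaper than answering from doubtful context).
5. **Refine.** An Insufficient verdict triggers a first-match rule tree:
   low coverage (< 0.5) and depth below its cap → deepen by one; low
   semantic relevance (< 0.5) → toggle BFS↔DFS once, thereafter double
   the node limit; low density (< 0.4) → double the node limit. Caps:
   k ≤ 4, node limit ≤ 200. Only the first triggered rule fires per
   iteration so every change is minimal and attributable in the trace.
   The loop re-executes the *original validated query* — refinement edits
   strategy parameters, never query structure — and runs at most T = 3
   iterations.
6. **Answer.** Context facts are serialized deterministically (ordered by
   relation type, then source id) as `[Fn]` anchored lines; one generator
   call produces the answer; anchors that do not resolve to a context
   fact are stripped and logged. Final confidence:
   C_final = clip(w₁·C_cypher + w₂·C_decision + w₃·S_coverage +
   w₄·C_entity − (k−1)·0.05, 0, 1) with w = (0.3, 0.3, 0.2, 0.2) and k
   the number of evaluate iterations executed. When linking, planning or
   retrieval yields nothing usable the agent answers from parametric
   knowledge only, always with an explicit not-graph-verified warning and
   zeroed graph-evidence confidence.

## Decision confidence on arbitration

When the verdict comes from score arbitration rather than agreement, the
decision confidence is 0.5 + 0.5·min(|Score − m|/max(m, 1 − m), 1) with
m the midpoint of (τ_low, τ_high): a score far from the ambiguous band is
a confident arbitration, one near the midpoint barely better than a coin
flip. On agreement it is the mean of the two internal consistencies.

## Construction pipeline

Chunking slices exactly at sentence boundaries (concatenating the units
reproduces the document byte-for-byte), with a configurable window and
overlap. Extraction payloads are validated record-by-record against the
schema; failures are retained as typed errors, never dropped silently.
Deduplication keys on CUI first, then the normalized name (casefold, trim,
collapse whitespace — no stemming, so the linker rather than the builder
absorbs surface variation), then the raw surface; attribute conflicts keep
the first-seen value and log the collision. Relation fusion groups
parallel edges by (source, target, type), averages numeric weights, takes
the strongest recommendation level on a configurable ordinal scale
(default expert-opinion < weak < conditional < strong), and unions
provenance. The expert-review ledger applies exact set algebra on entity
keys; relation corrections mirror the same algebra by construction.

## Evaluation metrics

Faithfulness F = |V|/|S|: statements are extracted from the answer
(sentence splitting under the mock generator) and each is verified
against the context by a judge; undefined (zero-statement) records are
excluded from aggregates and logged. Context recall is the fraction of
gold-answer sentences a judge attributes to the context. Answer relevancy
is the mean embedding cosine between the question and n = 3 questions
regenerated from the answer. The judge criterion for verification and
attribution is, under the mocks, a content-token overlap rule
(threshold 0.2) — a stated stand-in for an LLM judgment, chosen for
determinism.

## Mock providers

The generator dispatches on a `TASK:` header and fills fixed templates;
the judge applies the overlap rule (with forced-verdict and scripted-vote
hooks, without which the refinement branches would be unreachable in
deterministic tests); the embedder maps each token via salted MD5 to one
of 64 signed coordinates and returns the signed count histogram —
identical texts embed identically, disjoint vocabularies are near
orthogonal, and nothing depends on Python hash randomization. No real
LLM or embedding backend is bundled; the contracts accept one without any
workflow change, which a contract-substitution test enforces.

## Synthetic fixture

The fixture graph is a hand-curated hepatology core — hepatitis B/C,
fatty liver, alcoholic liver disease, cirrhosis, hepatocellular
carcinoma, with their drugs, genes, symptoms, tests, treatments,
etiologies, and criteria — covering all 11 relation types with realistic
evidence attributes, plus 2 seeded filler entities per category wired by
category-appropriate relations (43 entities, 44 relations at defaults).
Known chains (steatosis → cirrhosis → carcinoma; etiology → cirrhosis →
transplantation) guarantee multi-hop questions are answerable. The
question set is 10 factual (one-hop template questions), 10 multi-hop
(verbalized two-hop chains), and 10 ambiguous/colloquial questions whose
entity surface is a seeded single-character-deletion misspelling that is
absent from the dictionary yet clears the 0.8 fuzzy threshold.

What the fixture does *not* emulate: guideline-scale graphs (tens of
thousands of entities), noisy LLM extraction output, real lexical
ambiguity between concepts, or free-text clinical phrasing. Passing tests
therefore demonstrate the correctness and determinism of the mechanism —
traversal, voting, arbitration, refinement, confidence algebra — not
retrieval quality on real corpora; metric values on the fixture are
fixture-dependent by design.

## Numerical and degenerate-input choices

* Weight sums are checked to 1 ± 1e-9; violations raise configuration
  errors rather than renormalizing silently.
* Empty retrieval contexts produce all-zero metrics and are valid; an
  empty context that somehow reaches synthesis routes to the fallback.
* Zero-norm embeddings give semantic score 0 with a warning.
* Fuzzy similarity is undefined on empty strings and raises.
* Candidate ties (equal scores) break by concept id; BFS discovery ties
  break by edge insertion order — both documented, both deterministic.
* A judge call that raises is counted as an insufficient vote and logged.

## Problem sizes

Property suites compare traversals against independent oracles (networkx
shortest paths and simple-path enumeration) on random digraphs of up to
30 nodes for BFS and 15 for DFS; vote and arbitration logic is tested
exhaustively (8 vote patterns × 9 arbitration cells). The end-to-end
suite runs the full 30-question fixture twice and asserts byte-identical
output. The whole test suite completes in a few seconds on one CPU.

## Known limitations

* Entity lookup by name/CUI in the graph is linear-scan; adequate at
  fixture scale, an index would be needed for guideline-scale graphs.
* The intent classifier's keyword rules are English-only and intent
  categories are fixed.
* The rendered openCypher is for interop/audit; the package does not
  parse or execute arbitrary Cypher.
* Relation-level review reuses the entity set algebra; domain review
  workflows with richer relation edits would need a dedicated ledger
  format.
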