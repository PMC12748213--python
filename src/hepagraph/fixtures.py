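"""Synthetic hepatology knowledge-graph and question-set fixtures.

The generator emulates, at toy scale, the shape of a guideline-derived
liver-disease graph: a hand-curated clinical core (hepatitis B/C,
fatty liver, cirrhosis, hepatocellular carcinoma, their drugs, genes,
symptoms, tests, treatments, etiologies and criteria) wired with all
eleven relation types and evidence attributes, plus seeded synthetic
filler entities per category.  Known multi-hop chains (etiology ->
cirrhosis -> transplantation; steatosis -> cirrhosis -> carcinoma) make
multi-hop questions answerable by construction.

A matching terminology dictionary (with abbreviations and colloquial
synonyms such as HCC or "liver fat") and a 30-question evaluation set —
10 simple factual, 10 multi-hop, 10 ambiguous/colloquial with injected
misspellings — are generated alongside, with gold answers derivable from
the graph and gold entity links recorded for linker benchmarking.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .builder import normalize_name
from .errors import GenerationError
from .graph import Entity, PropertyGraph, Relation
from .linking import DictEntry, Dictionary
from .schema import (CRITERIA, DISEASE, DRUG, ETIOLOGY, EXAM, GENE, SYMPTOM,
                     TREATMENT, default_schema)


@dataclass
class FixtureSpec:
    seed: int = 7
    extra_entities_per_category: int = 2
    n_factual: int = 10
    n_multi_hop: int = 10
    n_ambiguous: int = 10


@dataclass
class EvalRecord:
    question: str
    category: str                    # "factual" | "multi_hop" | "ambiguous"
    gold: str
    gold_links: list[str] = field(default_factory=list)
    answer: str = ""
    context_text: str = ""


# (id, name, category, cui, attributes)
_CORE_ENTITIES = [
    ("d_hbv", "hepatitis b", DISEASE, "C0019163", {"chronicity": "chronic"}),
    ("d_hcv", "hepatitis c", DISEASE, "C0019196", {"chronicity": "chronic"}),
    ("d_cirrhosis", "cirrhosis", DISEASE, "C0023890",
     {"stage_system": "child-pugh"}),
    ("d_hcc", "hepatocellular carcinoma", DISEASE, "C2239176",
     {"malignant": True}),
    ("d_fatty", "fatty liver", DISEASE, "C0015695", {"reversible": True}),
    ("d_ald", "alcoholic liver disease", DISEASE, "C0023896", {}),
    ("dr_entecavir", "entecavir", DRUG, "C0971023",
     {"drug_class": "nucleoside analogue"}),
    ("dr_tenofovir", "tenofovir", DRUG, "C0384228",
     {"drug_class": "nucleotide analogue"}),
    ("dr_sorafenib", "sorafenib", DRUG, "C1516119",
     {"drug_class": "kinase inhibitor"}),
    ("dr_ibuprofen", "ibuprofen", DRUG, "C0020740", {"drug_class": "nsaid"}),
    ("g_tp53", "tp53", GENE, "C0079419", {}),
    ("g_pnpla3", "pnpla3", GENE, "C1424875", {}),
    ("g_raf1", "raf1", GENE, "C0812238", {}),
    ("s_jaundice", "jaundice", SYMPTOM, "C0022346", {"objective": True}),
    ("s_ascites", "ascites", SYMPTOM, "C0003962", {"objective": True}),
    ("s_fatigue", "fatigue", SYMPTOM, "C0015672", {"objective": False}),
    ("s_headache", "headache", SYMPTOM, "C0018681", {"objective": False}),
    ("e_ultrasound", "liver ultrasound", EXAM, "C0041618", {"modality": "imaging"}),
    ("e_afp", "alpha-fetoprotein test", EXAM, "C0523443", {"modality": "lab"}),
    ("e_biopsy", "liver biopsy", EXAM, "C0193388", {"modality": "procedure"}),
    ("t_transplant", "liver transplantation", TREATMENT, "C0023911",
     {"invasive": True}),
    ("t_abstinence", "alcohol abstinence", TREATMENT, "C0085828",
     {"invasive": False}),
    ("et_alcohol", "alcohol use", ETIOLOGY, "C0001948", {"modifiable": True}),
    ("et_hbvirus", "hepatitis b virus", ETIOLOGY, "C0019169",
     {"modifiable": False}),
    ("et_obesity", "obesity", ETIOLOGY, "C0028754", {"modifiable": True}),
    ("c_childpugh", "child-pugh score", CRITERIA, "C2347612", {}),
    ("c_milan", "milan criteria", CRITERIA, "C2959452", {}),
]

_DOSE = {"evidence_level": "A", "recommendation_strength": "strong",
         "approval_status": "approved", "route": "oral", "frequency": "daily"}

# (source, target, type, attributes)
_CORE_RELATIONS = [
    ("d_hbv", "dr_entecavir", "RECOMMENDS_DRUG",
     {**_DOSE, "dosage": "0.5 mg", "weight": 0.9}),
    ("d_hbv", "dr_tenofovir", "RECOMMENDS_DRUG",
     {**_DOSE, "dosage": "300 mg", "weight": 0.85}),
    ("d_hcc", "dr_sorafenib", "RECOMMENDS_DRUG",
     {**_DOSE, "recommendation_strength": "conditional",
      "dosage": "400 mg", "frequency": "twice daily", "weight": 0.7}),
    ("dr_entecavir", "s_headache", "HAS_ADVERSE_EFFECT", {"frequency": "rare"}),
    ("dr_sorafenib", "s_fatigue", "HAS_ADVERSE_EFFECT", {"frequency": "common"}),
    ("d_hcc", "g_tp53", "ASSOCIATED_WITH_GENE", {"evidence_level": "B"}),
    ("d_fatty", "g_pnpla3", "ASSOCIATED_WITH_GENE", {"evidence_level": "A"}),
    ("dr_sorafenib", "g_raf1", "TARGETS_GENE", {"mechanism": "inhibition"}),
    ("dr_ibuprofen", "d_cirrhosis", "IS_CONTRAINDICATED_FOR",
     {"severity": "major"}),
    ("d_cirrhosis", "c_childpugh", "REQUIRES_CRITERIA", {"purpose": "staging"}),
    ("d_hcc", "c_milan", "REQUIRES_CRITERIA",
     {"purpose": "transplant eligibility"}),
    ("d_cirrhosis", "s_jaundice", "HAS_SYMPTOM", {"frequency": "common"}),
    ("d_cirrhosis", "s_ascites", "HAS_SYMPTOM", {"frequency": "common"}),
    ("d_hbv", "s_fatigue", "HAS_SYMPTOM", {"frequency": "common"}),
    ("d_hcc", "e_afp", "IS_DIAGNOSED_BY", {"role": "surveillance"}),
    ("d_hcc", "e_ultrasound", "IS_DIAGNOSED_BY", {"role": "surveillance"}),
    ("d_cirrhosis", "e_biopsy", "IS_DIAGNOSED_BY", {"role": "confirmation"}),
    ("d_cirrhosis", "et_alcohol", "IS_CAUSED_BY", {"weight": 0.8}),
    ("d_cirrhosis", "et_hbvirus", "IS_CAUSED_BY", {"weight": 0.75}),
    ("d_fatty", "et_obesity", "IS_CAUSED_BY", {"weight": 0.8}),
    ("d_ald", "et_alcohol", "IS_CAUSED_BY", {"weight": 0.95}),
    ("d_cirrhosis", "t_transplant", "RECOMMENDS_TREATMENT",
     {"evidence_level": "A", "recommendation_strength": "strong",
      "weight": 0.85}),
    ("d_hcc", "t_transplant", "RECOMMENDS_TREATMENT",
     {"evidence_level": "A", "recommendation_strength": "conditional",
      "weight": 0.8}),
    ("d_ald", "t_abstinence", "RECOMMENDS_TREATMENT",
     {"evidence_level": "A", "recommendation_strength": "strong",
      "weight": 0.9}),
    ("d_fatty", "d_cirrhosis", "PROGRESSES_TO", {"weight": 0.4}),
    ("d_cirrhosis", "d_hcc", "PROGRESSES_TO", {"weight": 0.3}),
    ("d_hbv", "d_cirrhosis", "PROGRESSES_TO", {"weight": 0.35}),
    ("d_ald", "d_cirrhosis", "PROGRESSES_TO", {"weight": 0.5}),
]

_SYNONYMS = {
    "hepatocellular carcinoma": ("hcc", "liver cancer"),
    "fatty liver": ("hepatic steatosis", "liver fat"),
    "hepatitis b": ("hbv infection", "hep b"),
    "hepatitis c": ("hep c",),
    "cirrhosis": ("liver cirrhosis",),
    "jaundice": ("yellow skin",),
    "alpha-fetoprotein test": ("afp test", "afp"),
    "liver transplantation": ("liver transplant",),
    "alcohol use": ("drinking", "alcohol consumption"),
    "liver ultrasound": ("abdominal ultrasound",),
}

#: filler entities get relations of a category-appropriate type
_FILLER_RELATION = {
    DRUG: ("RECOMMENDS_DRUG", "in"),      # Disease -> new Drug
    GENE: ("ASSOCIATED_WITH_GENE", "in"),
    SYMPTOM: ("HAS_SYMPTOM", "in"),
    EXAM: ("IS_DIAGNOSED_BY", "in"),
    TREATMENT: ("RECOMMENDS_TREATMENT", "in"),
    ETIOLOGY: ("IS_CAUSED_BY", "in"),
    CRITERIA: ("REQUIRES_CRITERIA", "in"),
    DISEASE: ("PROGRESSES_TO", "out"),    # new Disease -> core Disease
}

_CATEGORY_SLUG = {
    DISEASE: "disease", DRUG: "drug", GENE: "gene", SYMPTOM: "symptom",
    EXAM: "test", TREATMENT: "therapy", ETIOLOGY: "exposure",
    CRITERIA: "criterion",
}


def generate_fixture_kg(spec: FixtureSpec | None = None) -> PropertyGraph:
    """Build the deterministic fixture graph for a given seed."""
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed)
    graph = PropertyGraph(default_schema())
    for eid, name, category, cui, attrs in _CORE_ENTITIES:
        graph.add_entity(Entity(id=eid, name=name, category=category, cui=cui,
                                raw_name=name, attributes=dict(attrs)))
    for src, tgt, rtype, attrs in _CORE_RELATIONS:
        graph.add_relation(Relation(source_id=src, target_id=tgt, type=rtype,
                                    attributes=dict(attrs),
                                    provenance=[f"guideline-{rtype.lower()}"]))
    diseases = [e for e, _, c, _, _ in _CORE_ENTITIES if c == DISEASE]
    counter = 0
    for category, slug in _CATEGORY_SLUG.items():
        for i in range(spec.extra_entities_per_category):
            counter += 1
            eid = f"x_{slug}_{i}"
            name = f"synthetic {slug} {i}"
            graph.add_entity(Entity(
                id=eid, name=name, category=category,
                cui=f"CX{counter:04d}", raw_name=name,
                attributes={"synthetic": True,
                            "salience": round(rng.random(), 3)}))
            rtype, direction = _FILLER_RELATION[category]
            disease = rng.choice(diseases)
            src, tgt = (disease, eid) if direction == "in" else (eid, disease)
            attrs = {"weight": round(rng.uniform(0.3, 0.9), 2)}
            graph.add_relation(Relation(source_id=src, target_id=tgt,
                                        type=rtype, attributes=attrs,
                                        provenance=[f"synthetic-{eid}"]))
    return graph


def build_fixture_dictionary(graph: PropertyGraph) -> Dictionary:
    """Terminology dictionary matching the fixture graph (CUIs as ids)."""
    entries = []
    for ent in graph.entities.values():
        synonyms = _SYNONYMS.get(ent.name, ())
        entries.append(DictEntry(concept_id=ent.cui or ent.id,
                                 canonical=ent.name, synonyms=synonyms,
                                 category=ent.category))
    return Dictionary(entries)


# --------------------------------------------------------------------------
# question generation

_FACTUAL_TEMPLATES = {
    "RECOMMENDS_DRUG": ("What drug is recommended for {src}?",
                        "{tgt} is recommended for {src}."),
    "HAS_SYMPTOM": ("What are typical signs of {src}?",
                    "{src} commonly presents with {tgt}."),
    "IS_DIAGNOSED_BY": ("Which test is used to diagnose {src}?",
                        "{src} is diagnosed by {tgt}."),
    "RECOMMENDS_TREATMENT": ("What treatment is recommended for {src}?",
                             "{tgt} is recommended for {src}."),
}

_AMBIGUOUS_TEMPLATES = (
    ("how to treat {surface}?", "RECOMMENDS_DRUG"),
    ("my {surface} is acting up, what should i take?", "RECOMMENDS_DRUG"),
    ("what do people with {surface} usually notice?", "HAS_SYMPTOM"),
)


def _misspell(name: str, dictionary: Dictionary, rng: random.Random) -> str | None:
    """Delete one internal character; keep only non-dictionary results that
    still clear the fuzzy threshold (similarity 1 - 1/len > 0.8)."""
    word = max(name.split(), key=len)
    if len(word) < 6:
        return None
    positions = list(range(1, len(word) - 1))
    rng.shuffle(positions)
    for pos in positions:
        variant = word[:pos] + word[pos + 1:]
        candidate = name.replace(word, variant)
        if not dictionary.has_surface(candidate) \
                and not dictionary.has_surface(variant):
            return candidate
    return None


def generate_question_set(graph: PropertyGraph, spec: FixtureSpec | None = None,
                          dictionary: Dictionary | None = None,
                          ) -> list[EvalRecord]:
    """10/10/10 factual / multi-hop / ambiguous questions with gold data.

    Every gold answer is derivable from the graph; every ambiguous
    question contains a surface form absent from the dictionary.
    """
    spec = spec or FixtureSpec()
    dictionary = dictionary or build_fixture_dictionary(graph)
    rng = random.Random(spec.seed + 1)
    records: list[EvalRecord] = []

    # factual: one-hop relations with a question template
    candidates = [r for r in graph.relations
                  if r.type in _FACTUAL_TEMPLATES
                  and not graph.entities[r.target_id].attributes.get("synthetic")]
    candidates.sort(key=lambda r: (r.type, r.source_id, r.target_id))
    if len(candidates) < spec.n_factual:
        raise GenerationError(
            f"graph supports only {len(candidates)} factual questions, "
            f"need {spec.n_factual}")
    for rel in rng.sample(candidates, spec.n_factual):
        qt, at = _FACTUAL_TEMPLATES[rel.type]
        src = graph.entities[rel.source_id]
        tgt = graph.entities[rel.target_id]
        records.append(EvalRecord(
            question=qt.format(src=src.name),
            category="factual",
            gold=at.format(src=src.name, tgt=tgt.name),
            gold_links=[src.cui or src.id],
        ))

    # multi-hop: 2-hop outgoing chains
    core = [eid for eid in graph.entities
            if not graph.entities[eid].attributes.get("synthetic")]
    paths = graph.dfs_paths(core, k=2).paths
    two_hop = [p for p in paths if len(p) == 2
               and not graph.entities[p.nodes[-1]].attributes.get("synthetic")]
    if len(two_hop) < spec.n_multi_hop:
        raise GenerationError(
            f"graph supports only {len(two_hop)} multi-hop questions, "
            f"need {spec.n_multi_hop}")
    for path in rng.sample(two_hop, spec.n_multi_hop):
        n0, n1, n2 = (graph.entities[n] for n in path.nodes)
        r1, r2 = (t.replace("_", " ").lower() for t in path.relation_types)
        records.append(EvalRecord(
            question=(f"Starting from {n0.name}, via {r1} and then {r2}, "
                      "which entity do we reach?"),
            category="multi_hop",
            gold=(f"From {n0.name} we reach {n2.name} through {n1.name} "
                  f"({r1}, then {r2})."),
            gold_links=[n0.cui or n0.id],
        ))

    # ambiguous: colloquial phrasing with injected misspellings
    sources = []
    for rel in graph.relations:
        src = graph.entities[rel.source_id]
        if rel.type in ("RECOMMENDS_DRUG", "HAS_SYMPTOM") \
                and not src.attributes.get("synthetic"):
            sources.append((rel, src))
    sources.sort(key=lambda pair: (pair[0].type, pair[0].source_id,
                                   pair[0].target_id))
    made = 0
    i = 0
    while made < spec.n_ambiguous:
        if not sources:
            raise GenerationError("no source relations for ambiguous questions")
        rel, src = sources[i % len(sources)]
        i += 1
        surface = _misspell(src.name, dictionary, rng)
        if surface is None:
            if i > 10 * len(sources):
                raise GenerationError(
                    "could not inject enough misspellings for ambiguous "
                    "questions")
            continue
        template, _ = _AMBIGUOUS_TEMPLATES[made % len(_AMBIGUOUS_TEMPLATES)]
        tgt = graph.entities[rel.target_id]
        if rel.type == "RECOMMENDS_DRUG":
            gold = f"{tgt.name} is recommended for {src.name}."
        else:
            gold = f"{src.name} commonly presents with {tgt.name}."
        records.append(EvalRecord(
            question=template.format(surface=surface),
            category="ambiguous",
            gold=gold,
            gold_links=[src.cui or src.id],
        ))
        made += 1

    return records


def write_questions_jsonl(records: list[EvalRecord], path) -> None:
    import json
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps({
                "question": rec.question, "category": rec.category,
                "gold": rec.gold, "gold_links": rec.gold_links,
            }, ensure_ascii=False, sort_keys=True) + "\n")


def read_questions_jsonl(path) -> list[EvalRecord]:
    import json
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                doc = json.loads(line)
                records.append(EvalRecord(
                    question=doc["question"], category=doc["category"],
                    gold=doc["gold"], gold_links=doc.get("gold_links", [])))
    return records
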