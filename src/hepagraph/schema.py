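"""Clinical property-graph schema.

The packaged default ontology models hepatology guideline knowledge with
eight entity categories (Disease, Drug, Gene, Symptom/Sign,
Examination/Test, Treatment, Etiology/Risk Factor, Clinical Criteria) and
eleven directed relation types, each mapped to exactly one
(source category, target category) pair.  Evidence-bearing relations such
as RECOMMENDS_DRUG carry structured attributes (evidence level,
recommendation strength, approval status, dosing regimen, and a numeric
confidence ``weight`` in [0, 1]).

Custom schemas can be loaded from YAML; the default requires no file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import SchemaError

DISEASE = "Disease"
DRUG = "Drug"
GENE = "Gene"
SYMPTOM = "Symptom/Sign"
EXAM = "Examination/Test"
TREATMENT = "Treatment"
ETIOLOGY = "Etiology/Risk Factor"
CRITERIA = "Clinical Criteria"

DEFAULT_ENTITY_TYPES = (
    DISEASE,
    DRUG,
    GENE,
    SYMPTOM,
    EXAM,
    TREATMENT,
    ETIOLOGY,
    CRITERIA,
)

#: relation name -> (source category, target category)
DEFAULT_RELATION_TYPES = {
    "RECOMMENDS_DRUG": (DISEASE, DRUG),
    "HAS_ADVERSE_EFFECT": (DRUG, SYMPTOM),
    "ASSOCIATED_WITH_GENE": (DISEASE, GENE),
    "TARGETS_GENE": (DRUG, GENE),
    "IS_CONTRAINDICATED_FOR": (DRUG, DISEASE),
    "REQUIRES_CRITERIA": (DISEASE, CRITERIA),
    "HAS_SYMPTOM": (DISEASE, SYMPTOM),
    "IS_DIAGNOSED_BY": (DISEASE, EXAM),
    "IS_CAUSED_BY": (DISEASE, ETIOLOGY),
    "RECOMMENDS_TREATMENT": (DISEASE, TREATMENT),
    "PROGRESSES_TO": (DISEASE, DISEASE),
}

DEFAULT_REQUIRED_ATTRIBUTES = {
    "RECOMMENDS_DRUG": (
        "evidence_level",
        "recommendation_strength",
        "approval_status",
        "dosage",
        "route",
        "frequency",
        "weight",
    ),
}


@dataclass(frozen=True)
class Schema:
    """Ontology of a clinical property graph.

    Parameters
    ----------
    entity_types
        Allowed entity categories.
    relation_types
        Map of relation name to its ``(source, target)`` category pair.
    required_attributes
        Per relation type, the attribute names expected on instances.
        Used for quality-control completeness reporting, not hard
        validation.
    """

    entity_types: frozenset[str]
    relation_types: dict[str, tuple[str, str]]
    required_attributes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, pair in self.relation_types.items():
            if len(pair) != 2:
                raise SchemaError(
                    f"relation_types[{name!r}] must map to a (source, target) pair"
                )
            src, tgt = pair
            for cat in (src, tgt):
                if cat not in self.entity_types:
                    raise SchemaError(
                        f"relation_types[{name!r}] references unknown "
                        f"entity category {cat!r}"
                    )

    def endpoint_categories(self, relation_type: str) -> tuple[str, str]:
        try:
            return self.relation_types[relation_type]
        except KeyError:
            raise SchemaError(f"unknown relation type {relation_type!r}") from None

    def compatible(self, source_category: str, relation_type: str,
                   target_category: str) -> bool:
        """True iff the categories match the relation's declared pair."""
        pair = self.relation_types.get(relation_type)
        return pair is not None and pair == (source_category, target_category)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "entity_types": sorted(self.entity_types),
            "relation_types": {
                name: {"source": src, "target": tgt,
                       "attributes": list(self.required_attributes.get(name, ()))}
                for name, (src, tgt) in sorted(self.relation_types.items())
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False),
                              encoding="utf-8")


def default_schema() -> Schema:
    """The packaged hepatology ontology: 8 entity / 11 relation types."""
    return Schema(
        entity_types=frozenset(DEFAULT_ENTITY_TYPES),
        relation_types=dict(DEFAULT_RELATION_TYPES),
        required_attributes=dict(DEFAULT_REQUIRED_ATTRIBUTES),
    )


def load_schema(path: str | Path | None = None) -> Schema:
    """Load a schema from YAML, or return the packaged default.

    The YAML layout mirrors :meth:`Schema.to_yaml`:

    .. code-block:: yaml

        entity_types: [Disease, Drug]
        relation_types:
          RECOMMENDS_DRUG: {source: Disease, target: Drug, attributes: [weight]}

    Raises
    ------
    SchemaError
        If the definition is malformed; the message names the offending
        field.
    """
    if path is None:
        return default_schema()
    raw = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise SchemaError(f"schema file is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("schema document must be a mapping")
    if "entity_types" not in doc:
        raise SchemaError("schema is missing field 'entity_types'")
    ents = doc["entity_types"]
    if not isinstance(ents, list) or not all(isinstance(e, str) for e in ents):
        raise SchemaError("field 'entity_types' must be a list of strings")
    rels_doc = doc.get("relation_types") or {}
    if not isinstance(rels_doc, dict):
        raise SchemaError("field 'relation_types' must be a mapping")
    relation_types: dict[str, tuple[str, str]] = {}
    required: dict[str, tuple[str, ...]] = {}
    for name, spec in rels_doc.items():
        if not isinstance(spec, dict) or "source" not in spec or "target" not in spec:
            raise SchemaError(
                f"relation_types[{name!r}] must be a mapping with "
                "'source' and 'target'"
            )
        relation_types[name] = (spec["source"], spec["target"])
        attrs = spec.get("attributes") or []
        if attrs:
            required[name] = tuple(attrs)
    return Schema(
        entity_types=frozenset(ents),
        relation_types=relation_types,
        required_attributes=required,
    )
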