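"""Exception hierarchy for hepagraph.

Every error raised by the library derives from :class:`HepagraphError`, so
callers (notably the agent workflow, which must never crash on a bad
question) can catch one base class.
"""


class HepagraphError(Exception):
    """Base class for all hepagraph errors."""


class SchemaError(HepagraphError):
    """A schema definition is malformed, or a record violates the schema."""


class IntegrityError(HepagraphError):
    """A relation references an entity id that is not in the graph."""


class LinkingError(HepagraphError):
    """An entity surface form could not be resolved (e.g. unknown seed id)."""


class PlanningError(HepagraphError):
    """Query generation failed (no linked entities, unparseable payloads)."""


class QueryValidationError(HepagraphError):
    """A graph query is semantically invalid and could not be repaired."""


class FusionError(HepagraphError):
    """Relation fusion hit an unknown ordinal label."""


class ConfigurationError(HepagraphError):
    """Weights or thresholds violate their contract (e.g. do not sum to 1)."""


class ProviderError(HepagraphError):
    """An LLM / embedding provider call failed or is unavailable."""


class GenerationError(HepagraphError):
    """Synthetic fixture generation was asked for an infeasible layout."""


class MetricError(HepagraphError):
    """An evaluation metric is undefined for the given record."""
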