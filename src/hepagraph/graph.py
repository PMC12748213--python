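"""Property-graph data model and bounded traversal primitives.

The graph is directed (relation directions follow the schema's
source -> target conventions).  Retrieval offers two bounded primitives:

* :func:`bfs_neighborhood` — the set of entities within shortest-path
  distance ``k`` of the seed set, N_BFS(V0, k) = {e : dist(V0, e) <= k},
  truncated deterministically by (distance, discovery order);
* :func:`dfs_paths` — all simple directed paths of length <= k from the
  seeds, P_DFS(V0, k), optionally restricted to a relation-type filter and
  truncated in lexicographic node-id order.

Paths are restricted to *simple* paths (no repeated node) so that
traversal terminates on cyclic graphs such as disease-progression loops.
Both primitives accept ``undirected=True`` to ignore edge direction, which
suits symptom-style lookups where the clinically natural direction points
into the anchor.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import IntegrityError, LinkingError, SchemaError
from .schema import Schema, default_schema

Scalar = str | int | float | bool | None


@dataclass
class Entity:
    """A node of the clinical property graph.

    ``name`` is the normalized surface form, ``raw_name`` the original
    one; ``cui`` is an optional concept identifier from a terminology
    dictionary.
    """

    id: str
    name: str
    category: str
    cui: str | None = None
    raw_name: str | None = None
    attributes: dict[str, Scalar] = field(default_factory=dict)

    def attribute_count(self) -> int:
        return len(self.attributes)


@dataclass
class Relation:
    """A typed, attribute-rich directed edge.

    ``attributes`` may carry ``weight`` (confidence in [0, 1]),
    ``evidence_level``, ``recommendation_strength`` and dosing fields;
    ``provenance`` lists the source-chunk ids the relation was extracted
    from.
    """

    source_id: str
    target_id: str
    type: str
    attributes: dict[str, Scalar] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    id: str = ""

    def key(self) -> tuple[str, str, str]:
        return (self.source_id, self.target_id, self.type)


@dataclass
class Subgraph:
    """Result of a BFS neighborhood query."""

    node_ids: list[str]
    relations: list[Relation]
    distances: dict[str, int]


@dataclass(frozen=True)
class Path:
    """One traversal path: node ids plus the relation label of each step."""

    nodes: tuple[str, ...]
    relation_types: tuple[str, ...]
    relation_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.relation_types)


@dataclass
class PathSet:
    """Result of a DFS path query."""

    paths: list[Path]
    max_depth: int


class PropertyGraph:
    """Directed property graph validated against a :class:`Schema`.

    Entities are keyed by caller-supplied string ids (deduplication is the
    KG builder's concern).  An adjacency index keeps traversal linear in
    the visited neighborhood.
    """

    def __init__(self, schema: Schema | None = None) -> None:
        self.schema = schema or default_schema()
        self.entities: dict[str, Entity] = {}
        self.relations: list[Relation] = []
        self._out: dict[str, list[int]] = {}
        self._in: dict[str, list[int]] = {}

    # -- construction ------------------------------------------------------

    def add_entity(self, entity: Entity) -> str:
        if not entity.name:
            raise SchemaError(f"entity {entity.id!r} has an empty name")
        if entity.category not in self.schema.entity_types:
            raise SchemaError(
                f"entity {entity.id!r}: category {entity.category!r} "
                "is not in the schema"
            )
        if entity.id in self.entities:
            raise IntegrityError(f"duplicate entity id {entity.id!r}")
        self.entities[entity.id] = entity
        self._out.setdefault(entity.id, [])
        self._in.setdefault(entity.id, [])
        return entity.id

    def add_relation(self, relation: Relation) -> None:
        pair = self.schema.relation_types.get(relation.type)
        if pair is None:
            raise SchemaError(f"relation type {relation.type!r} is not in the schema")
        for eid in (relation.source_id, relation.target_id):
            if eid not in self.entities:
                raise IntegrityError(
                    f"relation {relation.type} references missing entity {eid!r}"
                )
        src_cat = self.entities[relation.source_id].category
        tgt_cat = self.entities[relation.target_id].category
        if (src_cat, tgt_cat) != pair:
            raise SchemaError(
                f"relation {relation.type} expects {pair[0]} -> {pair[1]}, "
                f"got {src_cat} -> {tgt_cat}"
            )
        weight = relation.attributes.get("weight")
        if weight is not None and not (0.0 <= float(weight) <= 1.0):
            raise SchemaError(
                f"relation {relation.type}: weight {weight!r} outside [0, 1]"
            )
        if not relation.id:
            relation.id = f"r{len(self.relations)}"
        idx = len(self.relations)
        self.relations.append(relation)
        self._out[relation.source_id].append(idx)
        self._in[relation.target_id].append(idx)

    # -- lookups -----------------------------------------------------------

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.entities

    def __len__(self) -> int:
        return len(self.entities)

    def entity_by_name(self, name: str) -> Entity | None:
        needle = name.casefold().strip()
        for ent in self.entities.values():
            if ent.name.casefold().strip() == needle:
                return ent
        return None

    def entity_by_cui(self, cui: str) -> Entity | None:
        for ent in self.entities.values():
            if ent.cui == cui:
                return ent
        return None

    def relation_by_id(self, relation_id: str) -> Relation | None:
        for rel in self.relations:
            if rel.id == relation_id:
                return rel
        return None

    def _neighbors(
        self,
        node: str,
        relation_filter: frozenset[str] | None,
        undirected: bool,
    ) -> Iterator[tuple[str, Relation]]:
        """Outgoing (and, if undirected, incoming) edges in insertion order."""
        for idx in self._out.get(node, ()):
            rel = self.relations[idx]
            if relation_filter and rel.type not in relation_filter:
                continue
            yield rel.target_id, rel
        if undirected:
            for idx in self._in.get(node, ()):
                rel = self.relations[idx]
                if relation_filter and rel.type not in relation_filter:
                    continue
                yield rel.source_id, rel

    def _check_seeds(self, seeds: Sequence[str]) -> list[str]:
        missing = [s for s in seeds if s not in self.entities]
        if missing:
            raise LinkingError(f"unknown seed entities: {missing}")
        # preserve order, drop duplicates
        out: list[str] = []
        for s in seeds:
            if s not in out:
                out.append(s)
        return out

    # -- traversal ---------------------------------------------------------

    def bfs_neighborhood(
        self,
        seeds: Sequence[str],
        k: int,
        node_limit: int | None = None,
        relation_filter: Iterable[str] | None = None,
        undirected: bool = False,
    ) -> Subgraph:
        """Entities within shortest-path distance ``k`` of the seeds.

        Truncation to ``node_limit`` keeps nodes in (distance, discovery
        order); seeds are always at distance 0.  The induced relations are
        those whose endpoints both survive truncation (respecting the
        relation filter if one is given).
        """
        if k < 0:
            raise ValueError("k must be >= 0")
        if node_limit is not None and node_limit < 1:
            raise ValueError("node_limit must be >= 1")
        seeds = self._check_seeds(seeds)
        rfilter = frozenset(relation_filter) if relation_filter else None

        distances: dict[str, int] = {s: 0 for s in seeds}
        order: list[str] = list(seeds)
        queue: deque[str] = deque(seeds)
        while queue:
            node = queue.popleft()
            d = distances[node]
            if d >= k:
                continue
            for nbr, _rel in self._neighbors(node, rfilter, undirected):
                if nbr not in distances:
                    distances[nbr] = d + 1
                    order.append(nbr)
                    queue.append(nbr)

        if node_limit is not None and len(order) > node_limit:
            order = order[:node_limit]
        kept = set(order)
        distances = {n: distances[n] for n in order}
        relations = [
            rel
            for rel in self.relations
            if rel.source_id in kept and rel.target_id in kept
            and (not rfilter or rel.type in rfilter)
        ]
        return Subgraph(node_ids=order, relations=relations, distances=distances)

    def dfs_paths(
        self,
        seeds: Sequence[str],
        k: int,
        relation_filter: Iterable[str] | None = None,
        path_limit: int | None = None,
        undirected: bool = False,
    ) -> PathSet:
        """All simple paths of 1..k steps from the seeds.

        An empty/None ``relation_filter`` admits every relation type.
        Paths are returned (and truncated to ``path_limit``) in
        lexicographic node-id order.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        seeds = self._check_seeds(seeds)
        rfilter = frozenset(relation_filter) if relation_filter else None

        paths: list[Path] = []

        def extend(nodes: list[str], rtypes: list[str], rids: list[str]) -> None:
            if len(rtypes) >= k:
                return
            for nbr, rel in self._neighbors(nodes[-1], rfilter, undirected):
                if nbr in nodes:  # simple paths only
                    continue
                nodes.append(nbr)
                rtypes.append(rel.type)
                rids.append(rel.id)
                paths.append(Path(tuple(nodes), tuple(rtypes), tuple(rids)))
                extend(nodes, rtypes, rids)
                nodes.pop()
                rtypes.pop()
                rids.pop()

        for seed in seeds:
            extend([seed], [], [])

        paths.sort(key=lambda p: p.nodes)
        if path_limit is not None:
            paths = paths[:path_limit]
        return PathSet(paths=paths, max_depth=k)

    # -- conversions -------------------------------------------------------

    def to_networkx(self):
        """MultiDiGraph view (used for GraphML export and as a test oracle)."""
        import networkx as nx

        g = nx.MultiDiGraph()
        for ent in self.entities.values():
            attrs = {k: v for k, v in ent.attributes.items() if v is not None}
            g.add_node(ent.id, name=ent.name, category=ent.category,
                       **({"cui": ent.cui} if ent.cui else {}), **attrs)
        for rel in self.relations:
            attrs = {k: v for k, v in rel.attributes.items() if v is not None}
            if rel.provenance:
                attrs["provenance"] = "|".join(rel.provenance)
            g.add_edge(rel.source_id, rel.target_id, key=rel.id,
                       type=rel.type, **attrs)
        return g

    def copy(self) -> "PropertyGraph":
        out = PropertyGraph(self.schema)
        for ent in self.entities.values():
            out.add_entity(Entity(ent.id, ent.name, ent.category, ent.cui,
                                  ent.raw_name, dict(ent.attributes)))
        for rel in self.relations:
            out.add_relation(Relation(rel.source_id, rel.target_id, rel.type,
                                      dict(rel.attributes), list(rel.provenance),
                                      rel.id))
        return out


def bfs_neighborhood(graph: PropertyGraph, seeds: Sequence[str], k: int,
                     node_limit: int | None = None, **kw) -> Subgraph:
    return graph.bfs_neighborhood(seeds, k, node_limit, **kw)


def dfs_paths(graph: PropertyGraph, seeds: Sequence[str], k: int,
              relation_filter: Iterable[str] | None = None,
              path_limit: int | None = None, **kw) -> PathSet:
    return graph.dfs_paths(seeds, k, relation_filter, path_limit, **kw)
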