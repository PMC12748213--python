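import random

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hepagraph import (Config, Dictionary, Entity, PropertyGraph, Relation,
                       build_fixture_dictionary, default_schema,
                       generate_fixture_kg, make_provider_set)
from hepagraph.fixtures import FixtureSpec
from hepagraph.schema import DISEASE


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture
def path_graph(schema):
    """a -> b -> c -> d disease-progression chain."""
    g = PropertyGraph(schema)
    for eid in "abcd":
        g.add_entity(Entity(id=eid, name=f"disease {eid}", category=DISEASE))
    for src, tgt in [("a", "b"), ("b", "c"), ("c", "d")]:
        g.add_relation(Relation(src, tgt, "PROGRESSES_TO"))
    return g


@pytest.fixture
def star_graph(schema):
    """center with 5 progression leaves."""
    g = PropertyGraph(schema)
    g.add_entity(Entity(id="center", name="center disease", category=DISEASE))
    for i in range(5):
        g.add_entity(Entity(id=f"leaf{i}", name=f"leaf {i}", category=DISEASE))
        g.add_relation(Relation("center", f"leaf{i}", "PROGRESSES_TO"))
    return g


@pytest.fixture
def triangle_graph(schema):
    """a -> b -> c -> a progression cycle."""
    g = PropertyGraph(schema)
    for eid in "abc":
        g.add_entity(Entity(id=eid, name=f"disease {eid}", category=DISEASE))
    for src, tgt in [("a", "b"), ("b", "c"), ("c", "a")]:
        g.add_relation(Relation(src, tgt, "PROGRESSES_TO"))
    return g


def make_random_digraph(rng: random.Random, n_nodes: int,
                        edge_prob: float = 0.2) -> PropertyGraph:
    """Random schema-valid digraph (all Disease nodes, PROGRESSES_TO edges,
    no parallel edges)."""
    g = PropertyGraph(default_schema())
    for i in range(n_nodes):
        g.add_entity(Entity(id=f"n{i:02d}", name=f"disease {i}",
                            category=DISEASE))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_prob:
                g.add_relation(Relation(f"n{i:02d}", f"n{j:02d}",
                                        "PROGRESSES_TO"))
    return g


@pytest.fixture(scope="session")
def fixture_kg():
    return generate_fixture_kg(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def fixture_dictionary(fixture_kg) -> Dictionary:
    return build_fixture_dictionary(fixture_kg)


@pytest.fixture
def providers():
    return make_provider_set()


@pytest.fixture
def config():
    return Config()
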