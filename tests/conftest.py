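import numpy as np
import pytest

import pathpred as pp
from pathpred.network import INPUT, OUTPUT


@pytest.fixture
def toy():
    """The fixed 3-entity / 2-reaction / 2-attribute example network."""
    return pp.make_toy()


def random_network(rng: np.random.Generator, n_nodes: int | None = None,
                   n_edges: int | None = None, n_attrs: int | None = None,
                   allow_isolated: bool = True) -> pp.PathwayNetwork:
    """Small random hypergraph for oracle/property tests (<= 30 nodes)."""
    n_nodes = int(rng.integers(2, 31)) if n_nodes is None else n_nodes
    n_edges = int(rng.integers(1, 11)) if n_edges is None else n_edges
    n_attrs = int(rng.integers(1, 9)) if n_attrs is None else n_attrs
    entities = [f"v{i}" for i in range(n_nodes)]
    reactions = [f"e{j}" for j in range(n_edges)]
    attributes = [f"f{k}" for k in range(n_attrs)]
    memberships = set()
    # leave the last node isolated sometimes to exercise degree-0 handling
    pool = n_nodes - 1 if (allow_isolated and n_nodes > 2) else n_nodes
    for j in range(n_edges):
        size = int(rng.integers(1, min(4, pool) + 1))
        members = rng.choice(pool, size=size, replace=False)
        for v in members:
            role = (INPUT, OUTPUT)[int(rng.integers(2))]
            memberships.add((f"v{v}", f"e{j}", role))
    assignments = set()
    for v in range(n_nodes):
        for k in range(n_attrs):
            if rng.random() < 0.3:
                assignments.add((f"v{v}", f"f{k}"))
    return pp.build_network(entities, reactions, attributes,
                            sorted(memberships), sorted(assignments))


@pytest.fixture
def make_random_network():
    return random_network
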