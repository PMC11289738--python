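"""Seeded generator of pathway-like hypergraphs with planted structure.

Real pathway networks have two statistical signatures the prediction tasks
rely on: entities that work together (a functional module) co-occur across
many reactions, and products of one reaction feed the next as substrates
(reaction chains).  The generator plants both: entities, reactions and
attributes are partitioned into modules; each entity draws attributes from
its module's pool; reactions draw members from their module, chaining inputs
to the previous reaction's outputs with probability ``chain_prob`` and
occasionally crossing modules.  Co-module entities therefore co-occur in
reactions and share attributes, which makes both the link and the attribute
task learnable — and makes the generator a controllable stand-in for
database-derived pathway networks at the same order of sparsity
(a few thousand incidence nonzeros, 3–6 members per reaction).

What it does not emulate: reaction stoichiometry, hub entities with
power-law degrees, or semantically meaningful attribute hierarchies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import INPUT, OUTPUT, PathwayNetwork, build_network


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the planted-structure generator.

    ``attribute_noise_prob`` is the probability that an entity's intended
    module-pool attribute is redirected to a uniformly random attribute;
    ``chain_prob`` the probability that a reaction input is drawn from the
    previous reaction's outputs; ``cross_module_link_prob`` the probability
    that a non-chained input comes from a foreign module.
    """

    n_modules: int = 4
    entities_per_module: int = 50
    reactions_per_module: int = 40
    attributes_per_module: int = 30
    attributes_per_entity: tuple[int, int] = (2, 4)
    inputs_per_reaction: tuple[int, int] = (2, 4)
    outputs_per_reaction: tuple[int, int] = (1, 2)
    cross_module_link_prob: float = 0.05
    attribute_noise_prob: float = 0.05
    chain_prob: float = 0.6
    seed: int = 0

    def __post_init__(self):
        for name in ("n_modules", "entities_per_module", "reactions_per_module",
                     "attributes_per_module"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("attributes_per_entity", "inputs_per_reaction",
                     "outputs_per_reaction"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be an increasing range >= 1")
        for name in ("cross_module_link_prob", "attribute_noise_prob",
                     "chain_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def generate_network(config: GeneratorConfig = GeneratorConfig()
                     ) -> PathwayNetwork:
    """Draw a pathway network from the planted-module model.

    Deterministic for a given config (including record order).  Raises if a
    reaction needs more distinct members than its module holds.
    """
    c = config
    if c.inputs_per_reaction[1] > c.entities_per_module:
        raise ValueError("inputs_per_reaction exceeds module size")
    if c.outputs_per_reaction[1] > c.entities_per_module:
        raise ValueError("outputs_per_reaction exceeds module size")
    if c.attributes_per_entity[1] > c.attributes_per_module:
        raise ValueError("attributes_per_entity exceeds module attribute pool")
    rng = np.random.default_rng(c.seed)

    entities, reactions, attributes = [], [], []
    ent_module, attr_pool = [], []
    for m in range(c.n_modules):
        for i in range(c.entities_per_module):
            entities.append((f"ent-m{m}-{i:03d}", f"entity {i} of module {m}"))
            ent_module.append(m)
        pool = []
        for j in range(c.attributes_per_module):
            pool.append(len(attributes))
            attributes.append((f"att-m{m}-{j:03d}",
                               f"attribute {j} of module {m}"))
        attr_pool.append(pool)

    n_attr = len(attributes)
    assignments: set[tuple[str, str]] = set()
    for v, (vid, _) in enumerate(entities):
        pool = attr_pool[ent_module[v]]
        lo, hi = c.attributes_per_entity
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(pool), size=k, replace=False)
        for idx in chosen:
            f = pool[idx]
            if rng.random() < c.attribute_noise_prob:
                f = int(rng.integers(n_attr))
            assignments.add((vid, attributes[f][0]))

    module_entities = [
        [v for v in range(len(entities)) if ent_module[v] == m]
        for m in range(c.n_modules)
    ]
    memberships: set[tuple[str, str, str]] = set()
    for m in range(c.n_modules):
        own = module_entities[m]
        foreign = [v for v in range(len(entities)) if ent_module[v] != m]
        prev_outputs: list[int] = []
        for r in range(c.reactions_per_module):
            rid = f"rxn-m{m}-{r:03d}"
            reactions.append((rid, f"reaction {r} of module {m}"))
            n_out = int(rng.integers(c.outputs_per_reaction[0],
                                     c.outputs_per_reaction[1] + 1))
            outputs = [own[i] for i in
                       rng.choice(len(own), size=n_out, replace=False)]
            n_in = int(rng.integers(c.inputs_per_reaction[0],
                                    c.inputs_per_reaction[1] + 1))
            inputs: set[int] = set()
            for _ in range(n_in):
                u = rng.random()
                if prev_outputs and u < c.chain_prob:
                    v = prev_outputs[int(rng.integers(len(prev_outputs)))]
                elif foreign and rng.random() < c.cross_module_link_prob:
                    v = foreign[int(rng.integers(len(foreign)))]
                else:
                    v = own[int(rng.integers(len(own)))]
                inputs.add(v)
            for v in inputs:
                memberships.add((entities[v][0], rid, INPUT))
            for v in outputs:
                memberships.add((entities[v][0], rid, OUTPUT))
            prev_outputs = outputs

    return build_network(entities, reactions, attributes,
                         sorted(memberships), sorted(assignments))


def ablated_config(seed: int = 0) -> GeneratorConfig:
    """Negative-control configuration: no chaining, no cross-module links,
    and heavy attribute noise — the planted signal is strongly degraded
    (though module co-membership remains in the incidence structure)."""
    return GeneratorConfig(chain_prob=0.0, cross_module_link_prob=0.0,
                           attribute_noise_prob=0.5, seed=seed)


def make_toy() -> PathwayNetwork:
    """The fixed 3-entity / 2-reaction / 2-attribute example network.

    Reaction e1 consumes v1 and v2 and produces v3; e2 consumes v3 and
    produces v1.  Attribute f1 belongs to v1 and v3, f2 to v2.  Bit-stable
    across releases; used throughout the test-suite and the docs.
    """
    return build_network(
        entities=[("v1", "entity v1"), ("v2", "entity v2"), ("v3", "entity v3")],
        reactions=[("e1", "reaction e1"), ("e2", "reaction e2")],
        attributes=[("f1", "attribute f1"), ("f2", "attribute f2")],
        memberships=[
            ("v1", "e1", INPUT), ("v2", "e1", INPUT), ("v3", "e1", OUTPUT),
            ("v3", "e2", INPUT), ("v1", "e2", OUTPUT),
        ],
        assignments=[("v1", "f1"), ("v3", "f1"), ("v2", "f2")],
    )
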