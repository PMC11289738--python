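"""Shapley-value attribution for individual link predictions.

To explain why a model scored candidate entity c for reaction e, the
reaction's current member nodes and those members' attributes become the
players of a cooperative game.  The value of a coalition S is the model's
score for c when everything outside S is masked: a masked node loses its
membership in the query reaction (but keeps its other reactions — masking
ablates participation in this prediction, not the entity), and a masked
attribute has its (entity, attribute) cell zeroed in X.  Model parameters
stay frozen; only the inputs change.  The empty coalition leaves an empty
readout, so f(empty) = sigmoid(0) = 0.5 is the natural baseline.

Shapley values are computed exactly by subset enumeration when the game is
small, and otherwise estimated by uniformly sampled player permutations
(marginal-contribution averaging), capped at a fixed number of value-
function evaluations.  Permutation estimates preserve the efficiency
identity sum(phi) = f(N) - f(empty) exactly, because each permutation's
marginals telescope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .network import PathwayNetwork, mask_memberships
from .pipelines import readout

EXACT_PLAYER_CAP = 16  # enumeration above this is refused


@dataclass(frozen=True)
class ShapPlayer:
    """A maskable element: a member node of the query reaction, or an
    attribute of one of those members."""

    kind: str  # "node" | "attribute"
    entity_id: str
    attribute_id: str | None = None

    @property
    def label(self) -> str:
        if self.kind == "node":
            return self.entity_id
        return f"{self.attribute_id}@{self.entity_id}"


class ShapGame:
    """A cooperative game over an ordered player list.

    ``value_fn`` maps a frozenset of player indices to a real score; values
    are memoised, so the value of a coalition depends only on its members
    and repeated queries are free.
    """

    def __init__(self, players: list, value_fn: Callable[[frozenset], float]):
        if len(set(players)) != len(players):
            raise ValueError("players must be unique")
        self.players = list(players)
        self._value_fn = value_fn
        self._cache: dict[frozenset, float] = {}
        self.n_evaluations = 0

    @property
    def n_players(self) -> int:
        return len(self.players)

    def value(self, coalition) -> float:
        key = frozenset(coalition)
        if not key <= set(range(self.n_players)):
            raise ValueError("coalition contains unknown players")
        if key not in self._cache:
            self._cache[key] = float(self._value_fn(key))
            self.n_evaluations += 1
        return self._cache[key]


@dataclass(frozen=True)
class ShapAttribution:
    """Per-player Shapley values and the resulting contributor ranking.

    ``ranking`` lists (player, phi) sorted by phi descending (ties broken
    by player order).  ``sum(phi) = f(N) - f(empty)`` holds to numerical
    precision for both methods.
    """

    players: tuple
    phi: tuple[float, ...]
    method: str  # "exact" | "sampled"
    n_evaluations: int
    seed: int | None = None

    @property
    def ranking(self) -> list:
        order = sorted(range(len(self.players)),
                       key=lambda i: (-self.phi[i], i))
        return [(self.players[i], self.phi[i]) for i in order]


def shap_exact(game: ShapGame) -> ShapAttribution:
    """Exact Shapley values by full subset enumeration.

    phi_i = sum over S of |S|!(n-|S|-1)!/n! [f(S+i) - f(S)] with S ranging
    over subsets of the other players.  Refuses games above
    ``EXACT_PLAYER_CAP`` players (use :func:`shap_sampled`).
    """
    n = game.n_players
    if n == 0:
        raise ValueError("game has no players")
    if n > EXACT_PLAYER_CAP:
        raise ValueError(
            f"{n} players exceed the exact-enumeration cap "
            f"({EXACT_PLAYER_CAP}); use shap_sampled")
    fact = [math.factorial(k) for k in range(n + 1)]
    phi = [0.0] * n
    others = list(range(n))
    for i in range(n):
        rest = [j for j in others if j != i]
        for size in range(n):
            w = fact[size] * fact[n - size - 1] / fact[n]
            for S in itertools.combinations(rest, size):
                Sset = frozenset(S)
                phi[i] += w * (game.value(Sset | {i}) - game.value(Sset))
    return ShapAttribution(players=tuple(game.players), phi=tuple(phi),
                           method="exact", n_evaluations=game.n_evaluations)


def shap_sampled(game: ShapGame, cap: int = 1024,
                 seed: int = 0) -> ShapAttribution:
    """Permutation-sampling estimate within an evaluation budget.

    Delegates to exact enumeration whenever 2^n fits in the cap.  Otherwise
    draws uniform player permutations and averages each player's marginal
    contribution; one permutation costs n evaluations beyond the shared
    empty-coalition value, and sampling stops before the cap is exceeded.
    Deterministic per seed.
    """
    n = game.n_players
    if n == 0:
        raise ValueError("game has no players")
    if cap < 2 * n:
        raise ValueError(f"cap {cap} too small; need at least {2 * n}")
    if n <= EXACT_PLAYER_CAP and 2 ** n <= cap:
        return shap_exact(game)
    rng = np.random.default_rng(seed)
    n_perms = max(1, (cap - 1) // n)
    sums = np.zeros(n)
    for _ in range(n_perms):
        perm = rng.permutation(n)
        prev = game.value(frozenset())
        coalition: set[int] = set()
        for i in perm:
            coalition.add(int(i))
            cur = game.value(frozenset(coalition))
            sums[i] += cur - prev
            prev = cur
    phi = sums / n_perms
    return ShapAttribution(players=tuple(game.players),
                           phi=tuple(float(p) for p in phi),
                           method="sampled",
                           n_evaluations=game.n_evaluations, seed=seed)


# ---------------------------------------------------------------------------
# wiring the game to a trained link model
# ---------------------------------------------------------------------------

def build_players(network: PathwayNetwork, reaction_id: str) -> list[ShapPlayer]:
    """Player universe: the reaction's member nodes plus the attributes of
    those members (attributes of non-members are not players)."""
    e = network.reaction_index(reaction_id)
    players: list[ShapPlayer] = []
    for v in network.reaction_members(e):
        players.append(ShapPlayer("node", network.entities[v].id))
    for v in network.reaction_members(e):
        for f in network.entity_attributes(v):
            players.append(ShapPlayer("attribute", network.entities[v].id,
                                      network.attributes[f].id))
    return players


def _masked_network(network: PathwayNetwork, reaction_id: str,
                    players: list[ShapPlayer],
                    coalition: frozenset) -> PathwayNetwork:
    e = network.reaction_index(reaction_id)
    masked_mem = []
    masked_attr_cells = []
    for idx, p in enumerate(players):
        if idx in coalition:
            continue
        v = network.entity_index(p.entity_id)
        if p.kind == "node":
            for role in ("input", "output"):
                if (v, e, role) in network.memberships:
                    masked_mem.append((v, e, role))
        else:
            f = network.attribute_index(p.attribute_id)
            masked_attr_cells.append((v, f))
    net = network
    if masked_mem:
        net = _mask_allow_empty(net, masked_mem)
    if masked_attr_cells:
        net = _zero_X_cells(net, masked_attr_cells)
    return net


def _mask_allow_empty(network: PathwayNetwork, triples) -> PathwayNetwork:
    """Membership masking that tolerates emptying the query reaction (the
    empty coalition legitimately removes every member; the zero-readout
    convention handles it)."""
    from .network import _build_matrices
    remaining = network.memberships - set(triples)
    H, H_s, H_t, X = _build_matrices(
        network.n_entities, network.n_reactions, network.n_attributes,
        frozenset(remaining), network.assignments)
    return PathwayNetwork(
        entities=network.entities, reactions=network.reactions,
        attributes=network.attributes, memberships=frozenset(remaining),
        assignments=network.assignments, H=H, H_s=H_s, H_t=H_t, X=X)


def _zero_X_cells(network: PathwayNetwork, cells) -> PathwayNetwork:
    from .network import _build_matrices
    remaining = network.assignments - {(v, f) for (v, f) in cells}
    H, H_s, H_t, X = _build_matrices(
        network.n_entities, network.n_reactions, network.n_attributes,
        network.memberships, frozenset(remaining))
    return PathwayNetwork(
        entities=network.entities, reactions=network.reactions,
        attributes=network.attributes, memberships=network.memberships,
        assignments=frozenset(remaining), H=H, H_s=H_s, H_t=H_t, X=X)


def coalition_value(model, network: PathwayNetwork, reaction_id: str,
                    candidate_id: str, players: list[ShapPlayer],
                    coalition: frozenset) -> float:
    """Model score for the candidate with everything outside S masked.

    Rebuilds the masked network, recomputes embeddings with frozen
    parameters, and returns sigmoid(r_e . z_candidate).  Masking a node also
    silences its attribute players' direct feature contribution for this
    query (the node leaves the readout), though its features still propagate
    through the rest of the hypergraph.
    """
    e = network.reaction_index(reaction_id)
    if network.entity_index(candidate_id) in network.reaction_members(e):
        raise ValueError(
            f"candidate {candidate_id!r} is already a member of {reaction_id!r}")
    net = _masked_network(network, reaction_id, players, coalition)
    return model.coalition_score(net, reaction_id, candidate_id)


def make_game(model, network: PathwayNetwork, reaction_id: str,
              candidate_id: str) -> ShapGame:
    """Assemble the masking game for one predicted link."""
    players = build_players(network, reaction_id)
    if not players:
        raise ValueError(f"reaction {reaction_id!r} has no members to explain")

    def value_fn(S: frozenset) -> float:
        return coalition_value(model, network, reaction_id, candidate_id,
                               players, S)

    return ShapGame(players, value_fn)


def explain_prediction(model, network: PathwayNetwork, reaction_id: str,
                       candidate_id: str, cap: int = 1024,
                       seed: int = 0) -> ShapAttribution:
    """Shapley attribution of one predicted link to the reaction's members
    and their attributes.

    Returns the attribution whose ``ranking`` lists contributors by
    descending Shapley value — the top entries are the nodes/attributes that
    drive the prediction most.
    """
    game = make_game(model, network, reaction_id, candidate_id)
    return shap_sampled(game, cap=cap, seed=seed)
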