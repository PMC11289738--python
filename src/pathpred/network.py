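"""Attributed-hypergraph data model for biochemical pathway networks.

A pathway network is a hypergraph G = (V, E, F, H, X): biochemical entities
are nodes, reactions are hyperedges, and entity components/family members are
binary node attributes.  ``H`` is the |V|x|E| incidence matrix, with role-
restricted variants ``H_s`` (entities that enter a reaction as inputs) and
``H_t`` (outputs); ``X`` is the |V|x|F| attribute matrix.  All four are stored
as scipy CSR matrices because real pathway networks are very sparse (a few
thousand nonzeros in matrices with millions of cells), but every operation in
this package is defined on their dense {0,1} semantics.

Row/column order is the declaration order of the records and is fixed for the
lifetime of a network; every matrix, embedding and ranking indexes against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp

Role = str
INPUT: Role = "input"
OUTPUT: Role = "output"
_ROLES = (INPUT, OUTPUT)


class Record(NamedTuple):
    """An entity, reaction or attribute: a stable id plus a display name."""

    id: str
    name: str


class ValidationError(ValueError):
    """Raised when records, memberships or assignments are inconsistent."""


def _as_records(items: Iterable) -> tuple[Record, ...]:
    out = []
    for it in items:
        if isinstance(it, Record):
            out.append(it)
        elif isinstance(it, str):
            out.append(Record(it, it))
        else:
            i, n = it
            out.append(Record(str(i), str(n)))
    return tuple(out)


def _check_unique(records: Sequence[Record], kind: str) -> dict[str, int]:
    index: dict[str, int] = {}
    for i, rec in enumerate(records):
        if rec.id in index:
            raise ValidationError(f"duplicate {kind} id: {rec.id!r}")
        index[rec.id] = i
    return index


@dataclass(frozen=True)
class PathwayNetwork:
    """Validated attributed hypergraph.

    Construct via :func:`build_network`; the constructor assumes its inputs
    are already consistent.  ``memberships`` holds (entity index, reaction
    index, role) triples and ``assignments`` (entity index, attribute index)
    pairs, both as frozensets; an entity may hold both the input and the
    output role in the same reaction (e.g. a catalyst), in which case H
    stores a single 1.
    """

    entities: tuple[Record, ...]
    reactions: tuple[Record, ...]
    attributes: tuple[Record, ...]
    memberships: frozenset[tuple[int, int, Role]]
    assignments: frozenset[tuple[int, int]]
    H: sp.csr_matrix = field(repr=False)
    H_s: sp.csr_matrix = field(repr=False)
    H_t: sp.csr_matrix = field(repr=False)
    X: sp.csr_matrix = field(repr=False)

    # -- index helpers -----------------------------------------------------
    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    def entity_index(self, entity_id: str) -> int:
        try:
            return self._entity_idx[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity id: {entity_id!r}") from None

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._reaction_idx[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction id: {reaction_id!r}") from None

    def attribute_index(self, attribute_id: str) -> int:
        try:
            return self._attribute_idx[attribute_id]
        except KeyError:
            raise KeyError(f"unknown attribute id: {attribute_id!r}") from None

    @property
    def _entity_idx(self) -> dict[str, int]:
        d = self.__dict__.get("_entity_idx_cache")
        if d is None:
            d = {r.id: i for i, r in enumerate(self.entities)}
            object.__setattr__(self, "_entity_idx_cache", d)
        return d

    @property
    def _reaction_idx(self) -> dict[str, int]:
        d = self.__dict__.get("_reaction_idx_cache")
        if d is None:
            d = {r.id: i for i, r in enumerate(self.reactions)}
            object.__setattr__(self, "_reaction_idx_cache", d)
        return d

    @property
    def _attribute_idx(self) -> dict[str, int]:
        d = self.__dict__.get("_attribute_idx_cache")
        if d is None:
            d = {r.id: i for i, r in enumerate(self.attributes)}
            object.__setattr__(self, "_attribute_idx_cache", d)
        return d

    # -- views -------------------------------------------------------------
    def reaction_members(self, e: int, role: Role | None = None) -> list[int]:
        """Sorted entity indices of reaction ``e`` (optionally one role)."""
        if role is None:
            col = self.H
        elif role == INPUT:
            col = self.H_s
        elif role == OUTPUT:
            col = self.H_t
        else:
            raise ValueError(f"unknown role: {role!r}")
        return sorted(col.getcol(e).tocoo().row.tolist())

    def entity_attributes(self, v: int) -> list[int]:
        """Sorted attribute indices assigned to entity ``v``."""
        return sorted(self.X.getrow(v).tocoo().col.tolist())

    def decompose(self):
        """Records + relational sets, sufficient to rebuild the network."""
        member_ids = [
            (self.entities[v].id, self.reactions[e].id, role)
            for (v, e, role) in sorted(self.memberships)
        ]
        assign_ids = [
            (self.entities[v].id, self.attributes[f].id)
            for (v, f) in sorted(self.assignments)
        ]
        return (
            list(self.entities),
            list(self.reactions),
            list(self.attributes),
            member_ids,
            assign_ids,
        )


def _build_matrices(
    n_v: int,
    n_e: int,
    n_f: int,
    memberships: frozenset[tuple[int, int, Role]],
    assignments: frozenset[tuple[int, int]],
):
    def incidence(pairs, shape):
        pairs = sorted(pairs)
        rows = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
        cols = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
        data = np.ones(len(pairs), dtype=np.float64)
        return sp.csr_matrix((data, (rows, cols)), shape=shape)

    s_pairs = {(v, e) for (v, e, r) in memberships if r == INPUT}
    t_pairs = {(v, e) for (v, e, r) in memberships if r == OUTPUT}
    h_pairs = s_pairs | t_pairs  # H is the elementwise OR of H_s and H_t
    H = incidence(h_pairs, (n_v, n_e))
    H_s = incidence(s_pairs, (n_v, n_e))
    H_t = incidence(t_pairs, (n_v, n_e))
    X = incidence(assignments, (n_v, n_f))
    return H, H_s, H_t, X


def build_network(
    entities: Iterable,
    reactions: Iterable,
    attributes: Iterable,
    memberships: Iterable[tuple[str, str, Role]],
    assignments: Iterable[tuple[str, str]] = (),
) -> PathwayNetwork:
    """Validate records and relations and materialize H, H_s, H_t and X.

    Parameters
    ----------
    entities, reactions, attributes
        Iterables of ``Record``, ``(id, name)`` pairs, or bare id strings.
    memberships
        ``(entity_id, reaction_id, role)`` triples, role in {input, output}.
    assignments
        ``(entity_id, attribute_id)`` pairs.

    Raises
    ------
    ValidationError
        On duplicate ids, dangling references, unknown roles, or a reaction
        with no members.
    """
    ents = _as_records(entities)
    rxns = _as_records(reactions)
    attrs = _as_records(attributes)
    e_idx = _check_unique(ents, "entity")
    r_idx = _check_unique(rxns, "reaction")
    f_idx = _check_unique(attrs, "attribute")

    mem: set[tuple[int, int, Role]] = set()
    for (vid, eid, role) in memberships:
        if role not in _ROLES:
            raise ValidationError(f"unknown role {role!r} for ({vid!r}, {eid!r})")
        if vid not in e_idx:
            raise ValidationError(f"membership references undeclared entity {vid!r}")
        if eid not in r_idx:
            raise ValidationError(f"membership references undeclared reaction {eid!r}")
        mem.add((e_idx[vid], r_idx[eid], role))

    asn: set[tuple[int, int]] = set()
    for (vid, fid) in assignments:
        if vid not in e_idx:
            raise ValidationError(f"assignment references undeclared entity {vid!r}")
        if fid not in f_idx:
            raise ValidationError(f"assignment references undeclared attribute {fid!r}")
        asn.add((e_idx[vid], f_idx[fid]))

    populated = {e for (_, e, _) in mem}
    for j, rec in enumerate(rxns):
        if j not in populated:
            raise ValidationError(f"reaction {rec.id!r} has no members")

    H, H_s, H_t, X = _build_matrices(len(ents), len(rxns), len(attrs),
                                     frozenset(mem), frozenset(asn))
    return PathwayNetwork(
        entities=ents, reactions=rxns, attributes=attrs,
        memberships=frozenset(mem), assignments=frozenset(asn),
        H=H, H_s=H_s, H_t=H_t, X=X,
    )


@dataclass(frozen=True)
class DegreeInfo:
    """Diagonal degree matrices (stored as 1-D arrays of the diagonals).

    ``d_v[v]`` is the hypergraph node degree (number of reactions containing
    v), ``d_e[e]`` the hyperedge degree (number of distinct member entities),
    and ``d[v]`` the node degree in the clique-expanded graph A = H Hᵀ (row
    sums of A).  Isolated nodes legally have degree 0; normalisations apply a
    pseudo-inverse convention (1/0 -> 0) downstream.
    """

    d_v: np.ndarray
    d_e: np.ndarray
    d: np.ndarray

    @property
    def D_v(self) -> np.ndarray:
        return np.diag(self.d_v)

    @property
    def D_e(self) -> np.ndarray:
        return np.diag(self.d_e)

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.d)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Clique expansion A = H Hᵀ: integer co-membership counts, symmetric.

    ``A[v, u]`` counts the reactions containing both v and u; the diagonal
    equals the node degrees.  No thresholding and no added self-loops.
    """

    A: sp.csr_matrix

    def toarray(self) -> np.ndarray:
        return np.asarray(self.A.todense())


def clique_expand(network: PathwayNetwork) -> AdjacencyMatrix:
    """Convert the hypergraph to an ordinary weighted graph via A = H Hᵀ."""
    A = (network.H @ network.H.T).tocsr()
    return AdjacencyMatrix(A=A)


def degree_matrices(network: PathwayNetwork) -> DegreeInfo:
    """Node, hyperedge, and clique-graph degree diagonals."""
    d_v = np.asarray(network.H.sum(axis=1)).ravel()
    d_e = np.asarray(network.H.sum(axis=0)).ravel()
    A = network.H @ network.H.T
    d = np.asarray(A.sum(axis=1)).ravel()
    return DegreeInfo(d_v=d_v, d_e=d_e, d=d)


def mask_memberships(
    network: PathwayNetwork,
    masked: Iterable[tuple[int, int, Role]],
) -> PathwayNetwork:
    """Return a copy with the given (entity, reaction, role) triples removed.

    The original network is unmodified and attribute assignments are
    untouched.  Raises :class:`ValidationError` if a listed triple is absent
    or if the removal would leave a reaction with zero members (the average
    readout over an empty member set would be undefined as a label source).
    """
    masked = set(masked)
    for trip in masked:
        if trip not in network.memberships:
            raise ValidationError(f"membership not in network: {trip}")
    remaining = network.memberships - masked
    populated = {e for (_, e, _) in remaining}
    for j in range(network.n_reactions):
        if j not in populated:
            raise ValidationError(
                f"masking would leave reaction {network.reactions[j].id!r} empty"
            )
    H, H_s, H_t, X = _build_matrices(
        network.n_entities, network.n_reactions, network.n_attributes,
        frozenset(remaining), network.assignments,
    )
    return PathwayNetwork(
        entities=network.entities, reactions=network.reactions,
        attributes=network.attributes,
        memberships=frozenset(remaining), assignments=network.assignments,
        H=H, H_s=H_s, H_t=H_t, X=X,
    )


def mask_assignments(
    network: PathwayNetwork,
    masked: Iterable[tuple[int, int]],
) -> PathwayNetwork:
    """Return a copy with the given (entity, attribute) pairs removed from X."""
    masked = set(masked)
    for pair in masked:
        if pair not in network.assignments:
            raise ValidationError(f"assignment not in network: {pair}")
    remaining = network.assignments - masked
    H, H_s, H_t, X = _build_matrices(
        network.n_entities, network.n_reactions, network.n_attributes,
        network.memberships, frozenset(remaining),
    )
    return PathwayNetwork(
        entities=network.entities, reactions=network.reactions,
        attributes=network.attributes,
        memberships=network.memberships, assignments=frozenset(remaining),
        H=H, H_s=H_s, H_t=H_t, X=X,
    )


def add_memberships(
    network: PathwayNetwork,
    added: Iterable[tuple[int, int, Role]],
) -> PathwayNetwork:
    """Inverse of :func:`mask_memberships` for existing entity/reaction ids."""
    added = set(added)
    for (v, e, role) in added:
        if not (0 <= v < network.n_entities and 0 <= e < network.n_reactions):
            raise ValidationError(f"membership out of range: {(v, e, role)}")
        if role not in _ROLES:
            raise ValidationError(f"unknown role: {role!r}")
    remaining = network.memberships | added
    H, H_s, H_t, X = _build_matrices(
        network.n_entities, network.n_reactions, network.n_attributes,
        frozenset(remaining), network.assignments,
    )
    return PathwayNetwork(
        entities=network.entities, reactions=network.reactions,
        attributes=network.attributes,
        memberships=frozenset(remaining), assignments=network.assignments,
        H=H, H_s=H_s, H_t=H_t, X=X,
    )
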