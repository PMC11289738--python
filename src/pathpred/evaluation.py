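"""Data splitting, ranking metrics, and the repeated evaluation protocol.

Held-out units are individual relationships: (entity, reaction, role)
memberships for the link tasks, (entity, attribute) assignments for the
attribute task.  A random 8:1:1 split masks the validation/test pairs out of
the training network, subject to the constraint that no reaction may lose
its last member.  Ranking quality is measured with binary-relevance NDCG@K
and the top-K hit indicator ACC@K; the headline protocol repeats
split/train/evaluate five times with independent seeds and reports mean and
sample standard deviation per metric.

The conventional "NDCG" value without a cutoff is exposed as ``NDCG@inf``
(the full-ranking value) alongside the cutoff metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import (INPUT, OUTPUT, PathwayNetwork, mask_assignments,
                      mask_memberships)
from .pipelines import TrainConfig

LINK_TASKS = ("input_link", "output_link")
TASKS = LINK_TASKS + ("attribute",)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def ndcg_at_k(ranked_ids: Sequence[str], relevant: set[str],
              k: int | None = 10) -> float:
    """Binary-relevance NDCG at cutoff ``k`` (``None`` = full ranking).

    DCG sums 1/log2(rank+1) over relevant items in the top k (1-based
    ranks); the normaliser is the DCG of an ideal ranking placing
    min(|relevant|, k) hits first.  Returns 0 for an empty relevant set.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    if not relevant:
        return 0.0
    top = ranked_ids if k is None else ranked_ids[:k]
    dcg = sum(1.0 / math.log2(j + 2)
              for j, rid in enumerate(top) if rid in relevant)
    n_ideal = len(relevant) if k is None else min(len(relevant), k)
    idcg = sum(1.0 / math.log2(j + 2) for j in range(n_ideal))
    return dcg / idcg


def acc_at_k(ranked_ids: Sequence[str], relevant: set[str],
             k: int = 10) -> float:
    """1.0 iff any relevant id appears among the first ``k`` ranked ids."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 if any(rid in relevant for rid in ranked_ids[:k]) else 0.0


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition of maskable pairs plus the masked
    training network.

    ``pairs`` are (entity index, reaction index, role) for link tasks and
    (entity index, attribute index) for the attribute task.  The three lists
    are disjoint; validation and test each hold ~10% (floor) of the task's
    pairs and the remainder stays in training.
    """

    task: str
    train_pairs: tuple
    val_pairs: tuple
    test_pairs: tuple
    ratios: tuple[int, int, int]
    seed: int
    train_network: PathwayNetwork = field(repr=False)


def _link_pool(network: PathwayNetwork, role: str):
    return sorted((v, e, r) for (v, e, r) in network.memberships if r == role)


def random_split(network: PathwayNetwork, task: str,
                 ratios: tuple[int, int, int] = (8, 1, 1),
                 seed: int = 0) -> SplitSpec:
    """Uniform 8:1:1 split of maskable pairs, never emptying a reaction.

    Pairs are drawn without replacement for test and validation in a seeded
    random order; a pair whose removal would leave its reaction with no
    members at all is ineligible and skipped.  Raises if the quota cannot be
    met, stating the achievable maximum.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task: {task!r}")
    if len(ratios) != 3 or any(r < 0 for r in ratios) or ratios[0] <= 0:
        raise ValueError("ratios must be three nonnegative ints, train > 0")
    rng = np.random.default_rng(seed)

    if task == "attribute":
        pool = sorted(network.assignments)
    else:
        role = INPUT if task == "input_link" else OUTPUT
        pool = _link_pool(network, role)
    n = len(pool)
    total = sum(ratios)
    n_val = n * ratios[1] // total
    n_test = n * ratios[2] // total
    if n_val == 0 or n_test == 0:
        raise ValueError(
            f"too few pairs ({n}) for nonempty validation and test sets")

    order = rng.permutation(n)
    held: list = []
    if task == "attribute":
        for idx in order:
            if len(held) == n_val + n_test:
                break
            held.append(pool[idx])
    else:
        # member count per reaction at the H level (distinct entities)
        roles_left: dict[tuple[int, int], set] = {}
        for (v, e, r) in network.memberships:
            roles_left.setdefault((v, e), set()).add(r)
        members_left = [0] * network.n_reactions
        for (v, e) in roles_left:
            members_left[e] += 1
        for idx in order:
            if len(held) == n_val + n_test:
                break
            (v, e, r) = pool[idx]
            would_vanish = roles_left[(v, e)] == {r}
            if would_vanish and members_left[e] == 1:
                continue  # would empty the reaction
            held.append((v, e, r))
            roles_left[(v, e)] = roles_left[(v, e)] - {r}
            if would_vanish:
                members_left[e] -= 1
        if len(held) < n_val + n_test:
            raise ValueError(
                f"never-empty-reaction constraint allows at most {len(held)} "
                f"held-out pairs; {n_val + n_test} requested")

    test_pairs = tuple(held[:n_test])
    val_pairs = tuple(held[n_test:n_test + n_val])
    held_set = set(held[:n_test + n_val])
    train_pairs = tuple(p for p in pool if p not in held_set)

    if task == "attribute":
        train_net = mask_assignments(network, held_set)
    else:
        train_net = mask_memberships(network, held_set)
    return SplitSpec(task=task, train_pairs=train_pairs, val_pairs=val_pairs,
                     test_pairs=test_pairs, ratios=tuple(ratios), seed=seed,
                     train_network=train_net)


@dataclass(frozen=True)
class TemporalDiff:
    """Additions between two database versions, plus bookkeeping counts."""

    new_pairs: tuple
    n_removed: int
    n_new_entity: int
    n_new_reaction: int


def temporal_split(old: PathwayNetwork, new: PathwayNetwork) -> TemporalDiff:
    """Memberships added between versions, restricted to ids the old
    network already knows.

    Returns id-level (entity_id, reaction_id, role) triples present in
    ``new`` but not ``old`` whose entity and reaction both exist in ``old``.
    Additions involving brand-new ids, and removals, are only counted.
    """
    def id_pairs(net):
        return {(net.entities[v].id, net.reactions[e].id, r)
                for (v, e, r) in net.memberships}

    old_pairs, new_pairs = id_pairs(old), id_pairs(new)
    old_ents = {rec.id for rec in old.entities}
    old_rxns = {rec.id for rec in old.reactions}
    added = new_pairs - old_pairs
    eligible = sorted(p for p in added
                      if p[0] in old_ents and p[1] in old_rxns)
    # a pair may involve both a new entity and a new reaction
    n_new_entity = sum(1 for p in added if p[0] not in old_ents)
    n_new_reaction = sum(1 for p in added if p[1] not in old_rxns)
    return TemporalDiff(new_pairs=tuple(eligible),
                        n_removed=len(old_pairs - new_pairs),
                        n_new_entity=n_new_entity,
                        n_new_reaction=n_new_reaction)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QueryMetrics:
    query_id: str
    n_relevant: int
    values: dict


def _group_by_query(pairs, task):
    groups: dict[int, list[int]] = {}
    for p in pairs:
        if task == "attribute":
            v, f = p
            groups.setdefault(v, []).append(f)
        else:
            v, e, _ = p
            groups.setdefault(e, []).append(v)
    return groups


def evaluate(model, split: SplitSpec, ks: Sequence[int] = (1, 10),
             subset: str = "test") -> dict:
    """Score every held-out query of a split with NDCG@K / ACC@K.

    Each held-out pair's reaction (or entity) becomes one query; multiple
    pairs of the same query in the same subset are evaluated together as
    multiple relevant items.  Candidates already linked in the *training*
    network are excluded from the ranking; the held-out items themselves are
    therefore rankable.  Returns per-query metrics and their means,
    including the full-ranking ``NDCG@inf``.
    """
    task = split.task
    direction = getattr(model, "direction", None)
    if task in LINK_TASKS:
        want = "input" if task == "input_link" else "output"
        if direction is not None and direction != want:
            raise ValueError(
                f"model direction {direction!r} does not match task {task!r}")
    elif direction is not None:
        raise ValueError("link model cannot be evaluated on an attribute split")
    net = split.train_network
    pairs = {"val": split.val_pairs, "test": split.test_pairs}[subset]
    groups = _group_by_query(pairs, task)
    per_query: list[QueryMetrics] = []
    pool_size = net.n_entities if task in LINK_TASKS else net.n_attributes
    for q, items in sorted(groups.items()):
        if task in LINK_TASKS:
            qid = net.reactions[q].id
            relevant = {net.entities[v].id for v in items}
            ranking = model.predict(qid, k=pool_size, network=net)
        else:
            qid = net.entities[q].id
            relevant = {net.attributes[f].id for f in items}
            ranking = model.predict(qid, k=pool_size, network=net)
        values = {}
        for k in ks:
            values[f"NDCG@{k}"] = ndcg_at_k(ranking.candidate_ids, relevant, k)
            values[f"ACC@{k}"] = acc_at_k(ranking.candidate_ids, relevant, k)
        values["NDCG@inf"] = ndcg_at_k(ranking.candidate_ids, relevant, None)
        per_query.append(QueryMetrics(qid, len(relevant), values))
    if not per_query:
        raise ValueError(f"no held-out pairs in subset {subset!r}")
    metric_names = list(per_query[0].values)
    means = {name: float(np.mean([q.values[name] for q in per_query]))
             for name in metric_names}
    return {"per_query": per_query, "means": means,
            "n_queries": len(per_query)}


@dataclass(frozen=True)
class MetricReport:
    """Mean and sample standard deviation per metric over repeats."""

    task: str
    model: str
    per_repeat: dict  # metric name -> list of per-repeat means
    mean: dict
    std: dict
    n_repeats: int


def cross_validate(network: PathwayNetwork, task: str, config: TrainConfig,
                   n_repeats: int = 5, base_seed: int = 0,
                   ks: Sequence[int] = (1, 10),
                   ratios: tuple[int, int, int] = (8, 1, 1)) -> MetricReport:
    """Repeat (split, train, evaluate) with independent seeds.

    The benchmark protocol: ``n_repeats`` independent seeded 8:1:1
    re-splits (the simultaneous 8:1:1 and five-fold statements cannot both
    hold as true disjoint folds, so repeats with fresh splits implement the
    five-run mean +/- std).
    """
    from .estimators import train_attribute_model, train_link_model

    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    per_repeat: dict[str, list[float]] = {}
    for rep in range(n_repeats):
        seed = base_seed + rep
        split = random_split(network, task, ratios=ratios, seed=seed)
        cfg = TrainConfig(**{**config.__dict__, "task": task, "seed": seed})
        if task == "attribute":
            model = train_attribute_model(split.train_network, cfg,
                                          exclude_pairs=split.val_pairs
                                          + split.test_pairs)
        else:
            model = train_link_model(split.train_network, cfg.direction, cfg)
        result = evaluate(model, split, ks=ks, subset="test")
        for name, val in result["means"].items():
            per_repeat.setdefault(name, []).append(val)
    mean = {k: float(np.mean(v)) for k, v in per_repeat.items()}
    std = {k: float(np.std(v, ddof=1)) for k, v in per_repeat.items()}
    return MetricReport(task=task, model=config.model, per_repeat=per_repeat,
                        mean=mean, std=std, n_repeats=n_repeats)
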