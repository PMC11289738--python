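"""Ranking metrics against brute-force oracles, split soundness, temporal
diffs, and the repeated-evaluation protocol."""

import math

import numpy as np
import pytest

import pathpred as pp
from pathpred.network import INPUT, OUTPUT


def oracle_ndcg(ranked, relevant, k):
    """Brute-force DCG/IDCG from the definition."""
    if not relevant:
        return 0.0
    top = ranked if k is None else ranked[:k]
    dcg = 0.0
    for rank, rid in enumerate(top, start=1):
        if rid in relevant:
            dcg += 1.0 / math.log2(rank + 1)
    ideal_hits = len(relevant) if k is None else min(len(relevant), k)
    idcg = sum(1.0 / math.log2(r + 1) for r in range(1, ideal_hits + 1))
    return dcg / idcg


class TestMetricOracles:
    def test_hit_at_rank_1_is_perfect(self):
        assert pp.ndcg_at_k(["a", "b", "c"], {"a"}, 10) == 1.0

    def test_hit_at_rank_2_closed_form(self):
        assert pp.ndcg_at_k(["x", "a", "b"], {"a"}, 10) == pytest.approx(
            1.0 / math.log2(3), abs=1e-12)
        assert pp.ndcg_at_k(["x", "a", "b"], {"a"}, 10) == pytest.approx(
            0.6309, abs=1e-4)

    def test_miss_and_empty_relevant_are_zero(self):
        assert pp.ndcg_at_k(["a", "b"], {"z"}, 2) == 0.0
        assert pp.ndcg_at_k(["a", "b"], set(), 2) == 0.0

    def test_acc_boundaries(self):
        ranked = [f"v{i}" for i in range(20)]
        assert pp.acc_at_k(ranked, {"v9"}, 10) == 1.0   # at rank K
        assert pp.acc_at_k(ranked, {"v10"}, 10) == 0.0  # at rank K+1
        assert pp.acc_at_k(ranked, set(), 10) == 0.0

    def test_thousand_random_rankings_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            ranked = [f"v{i}" for i in rng.permutation(n)]
            relevant = {f"v{i}" for i in
                        rng.choice(n, size=int(rng.integers(0, n + 1)),
                                   replace=False)}
            k = int(rng.integers(1, 15))
            assert pp.ndcg_at_k(ranked, relevant, k) == pytest.approx(
                oracle_ndcg(ranked, relevant, k), abs=1e-12)
            assert pp.ndcg_at_k(ranked, relevant, None) == pytest.approx(
                oracle_ndcg(ranked, relevant, None), abs=1e-12)
            hits = any(r in relevant for r in ranked[:k])
            assert pp.acc_at_k(ranked, relevant, k) == float(hits)

    def test_acc_equals_ndcg_at_1_with_single_relevant(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            ranked = [f"v{i}" for i in rng.permutation(10)]
            relevant = {f"v{int(rng.integers(10))}"}
            assert pp.acc_at_k(ranked, relevant, 1) == \
                pp.ndcg_at_k(ranked, relevant, 1)


@pytest.fixture(scope="module")
def split_net():
    return pp.generate_network(pp.GeneratorConfig(
        n_modules=2, entities_per_module=20, reactions_per_module=15,
        seed=1))


class TestRandomSplit:

    def test_ratio_arithmetic_floor_rounding(self):
        # 20 input-role pairs at 8:1:1 -> 2 test, 2 val, 16 train
        entities = [f"v{i}" for i in range(20)]
        reactions = [f"e{j}" for j in range(5)]
        mems = [(f"v{4 * j + i}", f"e{j}", INPUT)
                for j in range(5) for i in range(4)]
        net = pp.build_network(entities, reactions, [], mems)
        split = pp.random_split(net, "input_link", seed=0)
        assert len(split.test_pairs) == 2
        assert len(split.val_pairs) == 2
        assert len(split.train_pairs) == 16

    def test_leak_free_and_constraint(self, split_net):
        net = split_net
        split = pp.random_split(net, "input_link", seed=3)
        train_mem = split.train_network.memberships
        for pair in split.val_pairs + split.test_pairs:
            assert pair not in train_mem
        counts = np.asarray(split.train_network.H.sum(axis=0)).ravel()
        assert (counts >= 1).all()
        # disjointness and containment
        all_sets = [set(split.train_pairs), set(split.val_pairs),
                    set(split.test_pairs)]
        assert not (all_sets[0] & all_sets[1] | all_sets[0] & all_sets[2]
                    | all_sets[1] & all_sets[2])

    def test_seed_reproducibility(self, split_net):
        net = split_net
        a = pp.random_split(net, "output_link", seed=11)
        b = pp.random_split(net, "output_link", seed=11)
        assert a.val_pairs == b.val_pairs and a.test_pairs == b.test_pairs
        c = pp.random_split(net, "output_link", seed=12)
        assert c.test_pairs != a.test_pairs

    def test_attribute_split_masks_X_only(self, split_net):
        net = split_net
        split = pp.random_split(net, "attribute", seed=5)
        assert (split.train_network.H != net.H).nnz == 0
        X = split.train_network.X.toarray()
        for (v, f) in split.val_pairs + split.test_pairs:
            assert X[v, f] == 0

    def test_single_member_reactions_make_split_infeasible(self):
        net = pp.build_network(["v1", "v2"], ["e1", "e2"], [],
                               [("v1", "e1", INPUT), ("v2", "e2", INPUT)])
        with pytest.raises(ValueError):
            pp.random_split(net, "input_link", seed=0)

    def test_mask_then_unmask_restores_original(self, split_net):
        net = split_net
        split = pp.random_split(net, "input_link", seed=2)
        restored = pp.add_memberships(split.train_network,
                                      split.val_pairs + split.test_pairs)
        assert (restored.H != net.H).nnz == 0
        assert (restored.H_s != net.H_s).nnz == 0


class TestTemporalSplit:
    def test_identical_versions_give_empty_diff(self, toy):
        diff = pp.temporal_split(toy, toy)
        assert diff.new_pairs == ()
        assert diff.n_removed == 0

    def test_single_added_membership_detected(self, toy):
        v2, e2 = toy.entity_index("v2"), toy.reaction_index("e2")
        new = pp.add_memberships(toy, [(v2, e2, INPUT)])
        diff = pp.temporal_split(toy, new)
        assert diff.new_pairs == (("v2", "e2", INPUT),)

    def test_membership_with_new_entity_counted_not_listed(self, toy):
        ents, rxns, attrs, mems, asns = toy.decompose()
        ents.append(("v4", "entity v4"))
        mems.append(("v4", "e2", INPUT))
        new = pp.build_network(ents, rxns, attrs, mems, asns)
        diff = pp.temporal_split(toy, new)
        assert diff.new_pairs == ()
        assert diff.n_new_entity == 1

    def test_removed_memberships_counted(self, toy):
        v3, e2 = toy.entity_index("v3"), toy.reaction_index("e2")
        older = pp.add_memberships(toy, [(v3, e2, OUTPUT)])
        diff = pp.temporal_split(older, toy)
        assert diff.n_removed == 1


class _OracleRanker:
    """Stub model whose ranking always puts a chosen id first."""

    def __init__(self, network, best_by_query, task="link"):
        self.network = network
        self.best = best_by_query
        self.task = task
        self.direction = "input" if task == "link" else None

    def predict(self, query_id, k=10, network=None):
        net = self.network
        if self.task == "link":
            pool = [r.id for r in net.entities]
            e = net.reaction_index(query_id)
            excluded = {net.entities[v].id
                        for v in net.reaction_members(e, "input")}
        else:
            pool = [r.id for r in net.attributes]
            v = net.entity_index(query_id)
            excluded = {net.attributes[f].id
                        for f in net.entity_attributes(v)}
        rest = [c for c in pool
                if c not in excluded and c != self.best.get(query_id)]
        ranked = ([self.best[query_id]] if query_id in self.best else []) + rest
        scores = np.linspace(1, 0, len(ranked))
        from pathpred.pipelines import RankingResult
        return RankingResult(query_id, tuple(ranked[:k]),
                             tuple(scores[:k]), k, frozenset(excluded))


@pytest.fixture(scope="module")
def eval_net():
    return pp.generate_network(pp.GeneratorConfig(
        n_modules=2, entities_per_module=20, reactions_per_module=15,
        seed=2))


class TestEvaluate:

    def test_perfect_ranker_scores_one_everywhere(self, eval_net):
        net = eval_net
        split = pp.random_split(net, "input_link", seed=0)
        best = {}
        for (v, e, _) in split.test_pairs:
            best[net.reactions[e].id] = net.entities[v].id
        model = _OracleRanker(split.train_network, best)
        res = pp.evaluate(model, split)
        assert res["means"]["NDCG@1"] == 1.0
        assert res["means"]["ACC@1"] == 1.0
        assert res["means"]["ACC@10"] == 1.0

    def test_acc_monotone_in_k(self, eval_net):
        net = eval_net
        split = pp.random_split(net, "input_link", seed=1)
        est = pp.LinkPredictor(model="hgnn", direction="input", epochs=10,
                               embedding_dim=16, random_state=0
                               ).fit(split.train_network)
        res = pp.evaluate(model=est, split=split, ks=(1, 5, 10))
        assert res["means"]["ACC@1"] <= res["means"]["ACC@5"] \
            <= res["means"]["ACC@10"]

    def test_direction_mismatch_rejected(self, eval_net):
        net = eval_net
        split = pp.random_split(net, "output_link", seed=1)
        est = pp.LinkPredictor(model="hgnn", direction="input", epochs=0,
                               embedding_dim=8).fit(split.train_network)
        with pytest.raises(ValueError, match="direction"):
            pp.evaluate(est, split)

    def test_random_scorer_matches_hypergeometric_baseline(self):
        """A uniform-random scorer hits ACC@10 ~ K/pool over many queries."""
        rng = np.random.default_rng(0)
        n_pool, k, n_queries = 120, 10, 500
        hits = 0
        for _ in range(n_queries):
            ranked = [f"v{i}" for i in rng.permutation(n_pool)]
            hits += pp.acc_at_k(ranked, {"v0"}, k)
        p = k / n_pool
        se = math.sqrt(p * (1 - p) / n_queries)
        assert abs(hits / n_queries - p) < 3 * se


class TestCrossValidate:
    def test_report_shape_and_mean_consistency(self):
        net = pp.generate_network(pp.GeneratorConfig(
            n_modules=2, entities_per_module=15, reactions_per_module=10,
            seed=3))
        cfg = pp.TrainConfig(model="hgnn", task="input_link", epochs=5,
                             embedding_dim=8)
        report = pp.cross_validate(net, "input_link", cfg, n_repeats=2,
                                   base_seed=0)
        for name, vals in report.per_repeat.items():
            assert len(vals) == 2
            assert report.mean[name] == pytest.approx(np.mean(vals), abs=1e-12)
            assert report.std[name] >= 0
        assert report.n_repeats == 2

    def test_single_repeat_rejected(self, toy):
        cfg = pp.TrainConfig(model="hgnn", task="input_link", epochs=1)
        with pytest.raises(ValueError, match="n_repeats"):
            pp.cross_validate(toy, "input_link", cfg, n_repeats=1)
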