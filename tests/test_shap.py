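"""Shapley-value correctness: hand games, axioms, a literal double-loop
oracle, sampling convergence, and the masking game on a trained model."""

import itertools
import math

import numpy as np
import pytest

import pathpred as pp
from pathpred.explain import ShapGame, build_players, coalition_value


def oracle_shapley(n, value):
    """Literal double loop over players and subsets with factorial weights."""
    players = list(range(n))
    phi = [0.0] * n
    for i in players:
        others = [j for j in players if j != i]
        for size in range(len(others) + 1):
            for S in itertools.combinations(others, size):
                w = (math.factorial(len(S)) * math.factorial(n - len(S) - 1)
                     / math.factorial(n))
                phi[i] += w * (value(frozenset(S) | {i}) - value(frozenset(S)))
    return phi


class TestShapExact:
    def test_cardinality_game_splits_evenly(self):
        game = ShapGame(["a", "b"], lambda S: float(len(S)))
        res = pp.shap_exact(game)
        assert res.phi == (1.0, 1.0)

    def test_two_player_hand_enumeration(self):
        table = {frozenset(): 0.0, frozenset({0}): 1.0,
                 frozenset({1}): 2.0, frozenset({0, 1}): 3.0}
        res = pp.shap_exact(ShapGame(["a", "b"], table.__getitem__))
        assert res.phi == (1.0, 2.0)

    def test_null_player_gets_zero(self):
        # player 1 never changes the value
        game = ShapGame(["a", "b", "c"],
                        lambda S: 2.0 * (0 in S) + 0.5 * (2 in S))
        res = pp.shap_exact(game)
        assert res.phi[1] == 0.0
        assert res.phi[0] == 2.0 and res.phi[2] == 0.5

    def test_symmetric_players_get_equal_values(self):
        game = ShapGame(list("abcd"),
                        lambda S: float(len({0, 1} & S) >= 1) + 3.0 * (3 in S))
        res = pp.shap_exact(game)
        assert res.phi[0] == pytest.approx(res.phi[1], abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_matches_double_loop_oracle_on_random_games(self, n):
        rng = np.random.default_rng(n)
        table = {frozenset(S): float(rng.normal())
                 for size in range(n + 1)
                 for S in itertools.combinations(range(n), size)}
        res = pp.shap_exact(ShapGame(list(range(n)), table.__getitem__))
        expect = oracle_shapley(n, table.__getitem__)
        assert np.allclose(res.phi, expect, atol=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 8, 10])
    def test_efficiency_on_random_games(self, n):
        rng = np.random.default_rng(100 + n)
        table = {frozenset(S): float(rng.normal())
                 for size in range(n + 1)
                 for S in itertools.combinations(range(n), size)}
        game = ShapGame(list(range(n)), table.__getitem__)
        res = pp.shap_exact(game)
        gap = sum(res.phi) - (game.value(frozenset(range(n)))
                              - game.value(frozenset()))
        assert abs(gap) < 1e-9

    def test_player_cap_refused_with_pointer_to_sampling(self):
        game = ShapGame(list(range(17)), lambda S: float(len(S)))
        with pytest.raises(ValueError, match="shap_sampled"):
            pp.shap_exact(game)


class TestShapSampled:
    def test_small_game_delegates_to_exact(self):
        table = {frozenset(S): float(len(S)) ** 2
                 for size in range(4)
                 for S in itertools.combinations(range(3), size)}
        game = ShapGame(list(range(3)), table.__getitem__)
        res = pp.shap_sampled(game, cap=1024, seed=0)
        assert res.method == "exact"
        assert res.phi == pp.shap_exact(
            ShapGame(list(range(3)), table.__getitem__)).phi

    def test_additive_game_recovered_exactly(self):
        rng = np.random.default_rng(5)
        weights = rng.normal(size=12)
        game = ShapGame(list(range(12)),
                        lambda S: float(sum(weights[i] for i in S)))
        res = pp.shap_sampled(game, cap=200, seed=1)
        assert res.method == "sampled"
        assert np.allclose(res.phi, weights, atol=1e-10)

    def test_same_seed_reproduces_estimates(self):
        rng = np.random.default_rng(9)
        w = rng.normal(size=20)
        mk = lambda: ShapGame(list(range(20)),
                              lambda S: float(sum(w[i] * (1 + 0.1 * len(S))
                                                  for i in S)))
        a = pp.shap_sampled(mk(), cap=300, seed=3)
        b = pp.shap_sampled(mk(), cap=300, seed=3)
        assert a.phi == b.phi
        assert pp.shap_sampled(mk(), cap=300, seed=4).phi != a.phi

    def test_cap_too_small_rejected(self):
        game = ShapGame(list(range(10)), lambda S: float(len(S)))
        with pytest.raises(ValueError, match="cap"):
            pp.shap_sampled(game, cap=5)

    def test_evaluation_budget_respected(self):
        game = ShapGame(list(range(20)), lambda S: float(len(S)) ** 1.5)
        pp.shap_sampled(game, cap=256, seed=0)
        assert game.n_evaluations <= 256

    def test_error_decreases_with_cap_on_8_player_games(self):
        """Mean |sampled - exact| shrinks as the evaluation cap grows."""
        errs = {cap: [] for cap in (64, 256, 1024)}
        for g in range(6):
            rng = np.random.default_rng(g)
            table = {frozenset(S): float(rng.normal())
                     for size in range(9)
                     for S in itertools.combinations(range(8), size)}
            exact = pp.shap_exact(
                ShapGame(list(range(8)), table.__getitem__)).phi
            for cap in errs:
                game = ShapGame(list(range(8)), table.__getitem__)
                # force the sampling path (2^8 = 256 fits small caps)
                n_perms = max(1, (cap - 1) // 8)
                rng2 = np.random.default_rng(g * 7 + cap)
                sums = np.zeros(8)
                est = _permutation_estimate(game, n_perms, rng2)
                errs[cap].append(np.abs(np.array(est) - exact).mean())
        means = {cap: np.mean(v) for cap, v in errs.items()}
        assert means[256] < means[64]
        assert means[1024] < means[256]

    def test_sampled_preserves_efficiency(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=15)
        game = ShapGame(list(range(15)),
                        lambda S: float(sum(w[i] for i in S)) ** 2 / 10)
        res = pp.shap_sampled(game, cap=400, seed=0)
        full = game.value(frozenset(range(15)))
        empty = game.value(frozenset())
        assert sum(res.phi) == pytest.approx(full - empty, abs=1e-9)


def _permutation_estimate(game, n_perms, rng):
    n = game.n_players
    sums = np.zeros(n)
    for _ in range(n_perms):
        perm = rng.permutation(n)
        prev = game.value(frozenset())
        coal = set()
        for i in perm:
            coal.add(int(i))
            cur = game.value(frozenset(coal))
            sums[i] += cur - prev
            prev = cur
    return sums / n_perms


@pytest.fixture(scope="module")
def trained_toy_model():
    net = pp.make_toy()
    est = pp.LinkPredictor(model="hgnn", direction="output", epochs=30,
                           embedding_dim=4, random_state=0).fit(net)
    return net, est


class TestMaskingGame:
    def test_full_coalition_reproduces_model_score(self, trained_toy_model):
        net, est = trained_toy_model
        players = build_players(net, "e2")
        full = frozenset(range(len(players)))
        val = coalition_value(est, net, "e2", "v2", players, full)
        # v2 is not a member of e2, so the readout route with
        # all members present is exactly the model's scoring path
        e = net.reaction_index("e2")
        Z = est.embed(net)
        members = net.reaction_members(e, "output")
        expected = pp.score_links(pp.readout(Z, members), Z)[
            net.entity_index("v2")]
        assert val == pytest.approx(float(expected), abs=1e-12)

    def test_empty_coalition_scores_one_half(self, trained_toy_model):
        net, est = trained_toy_model
        players = build_players(net, "e2")
        assert coalition_value(est, net, "e2", "v2", players,
                               frozenset()) == pytest.approx(0.5, abs=1e-12)

    def test_value_depends_only_on_coalition(self, trained_toy_model):
        net, est = trained_toy_model
        players = build_players(net, "e2")
        S = frozenset({0, 2})
        a = coalition_value(est, net, "e2", "v2", players, S)
        b = coalition_value(est, net, "e2", "v2", players, S)
        assert a == b

    def test_candidate_already_member_rejected(self, trained_toy_model):
        net, est = trained_toy_model
        players = build_players(net, "e2")
        with pytest.raises(ValueError, match="already a member"):
            coalition_value(est, net, "e2", "v3", players, frozenset())

    def test_player_universe_members_plus_their_attributes(self, toy):
        players = build_players(toy, "e1")
        nodes = {p.entity_id for p in players if p.kind == "node"}
        attrs = {(p.entity_id, p.attribute_id) for p in players
                 if p.kind == "attribute"}
        assert nodes == {"v1", "v2", "v3"}
        assert attrs == {("v1", "f1"), ("v3", "f1"), ("v2", "f2")}


class TestExplainPrediction:
    def test_single_member_no_attribute_game(self):
        net = pp.build_network(["v1", "v2"], ["e1"], [],
                               [("v1", "e1", "input")])
        est = pp.LinkPredictor(model="hgnn", direction="input", epochs=10,
                               embedding_dim=4, random_state=0).fit(net)
        res = pp.explain_prediction(est, net, "e1", "v2", seed=0)
        assert len(res.players) == 1
        game = pp.make_game(est, net, "e1", "v2")
        f_full = game.value(frozenset({0}))
        f_empty = game.value(frozenset())
        assert res.phi[0] == pytest.approx(f_full - f_empty, abs=1e-12)
        assert res.ranking[0][0].kind == "node"

    def test_attribute_players_null_when_model_ignores_features(self,
                                                                trained_toy_model):
        net, _ = trained_toy_model
        est = pp.LinkPredictor(model="mf", direction="output", epochs=2,
                               embedding_dim=4, random_state=0).fit(net)
        res = pp.explain_prediction(est, net, "e2", "v2", seed=0)
        # MF's Z is a free factor: masking X cells cannot move the score
        for (player, phi) in res.ranking:
            if player.kind == "attribute":
                assert phi == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_of_full_explanation(self, trained_toy_model):
        net, est = trained_toy_model
        res = pp.explain_prediction(est, net, "e2", "v2", seed=0)
        game = pp.make_game(est, net, "e2", "v2")
        f_full = game.value(frozenset(range(len(res.players))))
        assert sum(res.phi) == pytest.approx(f_full - 0.5, abs=1e-9)

    def test_reaction_without_members_rejected(self, trained_toy_model):
        net, est = trained_toy_model
        with pytest.raises(KeyError):
            pp.explain_prediction(est, net, "missing", "v2")
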