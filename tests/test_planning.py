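"""The MEEA* search loop and its primitive operations."""

import dataclasses
import math
import random

import pytest

from meeastar.heuristics import oracle_estimator, sum_estimator, zero_heuristic
from meeastar.mdp import Reaction, Stock
from meeastar.planning import (
    SearchConfig,
    SearchNode,
    _Tree,
    backup,
    enumerate_routes,
    evaluate_f,
    expand_node,
    extract_route,
    puct_select,
    search,
    select_candidate,
    simulate,
)
from meeastar.policy import TabularPolicy, policy_from_world
from meeastar.worlds import (
    ReactionWorld,
    WorldConfig,
    generate_world,
    optimal_route_oracle,
)


def make_node(state=("x",), g=0.0, parent=None, idx=0):
    return SearchNode(state, parent, None, g, idx)


class TestEvaluateF:
    def test_terminal_has_zero_h(self):
        node = make_node(("b",), g=1.2)
        f = evaluate_f(node, lambda s: 99.0, Stock.from_iterable(["b"]))
        assert node.h == 0.0 and f == pytest.approx(1.2)

    def test_root_f_is_h(self):
        node = make_node(("x",), g=0.0)
        f = evaluate_f(node, lambda s: 3.0, Stock.from_iterable([]))
        assert f == pytest.approx(3.0)

    def test_g_plus_h(self):
        node = make_node(("x",), g=0.7)
        f = evaluate_f(node, lambda s: 1.3, Stock.from_iterable([]))
        assert f == pytest.approx(2.0)

    def test_negative_estimate_clipped(self):
        node = make_node(("x",), g=0.5)
        f = evaluate_f(node, lambda s: -2.0, Stock.from_iterable([]))
        assert node.h == 0.0 and f == pytest.approx(0.5)


class TestPuctSelect:
    def _parent_with_children(self, qs, ns, gs=None, fs=None):
        parent = make_node(("p",))
        parent.status = "expanded"
        for i, (q, n) in enumerate(zip(qs, ns)):
            child = make_node((f"c{i}",), g=(gs[i] if gs else 0.0),
                              parent=parent, idx=i + 1)
            child.stats.Q = q
            child.stats.N = n
            if fs:
                child.f = fs[i]
            parent.children.append(child)
        return parent

    def test_hand_computed_scores(self):
        # Q=(1,3), N=(1,0), c_puct=4, |A|=2, sqrt(sum N)=1:
        # scores: -1 + 4*(1/2)*1/2 = 0.0 ; -3 + 4*(1/2)*1/1 = -1.0
        parent = self._parent_with_children(qs=[1.0, 3.0], ns=[1, 0])
        assert puct_select(parent, 4.0).state == ("c0",)

    def test_unvisited_edges_reduce_to_greedy_on_f(self):
        # all N=0 -> exploration term 0 -> child with smaller Q (= its f)
        parent = self._parent_with_children(qs=[2.0, 5.0], ns=[0, 0])
        assert puct_select(parent, 4.0).state == ("c0",)

    def test_single_child(self):
        parent = self._parent_with_children(qs=[7.0], ns=[3])
        assert puct_select(parent, 4.0).state == ("c0",)

    def test_no_live_children_rejected(self):
        parent = make_node(("p",))
        parent.status = "expanded"
        with pytest.raises(ValueError):
            puct_select(parent, 4.0)

    def test_tie_breaks_toward_larger_g(self):
        parent = self._parent_with_children(qs=[1.0, 1.0], ns=[0, 0],
                                            gs=[0.5, 1.5])
        assert puct_select(parent, 4.0).g == 1.5


class TestBackup:
    def test_first_backup_sets_q(self):
        root, leaf = make_node(("r",)), make_node(("l",), idx=1)
        leaf.parent = root
        backup([root, leaf], 4.2)
        assert leaf.stats.Q == pytest.approx(4.2) and leaf.stats.N == 1

    def test_running_mean(self):
        root, leaf = make_node(("r",)), make_node(("l",), idx=1)
        leaf.stats.N, leaf.stats.Q = 3, 2.0
        backup([root, leaf], 6.0)
        assert leaf.stats.Q == pytest.approx(3.0) and leaf.stats.N == 4

    def test_mean_fixed_point(self):
        root, leaf = make_node(("r",)), make_node(("l",), idx=1)
        leaf.stats.N, leaf.stats.Q = 5, 1.7
        backup([root, leaf], 1.7)
        assert leaf.stats.Q == pytest.approx(1.7) and leaf.stats.N == 6

    def test_q_is_arithmetic_mean_of_logged_values(self):
        """Property: after an arbitrary backup schedule, Q on each edge is
        exactly the mean of values logged through it and N their count."""
        rng = random.Random(0)
        root = make_node(("r",))
        nodes = [root]
        logs = {}
        for i in range(1, 8):
            parent = rng.choice(nodes)
            child = make_node((f"n{i}",), parent=parent, idx=i)
            parent.children.append(child)
            nodes.append(child)
            logs[child] = []
        for _ in range(200):
            leaf = rng.choice(nodes[1:])
            path = []
            n = leaf
            while n is not None:
                path.append(n)
                n = n.parent
            path.reverse()
            v = rng.uniform(-5, 5)
            backup(path, v)
            for node in path[1:]:
                logs[node].append(v)
        for node, vals in logs.items():
            assert node.stats.N == len(vals)
            if vals:
                assert node.stats.Q == pytest.approx(
                    sum(vals) / len(vals), abs=1e-12)


class TestSelectCandidate:
    def test_minimum_f(self):
        nodes = [make_node((f"n{i}",), idx=i) for i in range(3)]
        for node, f in zip(nodes, (3.0, 2.0, 5.0)):
            node.f = f
        assert select_candidate(set(nodes)).f == 2.0

    def test_f_tie_prefers_larger_g(self):
        a, b = make_node(("a",), g=1.0, idx=0), make_node(("b",), g=2.5, idx=1)
        a.f = b.f = 4.0
        assert select_candidate({a, b}) is b

    def test_empty_set_is_failure(self):
        with pytest.raises(ValueError):
            select_candidate(set())


class TestExpandNode:
    def _tree(self, world, estimator=None, **cfg):
        policy = policy_from_world(world)
        config = SearchConfig(**cfg)
        est = estimator or zero_heuristic
        return _Tree((world.targets[0],), world.stock, policy, est, config)

    def test_immediate_terminal_child(self, chain_world):
        tree = self._tree(chain_world)
        tree.root.state = ("M1",)
        terms = expand_node(tree, tree.root)
        assert len(terms) == 1 and terms[0].state == ("B1", "B2")

    def test_dead_end_marks_status(self):
        world = ReactionWorld(
            stock=Stock.from_iterable(["s"]),
            reactions=(Reaction(product="a", reactants=("dead",),
                                template_id="t"),),
            targets=("a",),
        )
        tree = self._tree(world)
        expand_node(tree, tree.root)
        dead_child = tree.root.children[0]
        assert expand_node(tree, dead_child) == []
        assert dead_child.status == "dead_end"
        assert not tree.root.live  # deadness propagates to the root

    def test_truncation_to_k_expansion(self, diamond_world):
        tree = self._tree(diamond_world, k_expansion=1)
        expand_node(tree, tree.root)
        assert len(tree.root.children) == 1
        assert tree.root.children[0].reaction.template_id == "Tcheap"

    def test_double_expansion_rejected(self, diamond_world):
        tree = self._tree(diamond_world)
        expand_node(tree, tree.root)
        with pytest.raises(ValueError):
            expand_node(tree, tree.root)

    def test_g_accumulates_edge_costs(self, chain_world):
        tree = self._tree(chain_world)
        expand_node(tree, tree.root)
        child = tree.root.children[0]
        assert child.g == pytest.approx(-math.log(0.25))

    def test_edge_stats_initialized_to_child_f(self, diamond_world):
        tree = self._tree(diamond_world, estimator=oracle_estimator(diamond_world))
        expand_node(tree, tree.root)
        for child in tree.root.children:
            assert child.stats.N == 0
            assert child.stats.Q == pytest.approx(child.f)


class TestSimulate:
    def test_root_only_tree_returns_root(self, diamond_world):
        policy = policy_from_world(diamond_world)
        tree = _Tree(("M1",), diamond_world.stock, policy, zero_heuristic,
                     SearchConfig())
        cands = set()
        leaf = simulate(tree.root, 4.0, cands)
        assert leaf is tree.root and cands == {tree.root}

    def test_first_simulation_reaches_lowest_f_child(self, diamond_world):
        est = oracle_estimator(diamond_world)
        policy = policy_from_world(diamond_world)
        tree = _Tree(("M1",), diamond_world.stock, policy, est, SearchConfig())
        expand_node(tree, tree.root)
        cands = set()
        leaf = simulate(tree.root, 4.0, cands)
        assert leaf.state == ("M2",)  # cheap branch child
        assert tree.root.children[0].stats.N + tree.root.children[1].stats.N == 1

    def test_candidate_set_bounded_by_leaves(self, diamond_world):
        policy = policy_from_world(diamond_world)
        tree = _Tree(("M1",), diamond_world.stock, policy, zero_heuristic,
                     SearchConfig())
        expand_node(tree, tree.root)
        cands = set()
        for _ in range(50):
            simulate(tree.root, 4.0, cands)
        assert len(cands) <= 2  # only two live leaves exist


class TestSearch:
    def test_target_in_stock(self, chain_world):
        policy = policy_from_world(chain_world)
        r = search("B1", chain_world.stock, policy, zero_heuristic)
        assert r.success and r.route.length == 0 and r.model_calls == 0

    def test_zero_budget_fails(self, chain_world):
        policy = policy_from_world(chain_world)
        cfg = SearchConfig(max_model_calls=0)
        r = search("M3", chain_world.stock, policy, zero_heuristic, cfg)
        assert not r.success and r.model_calls == 0

    @pytest.mark.parametrize("mode", ["meea", "astar", "mcts"])
    def test_route_cost_consistency(self, chain_world, mode):
        policy = policy_from_world(chain_world)
        r = search("M3", chain_world.stock, policy, zero_heuristic,
                   SearchConfig(mode=mode))
        assert r.success
        r.route.validate(stock=chain_world.stock)
        resummed = sum(-math.log(s.reaction.feasibility)
                       for s in r.route.steps)
        assert r.route.cost == pytest.approx(resummed)

    def test_certified_search_matches_oracle_on_random_worlds(self):
        for seed in range(6):
            world = generate_world(WorldConfig(n_stock=5, n_intermediates=9,
                                               decoy_rate=0.3, seed=seed))
            policy = policy_from_world(world)
            est = oracle_estimator(world)
            for target in world.targets:
                want = optimal_route_oracle(world, target).optimal_cost
                for mode in ("astar", "meea"):
                    cfg = SearchConfig(mode=mode, max_model_calls=5000,
                                       stop_on_first_goal=False)
                    r = search(target, world.stock, policy, est, cfg)
                    assert r.success and r.certified
                    assert r.route.cost == pytest.approx(want, abs=1e-9)

    def test_mcts_mode_forces_single_simulation(self):
        cfg = SearchConfig(mode="mcts", k_mcts=77)
        assert cfg.k_mcts == 1

    def test_cycle_control_terminates_on_looping_policy(self):
        """A policy with a 2-cycle of zero-cost reactions must not loop:
        successors equal to an ancestor state are pruned."""
        rxns = {
            "a": [Reaction(product="a", reactants=("b",), template_id="t1",
                           feasibility=1.0)],
            "b": [Reaction(product="b", reactants=("a",), template_id="t2",
                           feasibility=1.0)],
        }
        policy = TabularPolicy(rxns)
        stock = Stock.from_iterable(["z"])
        r = search("a", stock, policy, zero_heuristic,
                   SearchConfig(max_model_calls=50))
        assert not r.success and r.exhausted

    def test_monotone_budget(self):
        """Targets solved at budget B stay solved at any larger budget."""
        world = generate_world(WorldConfig(n_stock=5, n_intermediates=10,
                                           decoy_rate=0.4, seed=17))
        policy = policy_from_world(world)
        for target in world.targets:
            solved_small = [
                search(target, world.stock, policy, zero_heuristic,
                       SearchConfig(max_model_calls=b)).success
                for b in (2, 5, 20, 200)
            ]
            # once True, stays True
            assert solved_small == sorted(solved_small)

    def test_max_depth_limits_routes(self, chain_world):
        policy = policy_from_world(chain_world)
        r = search("M3", chain_world.stock, policy, zero_heuristic,
                   SearchConfig(max_depth=2, max_model_calls=100))
        assert not r.success  # M3 needs 3 reactions

    def test_f_and_g_consistency_across_tree(self, diamond_world):
        """f = g + h on every node and g increments by the edge cost."""
        policy = policy_from_world(diamond_world)
        est = oracle_estimator(diamond_world)
        tree = _Tree(("M1",), diamond_world.stock, policy, est, SearchConfig())
        expand_node(tree, tree.root)
        for child in tree.root.children:
            expand_node(tree, child)
        stack = [tree.root]
        while stack:
            n = stack.pop()
            assert n.f == pytest.approx(n.g + n.h)
            for c in n.children:
                assert c.g - n.g == pytest.approx(c.reaction.cost)
                stack.append(c)


class TestExtractAndEnumerate:
    def test_extract_requires_terminal(self, diamond_world):
        node = make_node(("M1",))
        with pytest.raises(ValueError):
            extract_route(node, "M1")

    def test_depth_one_route(self, chain_world):
        policy = policy_from_world(chain_world)
        r = search("M1", chain_world.stock, policy, zero_heuristic)
        assert r.success and r.route.length == 1
        assert r.route.cost == pytest.approx(-math.log(0.5))

    def test_two_level_route_leaves_are_stock(self, chain_world):
        policy = policy_from_world(chain_world)
        r = search("M2", chain_world.stock, policy, zero_heuristic)
        assert r.success and r.route.length == 2
        assert r.route.leaves <= chain_world.stock.members

    def test_enumerate_finds_exactly_both_diamond_routes(self, diamond_world):
        policy = policy_from_world(diamond_world)
        routes = enumerate_routes("M1", diamond_world.stock, policy,
                                  zero_heuristic,
                                  SearchConfig(max_model_calls=500),
                                  max_routes=25)
        assert len(routes) == 2
        costs = sorted(r.cost for r in routes)
        assert costs == [pytest.approx(0.9), pytest.approx(1.4)]

    def test_enumerate_one_equals_search(self, diamond_world):
        policy = policy_from_world(diamond_world)
        only = enumerate_routes("M1", diamond_world.stock, policy,
                                zero_heuristic, SearchConfig(), max_routes=1)
        single = search("M1", diamond_world.stock, policy, zero_heuristic)
        assert len(only) == 1
        assert only[0].signature() == single.route.signature()

    def test_unreachable_target_gives_empty(self):
        world = ReactionWorld(
            stock=Stock.from_iterable(["s"]),
            reactions=(Reaction(product="a", reactants=("dead",),
                                template_id="t"),),
            targets=("a",),
        )
        policy = policy_from_world(world)
        routes = enumerate_routes("a", world.stock, policy, zero_heuristic,
                                  SearchConfig(max_model_calls=100),
                                  max_routes=5)
        assert routes == []

    def test_oracle_cost_lower_bounds_every_mode(self):
        """Global sanity: no search mode ever beats the brute-force oracle."""
        for seed in (3, 4):
            world = generate_world(WorldConfig(seed=seed, decoy_rate=0.3))
            policy = policy_from_world(world)
            for target in world.targets:
                opt = optimal_route_oracle(world, target).optimal_cost
                for mode in ("meea", "astar", "mcts"):
                    r = search(target, world.stock, policy, zero_heuristic,
                               SearchConfig(mode=mode, max_model_calls=2000))
                    if r.success:
                        assert r.route.cost >= opt - 1e-9
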