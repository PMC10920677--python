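# meeastar

Retrosynthetic planning searches backwards from a target molecule through
candidate reactions until every remaining molecule is a purchasable
building block. Two search families dominate the field: best-first (A*)
search, which is optimal but can sink its whole budget into a branch a
misleading cost estimator makes look cheap, and Monte Carlo tree search
(MCTS), whose compulsive exploration struggles to reach deep solutions.
`meeastar` implements **MEEA\*** — A\* selection augmented with MCTS-style
lookahead — together with the surrounding machinery a planning researcher
needs: the planning MDP, pluggable expansion policies and cost
estimators, path-consistency-regularized estimator training, synthetic
reaction worlds with exact brute-force oracles, and route
quality/diversity metrics.

## The algorithm

A state `s` is the sorted set of molecules still required for the target.
Each node carries

```
f(s) = g(s) + h(s)
```

where `g` is the accumulated reaction cost from the root (each reaction
costs `-ln p_r`, its negative log feasibility) and `h` estimates the
remaining cost to a state made of building blocks only. One MEEA*
iteration runs three phases:

1. **Simulation** — `K_MCTS` descents from the root (default 100),
   steered by a uniform-prior pUCT rule over edge statistics,

   `a* = argmax_a { -Q(s,a) + c_puct · (1/|A|) · sqrt(Σ_b N(s,b)) / (1 + N(s,a)) }`,

   with `c_puct = 4.0`. Each descent stops at an unexpanded leaf, whose
   `f` is backed up along the path as a running mean
   `Q ← (N·Q + f_leaf)/(N+1), N ← N+1`. No nodes are expanded and no
   single-step model is called — lookahead is cheap.
2. **Selection** — the minimum-`f` leaf among those the simulations
   reached (the *candidate set*) is chosen.
3. **Expansion** — the single-step policy proposes up to 50 reactions for
   the candidate's first non-building-block molecule; successor states
   join the tree. This is the only phase that calls the policy model.

Setting `K_MCTS = 1` degenerates to pure MCTS; `mode="astar"` bypasses
simulation and selects the global minimum-`f` open leaf (classic A*).
Branch averages backed up by the simulations let MEEA* abandon a branch
whose *average* looks bad even when its frontier still looks attractive —
the failure mode that traps plain best-first search.

The estimator-training module fits a whole-state cost network (summed
molecule embeddings with a linear readout) to solved routes with

```
L = (h(s) - c(s))² + λ · (f(s) - f̄)²,    λ = 5.5,
```

where `c(s)` is the route's true remaining cost and `f̄` the mean `f`
along the route: *path consistency* — on an optimal path all `f` values
coincide — used as a regularizer.

## Worked example

```python
from meeastar import (WorldConfig, generate_world, policy_from_world,
                      oracle_estimator, SearchConfig, search,
                      optimal_route_oracle)

world = generate_world(WorldConfig(n_stock=6, n_intermediates=10,
                                   decoy_rate=0.3, seed=7))
target = world.targets[0]
policy = policy_from_world(world)
est = oracle_estimator(world)
result = search(target, world.stock, policy, est,
                SearchConfig(mode="meea", stop_on_first_goal=False,
                             max_model_calls=10_000))
oracle = optimal_route_oracle(world, target)
```

prints, via the obvious formatting:

```
target M0007: solved=True certified=True
route length 10, cost 10.1472 (oracle optimum 10.1472)
expansions 10, model calls 10
  M0007 -> M0002 + M0005 + M0006   (template T0010, -ln p = 0.457)
  M0002 -> B0001 + B0003 + M0001   (template T0002, -ln p = 0.907)
  ...
```

The route cost (sum of `-ln p_r` over its ten reactions) exactly matches
the brute-force oracle's optimum, and `certified=True` says the search
proved it: the banked goal's cost is no worse than the optimistic `f` of
every remaining open leaf. With `stop_on_first_goal=True` (the default)
the search instead stops at the first terminal state it generates —
faster, and the behavior used for the expansion-count comparisons.

The same workflow runs from a shell:

```
meeastar make-world --seed 5 --out world.json
meeastar plan --target M0010 --stock stock.txt --policy policy.json --mode meea
meeastar benchmark --world world.json --mode meea --out summary.json
meeastar metrics route1.json route2.json --reference ref.json
```

## Layout

| module | contents |
| --- | --- |
| `meeastar.mdp` | molecules, states, stocks, reactions, transitions, costs |
| `meeastar.policy` | tabular and classifier single-step expansion policies |
| `meeastar.heuristics` | zero / per-molecule-sum / joint-network / oracle estimators |
| `meeastar.planning` | the MEEA* loop, pUCT lookahead, A* and MCTS limiting modes |
| `meeastar.training` | route supervision, PC-regularized training, route corpora |
| `meeastar.worlds` | synthetic DAG reaction worlds, brute-force oracles, adversarial fixtures |
| `meeastar.evaluation` | route trees, tree edit distance, clustering, benchmark summaries |
| `meeastar.cli` | `meeastar plan / make-world / benchmark / metrics` |

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
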