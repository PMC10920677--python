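# Methods

## The planning MDP

A state is the sorted, duplicate-free tuple of molecules still required
to synthesize the target; the initial state is `{target}` and a state is
terminal when all its molecules belong to the building-block stock (the
empty state is terminal by convention, though unreachable since reactions
have non-empty reactant sets). An action is a retro-reaction decomposing
one molecule into its reactants; actions always apply to the
lexicographically first non-stock molecule of the state, which fixes a
canonical processing order without affecting reachability. The transition
replaces the product with its reactants and re-canonicalizes; duplicates
introduced by a transition collapse to one copy (set semantics — this
matters: a molecule can be decomposed, reappear later as a reactant, and
be decomposed again, and shared intermediates that coexist in a state are
synthesized once). The cost of a reaction is `-ln p_r`, the negative
natural log of its feasibility probability; natural base is a pure
rescaling and cannot change which route is cheapest. Costs are therefore
non-negative, zero exactly at feasibility 1.

Molecule identifiers are opaque canonical strings. Synthetic worlds use
tokens (`M0007`); when the optional RDKit backend is attached,
identifiers are canonical SMILES and featurization can use Morgan
fingerprints (radius 2, 2048 bits by default). Everything else in the
package is agnostic to the backend.

## MEEA* search

Each iteration: (1) `k_mcts` simulations descend from the root by the
uniform-prior pUCT rule, stop at an unexpanded leaf, and back the leaf's
`f = g + h` up the traversed edges as a running mean; the visited leaves
form the candidate set; (2) the minimum-`f` candidate is selected; (3) it
is expanded through the single-step policy (top-`k_expansion` proposals).
Only expansion calls the policy model, so the model-call budget counts
expansions. The candidate set is rebuilt from fresh simulations each
iteration, while edge statistics and cached leaf `f` values persist —
persistence is what makes the lookahead informative.

Parameter defaults: `k_mcts = 100`, `c_puct = 4.0`, `k_expansion = 50`,
budget 500 model calls or 600 s. `mode="mcts"` forces `k_mcts = 1`
(candidate set is a single leaf — pure MCTS); `mode="astar"` skips
simulation and selects the minimum-`f` node over all open leaves
directly, rather than approximating it with a very large `k_mcts`.

Design choices where the design was genuinely open:

- **Q initialization.** A never-backed-up edge carries `Q = f(child)`,
  so before any visits pUCT reduces to greedy-on-`f` and the first
  simulation of a fresh subtree walks the best-first path.
- **Tie-breaks.** Both pUCT and candidate selection break ties toward
  larger `g` (deeper, closer to a goal), then earlier creation order.
  Determinism here is what makes search traces reproducible and the
  limiting-mode equivalence tests exact.
- **Cycle control.** A successor equal to any ancestor state on its path
  is discarded at expansion; without this, zero-cost loops recur forever.
  No transposition table: identical states reached by different paths are
  distinct nodes (pure tree search).
- **Dead ends.** A node whose expansion yields no children becomes a dead
  end; exhaustion propagates upward and simulations restrict the pUCT
  action set to live children.
- **Estimates.** Negative estimator outputs are clipped to 0 (costs are
  non-negative); an unsolvable-state oracle estimate is `inf`, which
  propagates correctly through the running means.

**Termination.** Terminal children are detected at creation. By default
(`stop_on_first_goal=True`) the search succeeds immediately — the
behavior that matches expansion-count accounting and first-solution
timing. This cannot guarantee optimality: an on-optimal-path node may own
a direct-to-stock reaction that is far more expensive than its best
continuation, and generation-time success would accept it. With
`stop_on_first_goal=False` goals are banked instead, and the search
terminates once the cheapest banked goal costs no more than the minimum
`f` over open leaves — exact whenever `h` never overestimates (the
oracle and zero heuristics), since every open leaf's `f` then lower-bounds
any solution through it. The optimality tests run this certified mode;
route enumeration reuses the goal bank, collecting distinct routes in
discovery order without expanding goal nodes.

## Cost estimators

- `zero_heuristic`: `h = 0`; trivially consistent.
- `SumEstimator`: `h(s) = Σ_m h(m)` from a per-molecule table or callable
  (stock members default to 0).
- `JointEstimator`: each molecule is featurized (hashed token features,
  width 64, for synthetic worlds; any featurizer can be plugged in),
  passed through one dense ReLU layer into a 128-dimensional embedding by
  default; embeddings are summed into a state embedding and a linear head
  reads out a scalar. Sum pooling makes the output invariant to molecule
  order and lets one network handle arbitrary state sizes. The head is
  zero-initialized (a fresh estimator predicts 0 everywhere); prediction
  clips at 0, training uses the raw head.
- `oracle_estimator`: exact minimal remaining cost of a finite world,
  memoized uniform-cost search per queried state; consistent by
  construction (it satisfies the Bellman equation of the same transition
  system), used to instrument optimality tests.

The estimators are plain numpy with a hand-written Adam optimizer; the
models are small enough that a deep-learning framework would add nothing
but weight.

## Path-consistency training

Solved routes become supervision: at step `t`, `g(s_t)` is the prefix sum
of reaction costs and the label `c(s_t)` the suffix sum (0 at the
terminal state). The loss per state is

    L = (h(s) - c(s))² + λ (f(s) - f̄)²,  f̄ = mean of f over the state's route,

with `λ = 5.5`, Adam at learning rate 0.001, batches of at least 256
states assembled from whole routes (`f̄` is a per-route quantity, so
route groups are never split). `f` is recomputed from the current network
every epoch. `f̄` is treated as a detached target; this is not actually a
choice with this definition of `f̄` — because the per-route residuals
`f - f̄` sum to zero, the gradient contribution through the mean
vanishes identically and both variants coincide.

The training corpus generator draws small DAG worlds (6 building blocks,
10 intermediates, depth 2-4, 20% decoy branches) and collects up to four
distinct routes per target (300 routes by default). Each world's
molecules are namespaced so that identically named tokens from different
worlds remain distinct molecules. Keeping several routes per target is
deliberate: the same state then appears with different remaining-cost
labels (route-dependent suffix costs), exactly the label noise against
which path consistency regularizes — the unregularized fit memorizes the
noise, the PC fit resists it, trading a little training error for a
smaller validation-minus-train gap. The gap comparison uses 200 epochs, a
32-feature/64-embedding estimator, and a 70/30 route-level split.

## Synthetic worlds and oracles

Worlds are layered DAGs: intermediates sit on 1..depth layers, every
reaction's reactants come from strictly lower layers with at least one
from the layer immediately below, so depth is real. Feasibilities are
uniform on [0.2, 1.0] (keeping `-ln p` away from degenerate near-zero
probabilities); priors uniform on [0.1, 1.0], normalized per product by
the tabular policy. A decoy branch (probability `decoy_rate` per
intermediate) adds an attractive-looking reaction into a dead-end
molecule; decoys are never a product's only reaction, so every target
stays solvable by construction. Worlds are DAG-structured precisely so
the brute-force oracle is exact and finite; cyclic chemistry is excluded
from the testbed, while cycle control in the search is exercised
separately with looping tabular policies.

The oracle runs uniform-cost search over the same set-of-molecules state
space and first-open-molecule convention the planners use (per-molecule
dynamic programming would be wrong here: set-collapse lets states share
intermediates, so a state's optimum can be below the sum of per-molecule
optima). It returns the exact cheapest cost/route, the exact shortest
length under unit costs, and optionally the number of distinct routes up
to a depth bound; a hard cap of 2×10^5 distinct states guards against
misconfigured worlds.

Two hand-shaped adversarial fixtures realize the classic failure modes:

- **deep**: a binary tree of molecules whose biased per-molecule
  estimates (~0.25) sit far below truth, all dead-ending 5-6 levels down,
  with moderately-bad poison siblings (~2.5-3.5) at every level; the true
  3-step branch looks honestly mediocre (~0.74). A best-first search must
  clear the entire sub-threshold region node by node (~30-60 expansions);
  MEEA*'s simulations mix the poison values into the branch averages
  within a few iterations and the root edge shuts off.
- **wide**: five bushy mediocre branches (estimates ~1.4-2.4) around one
  deep 6-step true chain with exact estimates; pure MCTS's exploration
  quota sprays expansions across the width while min-f candidate
  selection walks straight down the chain.

The fixture shapes (branching 2+2, depth 5-6, poison band 2.5-3.5, and
the wide fixture's 5×3×3 bush) were chosen so that the sub-threshold
region is large for best-first search while branch averages separate
within a few lookahead batches at the default `c_puct`; they are fixed
constructions, jittered per seed, not tuned quantities.

## Route metrics

Routes are compared as ordered labeled trees built by replaying the
route: molecule nodes alternate with reaction nodes; when set-collapse
merged copies of a molecule, its decomposition subtree is duplicated to
every parent (standard route-tree semantics); children sort by molecule
identifier so the metric ignores serialization order. Tree edit distance
is the exact Zhang–Shasha dynamic program with unit
insert/delete/relabel costs (configurable); the unit-cost choice and the
complete-linkage clustering threshold (default 2.0) are documented
conventions, not literature values. Leaves overlap is
`|leaves(generated) ∩ leaves(reference)| / |leaves(reference)|`.
Benchmark summaries report success rate, penalized averages (failures
charged a configurable penalty; no canonical default exists, 32/64 are
placeholders) and zero-filled minimum averages, plus first-solution-time
statistics.

## What the synthetic testbed does and does not show

The worlds emulate the combinatorial structure of retrosynthesis —
branching reaction choices, shared intermediates, dead ends, deceptive
cost landscapes — at a scale where exact ground truth is computable.
They do not emulate chemistry: no templates are chemically meaningful,
molecule features are hashes rather than substructures, and feasibility
distributions are stylized. Passing tests therefore demonstrate
algorithmic properties (optimality under consistent heuristics,
correctness of the statistics, direction of the exploration trade-offs,
the regularization mechanism), not chemical performance; plugging in a
real single-step model and stock through the classifier-policy contract
is how the same machinery would face real chemistry. Problem sizes in
tests and the acceptance script (≈100-world batches, 25-50 fixture
seeds, 300-route corpora) were chosen as the smallest at which these
properties are stably exercised.

## Known limitations

- Pure tree search: no transposition sharing or AND-OR decomposition, so
  repeated sub-states cost repeated work.
- The certified termination bound is only exact for non-overestimating
  heuristics; with a learned estimator it is a heuristic stopping rule.
- The classifier policy's training loop targets toy template sets;
  corpus-scale template mining and training are out of scope.
- The joint estimator is a set encoder over per-molecule features;
  graph-structured molecule encoders are not provided.
- At 300-route corpus scale the per-split sign of the PC generalization
  comparison is noisy: the paired gap difference between λ = 5.5 and
  λ = 0 is small relative to split-to-split variance, so individual
  70/30 splits frequently disagree with the mean direction. The mean gap
  over several splits (what `scripts/acceptance.py` reports) is the more
  stable summary of the regularization effect at this scale.
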