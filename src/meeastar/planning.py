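"""MEEA*: best-first retrosynthetic search with MCTS lookahead.

Each iteration runs three phases:

1. **Simulation** — ``k_mcts`` pUCT-guided descents from the root, *without
   expanding any node*. Each descent ends at an unexpanded leaf, whose
   f = g + h value is backed up as a running mean along the traversed
   edges; the leaves reached form the iteration's *candidate set*.
2. **Selection** — the candidate with the smallest f value is chosen.
3. **Expansion** — the single-step policy proposes up to ``k_expansion``
   reactions for the candidate's first non-stock molecule; the resulting
   successor states are added to the tree. Only this phase calls the
   single-step model, so simulation is cheap lookahead.

Two limiting modes are built in: ``mode="mcts"`` forces ``k_mcts = 1``
(the candidate set is the single simulated leaf — pure MCTS), and
``mode="astar"`` bypasses simulation entirely and expands the minimum-f
node over *all* open leaves (classic A*).

Termination: by default the search succeeds as soon as an expansion
creates a terminal child (every molecule in stock). With
``stop_on_first_goal=False`` terminal children are instead banked as goals
and the search continues until the cheapest banked goal provably beats
every open leaf (its cost is <= the minimum open f), which certifies
optimality whenever the heuristic never overestimates.
"""

from __future__ import annotations

import heapq
import logging
import math
import time
from dataclasses import dataclass, field
from typing import Optional

from .heuristics import Estimator
from .mdp import (
    Molecule,
    State,
    Stock,
    canonicalize_state,
    is_terminal,
)
from .policy import ExpansionPolicy, successors
from .routes import Route, RouteStep

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeStats",
    "SearchNode",
    "SearchConfig",
    "SearchResult",
    "TraceRecord",
    "evaluate_f",
    "puct_select",
    "backup",
    "simulate",
    "select_candidate",
    "expand_node",
    "search",
    "extract_route",
    "enumerate_routes",
]

UNEXPANDED = "unexpanded"
EXPANDED = "expanded"
TERMINAL = "terminal"
DEAD_END = "dead_end"


@dataclass
class EdgeStats:
    """Visit count and running-mean backed-up value of a tree edge."""

    N: int = 0
    Q: float = 0.0


class SearchNode:
    """One node of the (pure tree-structured) search tree.

    Identical states reached along different paths are distinct nodes; no
    transposition merging. ``stats`` are the statistics of the edge from
    the parent into this node (root carries unused stats). ``live`` is
    False once the subtree can no longer yield an unexpanded leaf (dead
    ends and banked goals), and propagates upward.
    """

    __slots__ = ("state", "parent", "reaction", "g", "h", "f", "status",
                 "children", "stats", "creation_index", "depth", "live")

    def __init__(self, state: State, parent: Optional["SearchNode"],
                 reaction, g: float, creation_index: int):
        self.state = state
        self.parent = parent
        self.reaction = reaction
        self.g = g
        self.h = 0.0
        self.f = g
        self.status = UNEXPANDED
        self.children: list[SearchNode] = []
        self.stats = EdgeStats()
        self.creation_index = creation_index
        self.depth = 0 if parent is None else parent.depth + 1
        self.live = True

    def __repr__(self) -> str:  # debugging aid
        return (f"SearchNode({self.state!r}, status={self.status}, "
                f"g={self.g:.4g}, f={self.f:.4g}, N={self.stats.N})")


@dataclass
class SearchConfig:
    """Search hyperparameters.

    Defaults follow the standard MEEA* setting: ``k_mcts=100`` lookahead
    simulations per iteration with ``c_puct=4.0``, top-50 expansion, and a
    budget of 500 single-step model calls or 10 minutes. ``mode="mcts"``
    forces ``k_mcts=1``; ``mode="astar"`` skips simulation and selects the
    minimum-f node over all open leaves."""

    k_mcts: int = 100
    c_puct: float = 4.0
    k_expansion: int = 50
    max_model_calls: int = 500
    max_wall_seconds: float = 600.0
    max_depth: Optional[int] = None
    mode: str = "meea"
    seed: int = 0
    stop_on_first_goal: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("meea", "astar", "mcts"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k_mcts < 1:
            raise ValueError("k_mcts must be >= 1")
        if self.k_expansion < 1:
            raise ValueError("k_expansion must be >= 1")
        if self.mode == "mcts":
            self.k_mcts = 1


@dataclass(frozen=True)
class TraceRecord:
    """Per-iteration log line: which node was expanded and why."""

    iteration: int
    state: State
    g: float
    h: float
    f: float
    candidate_size: int
    model_calls: int

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "state": list(self.state),
            "g": self.g, "h": self.h, "f": self.f,
            "candidate_size": self.candidate_size,
            "model_calls": self.model_calls,
        }


@dataclass
class SearchResult:
    success: bool
    route: Optional[Route]
    expansions: int
    model_calls: int
    wall_time: float
    nodes_created: int
    iterations: int
    trace: list[TraceRecord]
    first_solution_time: Optional[float] = None
    certified: bool = False
    exhausted: bool = False


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


def evaluate_f(node: SearchNode, estimator: Estimator,
               stock: Stock) -> float:
    """Set node.h from the estimator (0 at terminal states) and node.f = g + h.

    Negative estimates are clipped to 0 (costs are non-negative) and
    logged at debug level."""
    if node.status == TERMINAL or is_terminal(node.state, stock):
        node.h = 0.0
    else:
        h = estimator(node.state)
        if h < 0.0:
            logger.debug("estimator returned %g for %r; clipping to 0",
                         h, node.state)
            h = 0.0
        node.h = h
    node.f = node.g + node.h
    return node.f


def puct_select(node: SearchNode, c_puct: float) -> SearchNode:
    """Select a child by the uniform-prior pUCT rule.

    score(a) = -Q(s,a) + c_puct * (1/|A|) * sqrt(sum_b N(s,b)) / (1 + N(s,a)),
    with the action set A restricted to live children. Ties break toward
    larger g (deeper), then earlier creation."""
    live = [c for c in node.children if c.live]
    if not live:
        raise ValueError("puct_select on a node with no live children")
    n_actions = len(live)
    total_n = sum(c.stats.N for c in live)
    sqrt_total = math.sqrt(total_n)

    def key(c: SearchNode):
        score = -c.stats.Q + c_puct * (1.0 / n_actions) * sqrt_total / (1 + c.stats.N)
        return (score, c.g, -c.creation_index)

    return max(live, key=key)


def backup(path: list[SearchNode], f_leaf: float) -> None:
    """Fold ``f_leaf`` into the running mean Q of every edge on the path.

    ``path`` is the root-to-leaf node sequence; the root's (nonexistent)
    incoming edge is skipped."""
    for node in path[1:]:
        st = node.stats
        if st.N == 0:
            st.Q = f_leaf
        else:
            st.Q = (st.N * st.Q + f_leaf) / (st.N + 1)
        st.N += 1


def simulate(root: SearchNode, c_puct: float,
             candidates: set[SearchNode]) -> SearchNode:
    """One MCTS lookahead: descend by pUCT to an unexpanded leaf, add it to
    the candidate set, back its (cached) f up the traversed path.

    No expansion happens here and no single-step model is called; node f
    values were computed when the nodes were created. Raises if the root
    has no live descendants (exhausted search space)."""
    if not root.live:
        raise ValueError("simulate called on an exhausted tree")
    path = [root]
    node = root
    while node.status == EXPANDED:
        node = puct_select(node, c_puct)
        path.append(node)
    candidates.add(node)
    backup(path, node.f)
    return node


def select_candidate(candidates) -> SearchNode:
    """Minimum-f candidate; ties broken by larger g, then earlier creation."""
    best = None
    for c in candidates:
        if best is None:
            best = c
            continue
        if (c.f, -c.g, c.creation_index) < (best.f, -best.g, best.creation_index):
            best = c
    if best is None:
        raise ValueError("empty candidate set: search space exhausted")
    return best


def _mark_unlive(node: SearchNode) -> None:
    """Remove a node from the live frontier and propagate upward."""
    node.live = False
    p = node.parent
    while p is not None and p.live:
        if p.status == EXPANDED and not any(c.live for c in p.children):
            p.live = False
            p = p.parent
        else:
            break


class _Tree:
    """Bookkeeping shared by one search run."""

    def __init__(self, root_state: State, stock: Stock, policy: ExpansionPolicy,
                 estimator: Estimator, config: SearchConfig):
        self.stock = stock
        self.policy = policy
        self.estimator = estimator
        self.config = config
        self.nodes_created = 0
        self.root = self._new_node(root_state, None, None, 0.0)
        # Lazy min-heap over open (unexpanded, live) leaves; f is frozen at
        # creation so stale entries are skipped on peek.
        self.open_heap: list[tuple[float, float, int, SearchNode]] = []
        self._push_open(self.root)

    def _new_node(self, state, parent, reaction, g) -> SearchNode:
        node = SearchNode(state, parent, reaction, g, self.nodes_created)
        self.nodes_created += 1
        if is_terminal(state, self.stock):
            node.status = TERMINAL
        evaluate_f(node, self.estimator, self.stock)
        node.stats.Q = node.f  # greedy-on-f before any backup
        return node

    def _push_open(self, node: SearchNode) -> None:
        if node.status == UNEXPANDED:
            heapq.heappush(self.open_heap,
                           (node.f, -node.g, node.creation_index, node))

    def open_min(self) -> Optional[SearchNode]:
        """Peek the minimum-f open live leaf (A* selection / certificate
        lower bound); discards stale heap entries."""
        while self.open_heap:
            _, _, _, node = self.open_heap[0]
            if node.status == UNEXPANDED and node.live:
                return node
            heapq.heappop(self.open_heap)
        return None


def expand_node(tree: _Tree, node: SearchNode) -> list[SearchNode]:
    """Expand an unexpanded node: create children from the top-k policy
    proposals, skipping successors equal to an ancestor state (cycle
    control) and successors beyond ``max_depth``.

    Returns the terminal children created (possibly empty). A node with
    no surviving children becomes a dead end. Counts as one model call
    (accounted by the caller)."""
    if node.status != UNEXPANDED:
        raise ValueError(f"cannot expand node with status {node.status!r}")
    cfg = tree.config
    ancestors = set()
    a = node
    while a is not None:
        ancestors.add(a.state)
        a = a.parent
    terminal_children: list[SearchNode] = []
    for reaction, nstate, cost in successors(tree.policy, node.state,
                                             tree.stock, cfg.k_expansion):
        if nstate in ancestors:
            continue
        if cfg.max_depth is not None and node.depth + 1 > cfg.max_depth:
            continue
        child = tree._new_node(nstate, node, reaction, node.g + cost)
        node.children.append(child)
        if child.status == TERMINAL:
            child.live = False  # goals are banked, never simulated into
            terminal_children.append(child)
        else:
            tree._push_open(child)
    if any(c.live for c in node.children):
        node.status = EXPANDED
    elif terminal_children:
        node.status = EXPANDED
        _mark_unlive(node)
    else:
        node.status = DEAD_END
        _mark_unlive(node)
    return terminal_children


def extract_route(goal_node: SearchNode, target: Molecule) -> Route:
    """Root-to-goal route; route cost equals g(goal) by construction."""
    if goal_node.status != TERMINAL:
        raise ValueError("can only extract a route from a terminal node")
    chain: list[SearchNode] = []
    n = goal_node
    while n.parent is not None:
        chain.append(n)
        n = n.parent
    chain.reverse()
    steps = tuple(
        RouteStep(state=c.parent.state, reaction=c.reaction,
                  g=c.parent.g, h=c.parent.h)
        for c in chain
    )
    return Route(target=target, steps=steps, final_state=goal_node.state)


# ---------------------------------------------------------------------------
# The search loop
# ---------------------------------------------------------------------------


def _run(target: Molecule, stock: Stock, policy: ExpansionPolicy,
         estimator: Estimator, config: SearchConfig,
         max_routes: Optional[int] = None,
         ) -> tuple[SearchResult, list[Route]]:
    t0 = time.monotonic()
    root_state = canonicalize_state([target])
    tree = _Tree(root_state, stock, policy, estimator, config)
    root = tree.root

    if root.status == TERMINAL:
        result = SearchResult(
            success=True, route=Route(target=target, steps=(),
                                      final_state=root_state),
            expansions=0, model_calls=0, wall_time=time.monotonic() - t0,
            nodes_created=tree.nodes_created, iterations=0, trace=[],
            first_solution_time=0.0, certified=True,
        )
        return result, [result.route]

    stop_first = config.stop_on_first_goal and max_routes is None
    goals: list[SearchNode] = []
    goal_sigs: set[tuple] = set()
    trace: list[TraceRecord] = []
    model_calls = 0
    expansions = 0
    iteration = 0
    first_solution_time: Optional[float] = None
    certified = False
    exhausted = False
    success_goal: Optional[SearchNode] = None

    def best_goal() -> Optional[SearchNode]:
        if not goals:
            return None
        return min(goals, key=lambda n: (n.g, n.creation_index))

    while True:
        if model_calls >= config.max_model_calls:
            break
        if time.monotonic() - t0 > config.max_wall_seconds:
            break
        if not root.live:
            exhausted = True
            if not stop_first:
                certified = bool(goals)
            break
        # Certified termination: the cheapest banked goal beats every
        # open leaf's optimistic f (exact when h never overestimates).
        if not stop_first and max_routes is None and goals:
            lb = tree.open_min()
            bg = best_goal()
            if lb is None or bg.g <= lb.f + 1e-12:
                certified = True
                break

        iteration += 1
        if config.mode == "astar":
            candidate = tree.open_min()
            if candidate is None:
                exhausted = True
                break
            candidate_size = 0
        else:
            candidates: set[SearchNode] = set()
            for _ in range(config.k_mcts):
                if not root.live:
                    break
                simulate(root, config.c_puct, candidates)
            if not candidates:
                exhausted = True
                break
            candidate = select_candidate(candidates)
            candidate_size = len(candidates)

        terminal_children = expand_node(tree, candidate)
        model_calls += 1
        expansions += 1
        trace.append(TraceRecord(
            iteration=iteration, state=candidate.state, g=candidate.g,
            h=candidate.h, f=candidate.f, candidate_size=candidate_size,
            model_calls=model_calls,
        ))

        if terminal_children:
            if first_solution_time is None:
                first_solution_time = time.monotonic() - t0
            for tc in sorted(terminal_children,
                             key=lambda n: (n.g, n.creation_index)):
                sig = tuple((c.reaction.product, c.reaction.template_id)
                            for c in _chain(tc))
                if sig not in goal_sigs:
                    goal_sigs.add(sig)
                    goals.append(tc)
            if stop_first:
                success_goal = min(terminal_children,
                                   key=lambda n: (n.g, n.creation_index))
                break
            if max_routes is not None and len(goals) >= max_routes:
                break

    if success_goal is None:
        success_goal = best_goal()
    route = (extract_route(success_goal, target)
             if success_goal is not None else None)
    result = SearchResult(
        success=route is not None,
        route=route,
        expansions=expansions,
        model_calls=model_calls,
        wall_time=time.monotonic() - t0,
        nodes_created=tree.nodes_created,
        iterations=iteration,
        trace=trace,
        first_solution_time=first_solution_time,
        certified=certified,
        exhausted=exhausted,
    )
    route_list = [extract_route(n, target) for n in goals]
    if max_routes is not None:
        route_list = route_list[:max_routes]
    return result, route_list


def search(target: Molecule, stock: Stock, policy: ExpansionPolicy,
           estimator: Estimator, config: Optional[SearchConfig] = None,
           ) -> SearchResult:
    """Plan a synthetic route for ``target``.

    Returns a :class:`SearchResult`; on success ``result.route`` is the
    extracted root-to-terminal route and ``result.route.cost == g(goal)``.
    """
    if config is None:
        config = SearchConfig()
    result, _ = _run(target, stock, policy, estimator, config)
    return result


def enumerate_routes(target: Molecule, stock: Stock, policy: ExpansionPolicy,
                     estimator: Estimator,
                     config: Optional[SearchConfig] = None,
                     max_routes: int = 25) -> list[Route]:
    """Collect up to ``max_routes`` distinct routes in discovery order.

    Goal nodes are banked (never expanded) and the search continues until
    enough routes are found, the budget runs out, or the space is
    exhausted. May return fewer routes than requested."""
    if max_routes < 1:
        raise ValueError("max_routes must be >= 1")
    if config is None:
        config = SearchConfig()
    _, routes = _run(target, stock, policy, estimator, config,
                     max_routes=max_routes)
    return routes


def _chain(goal: SearchNode) -> list[SearchNode]:
    out = []
    n = goal
    while n.parent is not None:
        out.append(n)
        n = n.parent
    out.reverse()
    return out
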