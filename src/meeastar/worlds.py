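"""Synthetic reaction worlds: finite, DAG-structured reaction universes.

A :class:`ReactionWorld` is a toy stand-in for a large reaction corpus: a
building-block stock, a set of intermediates organized in layers, and
retro-reactions whose reactants always lie strictly below their product in
a topological order. DAG structure keeps the state space finite, so a
brute-force uniform-cost oracle (:func:`optimal_route_oracle`) can compute
the exact cheapest route and exact shortest length for every target —
the ground truth against which the search algorithms are tested.

Molecule naming: ``B####`` building blocks, ``M####`` intermediates,
``D####`` decoy dead-ends, ``P####`` poison dead-ends (adversarial
fixtures), ``T`` / ``A#`` / ``C#`` / ``E...`` in the hand-shaped
adversarial fixtures.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field, asdict
from functools import cached_property
from typing import Optional

import numpy as np

from .mdp import (
    Molecule,
    Reaction,
    State,
    Stock,
    apply_reaction,
    first_open_molecule,
    is_terminal,
)
from .routes import Route, RouteStep

__all__ = [
    "WorldConfig",
    "ReactionWorld",
    "OracleResult",
    "DecoyFixture",
    "generate_world",
    "optimal_route_oracle",
    "OracleCostTable",
    "count_routes",
    "adversarial_decoy_world",
]

#: Hard cap on distinct canonical states the oracle may explore.
ORACLE_NODE_CAP = 200_000

UNSOLVABLE = math.inf


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the random world generator.

    ``depth_range`` bounds the number of intermediate layers (the minimum
    number of reactions on the deepest target's route). ``decoy_rate`` is
    the fraction of intermediates that receive an extra attractive-looking
    reaction leading into a dead-end decoy molecule; decoys are never a
    product's only option, so every target stays solvable.
    ``feasibility_range`` is the uniform support of reaction feasibilities
    (default [0.2, 1.0], keeping edge costs away from numerically
    dominating near-zero probabilities).
    """

    n_stock: int = 8
    n_intermediates: int = 12
    max_reactants: int = 3
    max_reactions_per_product: int = 2
    depth_range: tuple[int, int] = (2, 4)
    decoy_rate: float = 0.0
    feasibility_range: tuple[float, float] = (0.2, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_stock, self.n_intermediates, self.max_reactants,
               self.max_reactions_per_product) < 1:
            raise ValueError("all counts must be positive")
        lo, hi = self.depth_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid depth_range {self.depth_range}")
        if hi > self.n_intermediates:
            raise ValueError(
                f"depth {hi} unachievable with {self.n_intermediates} "
                "intermediates (need at least one per layer)"
            )
        if not (0.0 <= self.decoy_rate <= 1.0):
            raise ValueError("decoy_rate must be in [0, 1]")
        flo, fhi = self.feasibility_range
        if not (0.0 < flo <= fhi <= 1.0):
            raise ValueError("feasibility_range must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class ReactionWorld:
    """A finite reaction universe with known stock and target pool."""

    stock: Stock
    reactions: tuple[Reaction, ...]
    targets: tuple[Molecule, ...]
    config: Optional[WorldConfig] = None
    seed: Optional[int] = None

    @cached_property
    def reactions_by_product(self) -> dict[Molecule, tuple[Reaction, ...]]:
        table: dict[Molecule, list[Reaction]] = {}
        for r in self.reactions:
            table.setdefault(r.product, []).append(r)
        return {p: tuple(rs) for p, rs in table.items()}

    @cached_property
    def molecules(self) -> frozenset[Molecule]:
        mols = set(self.stock.members)
        for r in self.reactions:
            mols.add(r.product)
            mols.update(r.reactants)
        return frozenset(mols)

    def validate(self) -> None:
        """Check the acyclic-synthesis invariant (reactants can be ordered
        strictly before their products) and feasibility bounds."""
        # DFS cycle check on the reactant -> product dependency graph.
        edges: dict[Molecule, set[Molecule]] = {}
        for r in self.reactions:
            if not (0.0 < r.feasibility <= 1.0):
                raise ValueError(f"feasibility out of range in {r.template_id}")
            for m in r.reactants:
                edges.setdefault(m, set()).add(r.product)
        color: dict[Molecule, int] = {}

        def visit(m: Molecule, stack: list) -> None:
            color[m] = 1
            for nxt in edges.get(m, ()):
                c = color.get(nxt, 0)
                if c == 1:
                    raise ValueError(
                        f"cyclic synthesis structure through {nxt!r}"
                    )
                if c == 0:
                    visit(nxt, stack)
            color[m] = 2

        for m in sorted(self.molecules):
            if color.get(m, 0) == 0:
                visit(m, [])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "stock": sorted(self.stock.members),
            "reactions": [r.to_dict() for r in self.reactions],
            "targets": list(self.targets),
            "seed": self.seed,
        }
        if self.config is not None:
            cfg = asdict(self.config)
            cfg["depth_range"] = list(cfg["depth_range"])
            cfg["feasibility_range"] = list(cfg["feasibility_range"])
            d["config"] = cfg
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionWorld":
        cfg = None
        if d.get("config") is not None:
            c = dict(d["config"])
            c["depth_range"] = tuple(c["depth_range"])
            c["feasibility_range"] = tuple(c["feasibility_range"])
            cfg = WorldConfig(**c)
        return cls(
            stock=Stock.from_iterable(d["stock"]),
            reactions=tuple(Reaction.from_dict(r) for r in d["reactions"]),
            targets=tuple(d["targets"]),
            config=cfg,
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, path) -> "ReactionWorld":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def generate_world(config: WorldConfig) -> ReactionWorld:
    """Draw a random DAG world from ``config`` (deterministic per seed).

    Intermediates are placed on 1..depth layers; every reaction's reactants
    come from strictly lower layers (or stock) with at least one reactant
    from the layer immediately below, so the top layer's molecules need at
    least ``depth`` reactions. Every intermediate keeps at least one
    decoy-free reaction, hence every target is solvable by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
    sizes = [1] * depth
    for _ in range(config.n_intermediates - depth):
        sizes[int(rng.integers(depth))] += 1

    stock_mols = [f"B{i:04d}" for i in range(1, config.n_stock + 1)]
    layers: list[list[Molecule]] = [list(stock_mols)]
    idx = 0
    for d in range(depth):
        layer = []
        for _ in range(sizes[d]):
            idx += 1
            layer.append(f"M{idx:04d}")
        layers.append(layer)

    flo, fhi = config.feasibility_range
    reactions: list[Reaction] = []
    n_templates = 0
    n_decoys = 0

    def new_template() -> str:
        nonlocal n_templates
        n_templates += 1
        return f"T{n_templates:04d}"

    for d in range(1, depth + 1):
        below = [m for layer in layers[:d] for m in layer]
        anchor_pool = layers[d - 1]
        for product in layers[d]:
            n_rxn = int(rng.integers(1, config.max_reactions_per_product + 1))
            for _ in range(n_rxn):
                n_react = int(rng.integers(1, config.max_reactants + 1))
                anchor = anchor_pool[int(rng.integers(len(anchor_pool)))]
                others = [m for m in below if m != anchor]
                extra = list(
                    rng.choice(others, size=min(n_react - 1, len(others)),
                               replace=False)
                ) if n_react > 1 and others else []
                reactants = tuple(sorted({anchor, *map(str, extra)}))
                reactions.append(Reaction(
                    product=product,
                    reactants=reactants,
                    template_id=new_template(),
                    prior=float(rng.uniform(0.1, 1.0)),
                    feasibility=float(rng.uniform(flo, fhi)),
                ))
            if rng.random() < config.decoy_rate:
                n_decoys += 1
                decoy = f"D{n_decoys:04d}"
                reactions.append(Reaction(
                    product=product,
                    reactants=(decoy,),
                    template_id=new_template(),
                    prior=float(rng.uniform(0.8, 1.0)),
                    feasibility=float(rng.uniform(0.8, 1.0)),
                ))

    world = ReactionWorld(
        stock=Stock.from_iterable(stock_mols),
        reactions=tuple(reactions),
        targets=tuple(layers[depth]),
        config=config,
        seed=config.seed,
    )
    world.validate()
    return world


@dataclass(frozen=True)
class OracleResult:
    """Exact ground truth for one target of a world.

    ``optimal_cost`` is the minimum total -ln(feasibility) over the state
    space (``math.inf`` when unsolvable); ``shortest_length`` the minimum
    number of reactions; ``n_routes`` the count of distinct routes up to
    ``route_depth_bound`` reactions (None when counting was not requested).
    """

    target: Molecule
    optimal_cost: float
    optimal_route: Optional[Route]
    shortest_length: float
    shortest_route: Optional[Route]
    n_routes: Optional[int] = None
    route_depth_bound: Optional[int] = None
    nodes_explored: int = 0

    @property
    def solvable(self) -> bool:
        return math.isfinite(self.optimal_cost)


def _world_successors(world: ReactionWorld, state: State):
    mol = first_open_molecule(state, world.stock)
    for r in world.reactions_by_product.get(mol, ()):
        yield r, apply_reaction(state, r)


def _dijkstra(
    world: ReactionWorld,
    start: State,
    unit: bool,
    node_cap: int,
) -> tuple[float, Optional[list[tuple[State, Reaction]]], int]:
    """Uniform-cost search over canonical states; returns (cost, step list,
    states settled). Step list is None when unsolvable."""
    if is_terminal(start, world.stock):
        return 0.0, [], 0
    dist: dict[State, float] = {start: 0.0}
    parent: dict[State, tuple[State, Reaction]] = {}
    done: set[State] = set()
    heap: list[tuple[float, int, State]] = [(0.0, 0, start)]
    tick = 0
    while heap:
        d, _, s = heapq.heappop(heap)
        if s in done or d > dist.get(s, math.inf):
            continue
        done.add(s)
        if is_terminal(s, world.stock):
            steps: list[tuple[State, Reaction]] = []
            cur = s
            while cur != start:
                prev, r = parent[cur]
                steps.append((prev, r))
                cur = prev
            steps.reverse()
            return d, steps, len(done)
        for r, nxt in _world_successors(world, s):
            nd = d + (1.0 if unit else r.cost)
            if nd < dist.get(nxt, math.inf) - 1e-15:
                dist[nxt] = nd
                parent[nxt] = (s, r)
                tick += 1
                heapq.heappush(heap, (nd, tick, nxt))
                if len(dist) > node_cap:
                    raise RuntimeError(
                        f"oracle state space exceeds cap ({node_cap})"
                    )
    return UNSOLVABLE, None, len(done)


def _steps_to_route(target: Molecule, steps: list[tuple[State, Reaction]]) -> Route:
    route_steps = []
    g = 0.0
    state: State = (target,)
    for s, r in steps:
        route_steps.append(RouteStep(state=s, reaction=r, g=g))
        g += r.cost
        state = apply_reaction(s, r)
    return Route(target=target, steps=tuple(route_steps), final_state=state)


def count_routes(
    world: ReactionWorld,
    state: State,
    depth_bound: int,
    cap: int = 1_000_000,
) -> int:
    """Number of distinct routes from ``state`` to a terminal state using at
    most ``depth_bound`` reactions (exact recursive count, memoized)."""
    memo: dict[tuple[State, int], int] = {}

    def rec(s: State, budget: int) -> int:
        if is_terminal(s, world.stock):
            return 1
        if budget == 0:
            return 0
        key = (s, budget)
        if key in memo:
            return memo[key]
        if len(memo) > cap:
            raise RuntimeError(f"route counting exceeds cap ({cap})")
        total = sum(rec(nxt, budget - 1) for _, nxt in _world_successors(world, s))
        memo[key] = total
        return total

    return rec(state, depth_bound)


def optimal_route_oracle(
    world: ReactionWorld,
    target: Molecule,
    count_depth: Optional[int] = None,
    node_cap: int = ORACLE_NODE_CAP,
) -> OracleResult:
    """Exact cheapest-route and shortest-route ground truth for ``target``.

    Runs uniform-cost search over the set-of-molecules state space under
    the first-open-molecule convention — the same transition system the
    planners search — so its optimum is a true lower bound for every
    search mode. Raises if ``target`` is not a molecule of the world.
    """
    if target not in world.molecules:
        raise ValueError(f"target {target!r} not in world")
    start: State = (target,)
    cost, steps, n1 = _dijkstra(world, start, unit=False, node_cap=node_cap)
    length, lsteps, n2 = _dijkstra(world, start, unit=True, node_cap=node_cap)
    n_routes = None
    if count_depth is not None:
        n_routes = count_routes(world, start, count_depth)
    return OracleResult(
        target=target,
        optimal_cost=cost,
        optimal_route=_steps_to_route(target, steps) if steps is not None else None,
        shortest_length=length,
        shortest_route=_steps_to_route(target, lsteps) if lsteps is not None else None,
        n_routes=n_routes,
        route_depth_bound=count_depth,
        nodes_explored=max(n1, n2),
    )


class OracleCostTable:
    """Memoized exact remaining cost from arbitrary states of a world.

    ``unit=True`` measures remaining reactions instead of -ln(feasibility)
    cost. Unsolvable states map to ``math.inf``. Backs the exact
    consistent heuristic used in optimality tests."""

    def __init__(self, world: ReactionWorld, unit: bool = False,
                 node_cap: int = ORACLE_NODE_CAP):
        self.world = world
        self.unit = unit
        self.node_cap = node_cap
        self._cache: dict[State, float] = {}

    def cost_from(self, state: State) -> float:
        if state not in self._cache:
            cost, _, _ = _dijkstra(self.world, state, self.unit, self.node_cap)
            self._cache[state] = cost
        return self._cache[state]

    def __call__(self, state: State) -> float:
        return self.cost_from(state)


# ---------------------------------------------------------------------------
# Adversarial fixtures: the two classic failure modes of guided search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecoyFixture:
    """An adversarial world plus the biased per-molecule heuristic table.

    ``scenario="deep"``: a deep, heuristic-flattering dead-end chain that a
    plain best-first search digs to the bottom before trying the real
    branch; lookahead statistics (poisoned branch averages) let MEEA*
    abandon it early.

    ``scenario="wide"``: many shallow mediocre branches around one deep
    true route; a pure-MCTS search compulsively samples the width while
    min-f selection walks straight down the true chain.

    ``heuristic`` maps molecules to the (biased) per-molecule cost
    estimates to be summed per state; missing molecules (stock) count 0.
    """

    world: ReactionWorld
    target: Molecule
    heuristic: dict[Molecule, float]
    scenario: str


def adversarial_decoy_world(
    scenario: str = "deep",
    seed: int = 0,
    enable_decoy: bool = True,
) -> DecoyFixture:
    """Build the deterministic adversarial fixture for ``scenario``.

    With ``enable_decoy=False`` the misleading branch is omitted, leaving
    a plain solvable world on which every mode finds the optimum."""
    if scenario not in ("deep", "wide"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    reactions: list[Reaction] = []
    h: dict[Molecule, float] = {}
    stock = [f"B{i:04d}" for i in range(1, 4)]
    target = "T0000"
    n_tpl = 0

    def rxn(product, reactants, prior, feas):
        nonlocal n_tpl
        n_tpl += 1
        reactions.append(Reaction(
            product=product, reactants=tuple(sorted(set(reactants))),
            template_id=f"T{n_tpl:04d}", prior=prior, feasibility=feas,
        ))

    if scenario == "deep":
        # True branch: T -> A1 -> A2 -> {B1, B2}; honest per-molecule h.
        feas_true = [float(rng.uniform(0.75, 0.85)) for _ in range(3)]
        rxn(target, ["A0001"], 0.5, feas_true[0])
        rxn("A0001", ["A0002"], 0.9, feas_true[1])
        rxn("A0002", [stock[0], stock[1]], 0.9, feas_true[2])
        h["A0001"] = -math.log(feas_true[1]) - math.log(feas_true[2])
        h["A0002"] = -math.log(feas_true[2])
        if enable_decoy:
            # Decoy: a binary tree of attractive-looking molecules (biased
            # h far below truth) that all dead-end at the bottom, with
            # moderately-bad poison siblings at every level. A best-first
            # search must clear the whole sub-threshold region node by
            # node; lookahead backups mix the poison values into the
            # branch average and shut the branch off at the root.
            levels = int(rng.integers(5, 7))
            n_d = n_p = 0

            def grow(parent: str, depth: int) -> None:
                nonlocal n_d, n_p
                if depth >= levels:
                    return  # dead end
                kids = []
                for _ in range(2):
                    n_d += 1
                    kid = f"D{n_d:04d}"
                    h[kid] = float(rng.uniform(0.2, 0.3))
                    rxn(parent, [kid], 0.6,
                        float(rng.uniform(0.90, 0.95)))
                    kids.append(kid)
                for _ in range(2):
                    n_p += 1
                    p = f"P{n_p:04d}"
                    h[p] = float(rng.uniform(2.5, 3.5))
                    rxn(parent, [p], 0.3, float(rng.uniform(0.7, 0.85)))
                for kid in kids:
                    grow(kid, depth + 1)

            n_d += 1
            h["D0001"] = float(rng.uniform(0.2, 0.3))
            rxn(target, ["D0001"], 0.9, float(rng.uniform(0.90, 0.95)))
            grow("D0001", 1)
    else:  # wide
        # True branch: chain T -> C1 -> ... -> C5 -> {B1, B2}; exact h.
        chain = [f"C{i:04d}" for i in range(1, 6)]
        feas = [float(rng.uniform(0.78, 0.86)) for _ in range(6)]
        seq = [target] + chain
        for i in range(5):
            rxn(seq[i], [seq[i + 1]], 0.6, feas[i])
        rxn(chain[-1], [stock[0], stock[1]], 0.6, feas[5])
        costs = [-math.log(f) for f in feas]
        for i, m in enumerate(chain):
            h[m] = sum(costs[i + 1:])
        h[target] = sum(costs)
        if enable_decoy:
            # 5 mediocre bushy branches of depth 3 hanging off the root.
            n_e = 0
            for w in range(5):
                n_e += 1
                top = f"E{n_e:04d}"
                rxn(target, [top], 0.4, float(rng.uniform(0.75, 0.9)))
                frontier = [top]
                for depth in range(3):
                    nxt = []
                    for node in frontier:
                        h[node] = float(rng.uniform(1.4, 2.4))
                        if depth < 2:
                            for _ in range(3):
                                n_e += 1
                                child = f"E{n_e:04d}"
                                rxn(node, [child], 0.4,
                                    float(rng.uniform(0.75, 0.9)))
                                nxt.append(child)
                    frontier = nxt
                for node in frontier:  # depth-3 dead ends
                    h[node] = float(rng.uniform(1.4, 2.4))

    world = ReactionWorld(
        stock=Stock.from_iterable(stock),
        reactions=tuple(reactions),
        targets=(target,),
        seed=seed,
    )
    world.validate()
    return DecoyFixture(world=world, target=target, heuristic=h,
                        scenario=scenario)
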