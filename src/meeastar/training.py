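"""Path-consistency-regularized training of the joint cost estimator.

Solved routes are turned into (state, remaining-cost) supervision: at step
t of a route, the true remaining cost c(s_t) is the suffix sum of reaction
costs and g(s_t) the prefix sum. The estimator h_theta is fit with

    L = L_RL + lambda * L_PC,

where L_RL = (h(s) - c(s))^2 is the plain regression loss and L_PC is the
squared deviation of f(s) = g(s) + h(s) from the mean f along the state's
own route. Path consistency expresses that f is constant along an optimal
route (with an exact heuristic, f everywhere equals the route cost); as a
regularizer it couples the estimates of all states of a route and damps
per-state overfitting. The route mean f-bar is treated as a detached
target (no gradient flows through the mean); f is recomputed from the
current network every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _nn
from .heuristics import JointEstimator
from .mdp import State
from .routes import Route

__all__ = [
    "RouteExample",
    "LossConfig",
    "TrainingHistory",
    "route_to_training_examples",
    "rl_loss",
    "pc_loss",
    "combined_loss",
    "train_estimator",
    "make_route_corpus",
]


@dataclass(frozen=True)
class RouteExample:
    """One supervised example: a state with its path-cost coordinates.

    ``g`` is the accumulated cost from the route's root to this state and
    ``c`` the true remaining cost to the route's end; c(terminal) = 0.
    Along one route g is non-decreasing and c non-increasing."""

    state: State
    g: float
    c: float


def route_to_training_examples(route: Route) -> list[RouteExample]:
    """One example per route state (including the terminal state).

    c(s_t) is the suffix sum of reaction costs from step t onward, g(s_t)
    the prefix sum before step t; c(s_t) = cost_t + c(s_{t+1}) holds by
    construction. Raises ``ValueError`` on malformed routes."""
    route.validate()
    costs = [s.reaction.cost for s in route.steps]
    total = sum(costs)
    examples = []
    g = 0.0
    for i, step in enumerate(route.steps):
        examples.append(RouteExample(state=step.state, g=g, c=total - g))
        g += costs[i]
    examples.append(RouteExample(state=route.final_state, g=g, c=0.0))
    return examples


def rl_loss(h_pred: float, c_true: float) -> float:
    """Squared-error regression loss (h - c)^2."""
    return (h_pred - c_true) ** 2


def pc_loss(f_values: Sequence[float]) -> list[float]:
    """Per-state path-consistency losses (f - f_bar)^2 along one route.

    f_bar is the mean of all f values of the route; a constant-f route
    (path consistency satisfied) yields all zeros."""
    if len(f_values) == 0:
        raise ValueError("pc_loss requires at least one f value")
    f = np.asarray(f_values, dtype=float)
    fbar = float(f.mean())
    return [float((v - fbar) ** 2) for v in f]


def combined_loss(rl: float, pc: float, lam: float) -> float:
    """L = L_RL + lambda * L_PC; lambda must be non-negative."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return rl + lam * pc


@dataclass
class LossConfig:
    """Training hyperparameters; ``lam`` is the PC regularization weight
    (default 5.5)."""

    lam: float = 5.5
    lr: float = 0.001
    batch_size: int = 256
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch mean losses on the training and validation corpora."""

    train_rl: list[float] = field(default_factory=list)
    train_pc: list[float] = field(default_factory=list)
    val_rl: list[float] = field(default_factory=list)
    val_pc: list[float] = field(default_factory=list)

    @property
    def final_gap(self) -> float:
        """Validation-minus-train L_RL at the last epoch."""
        return self.val_rl[-1] - self.train_rl[-1]


def _route_groups(routes: Sequence[Route]) -> list[list[RouteExample]]:
    groups = [route_to_training_examples(r) for r in routes]
    if not groups:
        raise ValueError("empty training corpus")
    return groups


def _evaluate(est: JointEstimator, groups: list[list[RouteExample]],
              ) -> tuple[float, float]:
    """Mean L_RL and L_PC over all states of a grouped corpus (raw head)."""
    rl_sum = 0.0
    pc_sum = 0.0
    n = 0
    for group in groups:
        h = np.array([est.raw(ex.state) for ex in group])
        c = np.array([ex.c for ex in group])
        g = np.array([ex.g for ex in group])
        f = g + h
        fbar = f.mean()
        rl_sum += float(((h - c) ** 2).sum())
        pc_sum += float(((f - fbar) ** 2).sum())
        n += len(group)
    return rl_sum / n, pc_sum / n


def train_estimator(
    train_routes: Sequence[Route],
    estimator: JointEstimator,
    config: Optional[LossConfig] = None,
    val_routes: Sequence[Route] = (),
) -> TrainingHistory:
    """Fit the joint estimator on a route corpus by Adam on the combined
    loss; deterministic given the config seed.

    Batches are whole routes (f-bar is a per-route quantity, so route
    groups are never split); routes are accumulated into a batch until it
    holds at least ``batch_size`` states. History records the mean L_RL
    and L_PC on train and validation corpora after every epoch."""
    if config is None:
        config = LossConfig()
    groups = _route_groups(train_routes)
    val_groups = [route_to_training_examples(r) for r in val_routes]
    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(estimator.params, lr=config.lr)
    history = TrainingHistory()
    lam = config.lam

    for _ in range(config.epochs):
        order = rng.permutation(len(groups))
        batch: list[list[RouteExample]] = []
        batch_states = 0
        for gi in order:
            batch.append(groups[gi])
            batch_states += len(groups[gi])
            if batch_states >= config.batch_size:
                _sgd_step(estimator, opt, batch, lam)
                batch, batch_states = [], 0
        if batch:
            _sgd_step(estimator, opt, batch, lam)
        tr_rl, tr_pc = _evaluate(estimator, groups)
        history.train_rl.append(tr_rl)
        history.train_pc.append(tr_pc)
        if val_groups:
            va_rl, va_pc = _evaluate(estimator, val_groups)
            history.val_rl.append(va_rl)
            history.val_pc.append(va_pc)
    return history


def _relabel_route(route: Route, prefix: str) -> Route:
    """Prefix every molecule identifier (keeps within-route sort order)."""
    from .mdp import Reaction
    from .routes import RouteStep

    def relabel_state(state: State) -> State:
        return tuple(prefix + m for m in state)

    steps = tuple(
        RouteStep(
            state=relabel_state(s.state),
            reaction=Reaction(
                product=prefix + s.reaction.product,
                reactants=relabel_state(s.reaction.reactants),
                template_id=s.reaction.template_id,
                prior=s.reaction.prior,
                feasibility=s.reaction.feasibility,
            ),
            g=s.g, h=s.h,
        )
        for s in route.steps
    )
    return Route(target=prefix + route.target, steps=steps,
                 final_state=relabel_state(route.final_state))


def make_route_corpus(n_routes: int = 200, seed: int = 0,
                      max_per_target: int = 1) -> list[Route]:
    """Solved-route corpus for estimator training, from random worlds.

    Draws small DAG worlds (6 building blocks, 10 intermediates, depth
    2-4, 20% decoy branches) with seeds derived from ``seed`` and collects
    up to ``max_per_target`` routes per target by budgeted search, until
    ``n_routes`` routes are gathered. Each world's molecules are
    namespaced with a per-world prefix so identically named molecules
    from different worlds stay distinct (they are unrelated chemistry and
    must not share features). Deterministic given ``seed``."""
    from .planning import SearchConfig, enumerate_routes
    from .policy import policy_from_world
    from .worlds import WorldConfig, generate_world
    from .heuristics import zero_heuristic

    routes: list[Route] = []
    i = 0
    while len(routes) < n_routes:
        wseed = (seed * 1_000_003 + i) % (2 ** 31)
        prefix = f"w{i}:"
        i += 1
        world = generate_world(WorldConfig(
            n_stock=6, n_intermediates=10, depth_range=(2, 4),
            decoy_rate=0.2, seed=wseed,
        ))
        policy = policy_from_world(world)
        cfg = SearchConfig(mode="meea", max_model_calls=300)
        for target in world.targets:
            found = enumerate_routes(target, world.stock, policy,
                                     zero_heuristic, cfg,
                                     max_routes=max_per_target)
            routes.extend(_relabel_route(r, prefix) for r in found)
            if len(routes) >= n_routes:
                break
    return routes[:n_routes]


def _sgd_step(est: JointEstimator, opt: _nn.Adam,
              batch: list[list[RouteExample]], lam: float) -> None:
    """One gradient step on mean combined loss over the batch's states."""
    # Flatten all molecules of all states, remembering state boundaries.
    states: list[RouteExample] = [ex for group in batch for ex in group]
    route_id = np.concatenate([
        np.full(len(group), ri) for ri, group in enumerate(batch)
    ])
    n_states = len(states)
    mol_rows = []
    seg = []
    for si, ex in enumerate(states):
        for m in ex.state:
            mol_rows.append(est.features(m))
            seg.append(si)
    if mol_rows:
        X = np.stack(mol_rows)
        seg = np.array(seg)
        Z = X @ est.W1 + est.b1
        E = _nn.relu(Z)
        EG = np.zeros((n_states, est.embedding_dim))
        np.add.at(EG, seg, E)
    else:
        X = np.zeros((0, est.n_features))
        seg = np.array([], dtype=int)
        Z = np.zeros((0, est.embedding_dim))
        EG = np.zeros((n_states, est.embedding_dim))
    h = EG @ est.w2 + est.b2[0]
    c = np.array([ex.c for ex in states])
    g = np.array([ex.g for ex in states])
    f = g + h
    # Per-route detached mean f.
    n_routes = len(batch)
    sums = np.zeros(n_routes)
    counts = np.zeros(n_routes)
    np.add.at(sums, route_id, f)
    np.add.at(counts, route_id, 1.0)
    fbar = (sums / counts)[route_id]

    dh = (2.0 * (h - c) + lam * 2.0 * (f - fbar)) / n_states
    gw2 = EG.T @ dh
    gb2 = np.array([dh.sum()])
    if len(seg):
        dE = np.outer(dh[seg], est.w2)
        dZ = dE * _nn.drelu(Z)
        gW1 = X.T @ dZ
        gb1 = dZ.sum(axis=0)
    else:
        gW1 = np.zeros_like(est.W1)
        gb1 = np.zeros_like(est.b1)
    opt.step([gW1, gb1, gw2, gb2])
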