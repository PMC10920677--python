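"""Cost estimators h(s): the remaining-cost heuristics guiding the search.

An estimator is any callable ``State -> float`` (non-negative; the empty
state maps to 0). Provided here:

* :func:`zero_heuristic` — h = 0, trivially consistent (the uninformed
  baseline);
* :class:`SumEstimator` — h(s) = sum of independent per-molecule cost
  predictions;
* :class:`JointEstimator` — a whole-state network: per-molecule embeddings
  are sum-pooled into a global state embedding and read out as a single
  scalar cost, so inter-molecular context can inform the estimate and the
  output is invariant to molecule order;
* :func:`oracle_estimator` — the exact remaining cost of a synthetic
  world, consistent by construction (test instrument).
"""

from __future__ import annotations

import json
from typing import Callable, Mapping, Optional, Union

import numpy as np

from . import _nn
from .mdp import Molecule, State
from .worlds import OracleCostTable, ReactionWorld

__all__ = [
    "Estimator",
    "zero_heuristic",
    "SumEstimator",
    "sum_estimator",
    "JointEstimator",
    "oracle_estimator",
]

Estimator = Callable[[State], float]


def zero_heuristic(state: State) -> float:
    """The zero heuristic: h(s) = 0 for every state."""
    return 0.0


zero_heuristic.descriptor = "zero"  # type: ignore[attr-defined]


class SumEstimator:
    """h(s) = sum over molecules of a per-molecule cost function.

    ``per_molecule`` is either a mapping (missing molecules — typically
    stock members — default to ``default``) or a callable. Per-molecule
    values must be non-negative."""

    def __init__(
        self,
        per_molecule: Union[Mapping[Molecule, float], Callable[[Molecule], float]],
        default: float = 0.0,
        descriptor: str = "sum",
    ):
        if callable(per_molecule):
            self._fn = per_molecule
        else:
            table = dict(per_molecule)
            self._fn = lambda m: table.get(m, default)
        self.descriptor = descriptor

    def __call__(self, state: State) -> float:
        total = 0.0
        for m in state:
            v = self._fn(m)
            if v < 0:
                raise ValueError(f"negative per-molecule cost for {m!r}: {v}")
            total += v
        return total


def sum_estimator(
    per_molecule: Union[Mapping[Molecule, float], Callable[[Molecule], float]],
    default: float = 0.0,
) -> SumEstimator:
    """Convenience constructor for :class:`SumEstimator`."""
    return SumEstimator(per_molecule, default=default)


class JointEstimator:
    """Whole-state cost network with sum-pooled molecule embeddings.

    Each molecule is featurized (hashed token features by default; any
    ``Molecule -> vector`` featurizer such as a Morgan fingerprint works),
    passed through one dense ReLU layer into an embedding, embeddings are
    summed into the global state embedding, and a linear head reads out a
    scalar cost. The readout head is zero-initialized, so a fresh
    estimator predicts 0 for every state. Predictions are clipped at 0
    (costs are non-negative); training operates on the raw head output.
    """

    def __init__(
        self,
        n_features: int = 64,
        embedding_dim: int = 128,
        featurizer: Optional[Callable[[Molecule], np.ndarray]] = None,
        seed: int = 0,
    ):
        self.n_features = n_features
        self.embedding_dim = embedding_dim
        if featurizer is None:
            featurizer = lambda m: _nn.token_hash_features(m, n_features)
        self.featurizer = featurizer
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / n_features),
                             size=(n_features, embedding_dim))
        self.b1 = np.zeros(embedding_dim)
        self.w2 = np.zeros(embedding_dim)
        self.b2 = np.zeros(1)
        self._feat_cache: dict[Molecule, np.ndarray] = {}
        self.descriptor = "joint"

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.w2, self.b2]

    def features(self, molecule: Molecule) -> np.ndarray:
        if molecule not in self._feat_cache:
            x = np.asarray(self.featurizer(molecule), dtype=float)
            if x.shape != (self.n_features,):
                raise ValueError(
                    f"featurizer returned shape {x.shape}, "
                    f"expected ({self.n_features},) for {molecule!r}"
                )
            self._feat_cache[molecule] = x
        return self._feat_cache[molecule]

    def state_matrix(self, state: State) -> np.ndarray:
        return np.stack([self.features(m) for m in state])

    def raw(self, state: State) -> float:
        """Unclipped head output (training scale). Empty state -> 0."""
        if not state:
            return 0.0
        X = self.state_matrix(state)
        E = _nn.relu(X @ self.W1 + self.b1)
        eg = E.sum(axis=0)
        return float(eg @ self.w2 + self.b2[0])

    def __call__(self, state: State) -> float:
        return max(0.0, self.raw(state))

    # -- checkpointing (text format) ---------------------------------------

    def save(self, path) -> None:
        payload = {
            "format": "meeastar-joint-estimator-v1",
            "n_features": self.n_features,
            "embedding_dim": self.embedding_dim,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path, featurizer=None) -> "JointEstimator":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "meeastar-joint-estimator-v1":
            raise ValueError("unrecognized estimator checkpoint format")
        est = cls(
            n_features=payload["n_features"],
            embedding_dim=payload["embedding_dim"],
            featurizer=featurizer,
        )
        est.W1 = np.array(payload["W1"])
        est.b1 = np.array(payload["b1"])
        est.w2 = np.array(payload["w2"])
        est.b2 = np.array(payload["b2"])
        return est


def oracle_estimator(world: ReactionWorld, unit: bool = False) -> OracleCostTable:
    """Exact remaining-cost estimator for a finite world.

    h(s) is the brute-force minimal remaining cost from s (``math.inf``
    for unsolvable states), memoized per state; consistent by construction
    since it satisfies the Bellman equation of the same transition system
    the planners search."""
    return OracleCostTable(world, unit=unit)
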