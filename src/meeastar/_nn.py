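"""Minimal dense-network building blocks shared by the learned estimators.

Only what the package needs: a hashed token featurizer for synthetic-world
molecule identifiers, dense layers with manual gradients, and Adam. Kept
deliberately small; real-chemistry featurization (Morgan fingerprints) lives
in :mod:`meeastar.policy`.
"""

from __future__ import annotations

import zlib
from typing import Iterable

import numpy as np

__all__ = ["token_hash_features", "Adam", "relu", "drelu"]


def token_hash_features(identifier: str, width: int = 64) -> np.ndarray:
    """Deterministic pseudo-random feature vector for an identifier string.

    The CRC32 of the identifier seeds a generator that draws a fixed
    standard-normal vector, so the mapping is stable across processes and
    independent of any global seed. Used to featurize synthetic-world
    molecule tokens, which carry no chemical substructure.
    """
    seed = zlib.crc32(identifier.encode("utf8"))
    rng = np.random.default_rng(seed)
    return rng.standard_normal(width)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def drelu(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: Iterable[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
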