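"""Single-step retrosynthetic expansion policy.

The policy B answers: given one molecule, which k reactions are most likely
to have produced it, and with what prior probability? Two implementations
are provided behind one duck-typed contract (any object with a
``proposals(molecule)`` method returning ranked :class:`PolicyProposal`
lists):

* :class:`TabularPolicy` — an explicit product -> proposals table, the
  exact policy of a synthetic reaction world;
* :class:`ClassifierPolicy` — the template-classifier contract used for
  real chemistry: featurize the molecule, score reaction templates with a
  one-hidden-layer softmax network, apply the top templates to obtain
  reactant sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from . import _nn
from .mdp import (
    Molecule,
    Reaction,
    State,
    Stock,
    apply_reaction,
    first_open_molecule,
    is_terminal,
)

__all__ = [
    "PolicyProposal",
    "ExpansionPolicy",
    "TabularPolicy",
    "ClassifierPolicy",
    "TemplateClassifier",
    "morgan_fingerprint",
    "expand_molecule",
    "successors",
    "policy_from_world",
]

DEFAULT_TOP_K = 50


@dataclass(frozen=True)
class PolicyProposal:
    """One ranked candidate reaction for a queried molecule."""

    reaction: Reaction
    prior: float
    rank: int


class ExpansionPolicy(Protocol):
    def proposals(self, molecule: Molecule) -> list[PolicyProposal]:
        """Full ranked proposal list for ``molecule`` (empty = dead end)."""


def _rank_proposals(reactions: Sequence[Reaction]) -> list[PolicyProposal]:
    """Sort by prior descending, ties broken by template_id, assign ranks."""
    ordered = sorted(reactions, key=lambda r: (-r.prior, r.template_id))
    return [
        PolicyProposal(reaction=r, prior=r.prior, rank=i + 1)
        for i, r in enumerate(ordered)
    ]


class TabularPolicy:
    """Explicit mapping from product molecule to ranked reaction proposals.

    The test double for B in synthetic worlds: it *is* the world's reaction
    table. Unknown molecules yield an empty proposal list (dead end).
    """

    def __init__(self, table: dict[Molecule, Sequence[Reaction]]):
        self._table: dict[Molecule, list[PolicyProposal]] = {}
        for product, reactions in table.items():
            for r in reactions:
                if r.product != product:
                    raise ValueError(
                        f"reaction {r.template_id!r} filed under {product!r} "
                        f"but produces {r.product!r}"
                    )
            self._table[product] = _rank_proposals(reactions)

    def proposals(self, molecule: Molecule) -> list[PolicyProposal]:
        return self._table.get(molecule, [])

    @property
    def products(self) -> list[Molecule]:
        return sorted(self._table)

    def to_json(self, path) -> None:
        payload = {
            product: [
                {
                    "template_id": p.reaction.template_id,
                    "reactants": list(p.reaction.reactants),
                    "prior": p.reaction.prior,
                    "feasibility": p.reaction.feasibility,
                }
                for p in props
            ]
            for product, props in self._table.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TabularPolicy":
        with open(path) as fh:
            payload = json.load(fh)
        table = {
            product: [
                Reaction(
                    product=product,
                    reactants=tuple(e["reactants"]),
                    template_id=e["template_id"],
                    prior=float(e["prior"]),
                    feasibility=float(e.get("feasibility", e["prior"])),
                )
                for e in entries
            ]
            for product, entries in payload.items()
        }
        return cls(table)


def expand_molecule(
    policy: ExpansionPolicy, molecule: Molecule, k: int = DEFAULT_TOP_K
) -> list[PolicyProposal]:
    """Top-k proposals for ``molecule``, sorted by prior descending.

    An empty list signals a dead end, not an error."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return policy.proposals(molecule)[:k]


def successors(
    policy: ExpansionPolicy,
    state: State,
    stock: Stock,
    k: int = DEFAULT_TOP_K,
) -> list[tuple[Reaction, State, float]]:
    """Successor states of ``state`` under the first-open-molecule convention.

    For each of the top-k proposals on the first non-stock molecule, returns
    ``(reaction, next_state, edge_cost)`` in proposal-rank order. Raises
    ``ValueError`` on terminal states."""
    if is_terminal(state, stock):
        raise ValueError("cannot expand a terminal state")
    target = first_open_molecule(state, stock)
    out = []
    for prop in expand_molecule(policy, target, k):
        nxt = apply_reaction(state, prop.reaction)
        out.append((prop.reaction, nxt, prop.reaction.cost))
    return out


def policy_from_world(world) -> TabularPolicy:
    """Exact tabular policy of a synthetic reaction world.

    Priors are the world's raw priors normalized per product molecule;
    feasibilities are kept as-is (they define edge costs)."""
    table: dict[Molecule, list[Reaction]] = {}
    for r in world.reactions:
        table.setdefault(r.product, []).append(r)
    normalized: dict[Molecule, list[Reaction]] = {}
    for product, reactions in table.items():
        total = sum(r.prior for r in reactions)
        normalized[product] = [
            Reaction(
                product=r.product,
                reactants=r.reactants,
                template_id=r.template_id,
                prior=r.prior / total,
                feasibility=r.feasibility,
            )
            for r in reactions
        ]
    return TabularPolicy(normalized)


# ---------------------------------------------------------------------------
# Classifier policy contract (real-chemistry shape, toy-scale training)
# ---------------------------------------------------------------------------


def morgan_fingerprint(
    smiles: str, radius: int = 2, n_bits: int = 2048
) -> np.ndarray:
    """Morgan (circular) fingerprint bit vector via RDKit (optional extra)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits
    )
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=np.float32)


class TemplateClassifier:
    """One-hidden-layer softmax classifier over reaction template ids.

    Architecture: dense(hidden, relu) -> dense(n_templates) -> softmax;
    trained with cross-entropy and Adam. Defaults follow the standard
    template-classification setup (512 hidden units, lr 0.001, batch 1024);
    the training loop here is intended for small synthetic template sets.
    """

    def __init__(
        self,
        n_features: int,
        template_ids: Sequence[str],
        hidden: int = 512,
        seed: int = 0,
    ):
        if not template_ids:
            raise ValueError("need at least one template id")
        self.template_ids = list(template_ids)
        rng = np.random.default_rng(seed)
        n_out = len(self.template_ids)
        s1 = np.sqrt(2.0 / n_features)
        s2 = np.sqrt(2.0 / hidden)
        self.W1 = rng.normal(0.0, s1, size=(n_features, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, s2, size=(hidden, n_out))
        self.b2 = np.zeros(n_out)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def _logits(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Z = X @ self.W1 + self.b1
        H = _nn.relu(Z)
        return Z, H @ self.W2 + self.b2

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax distribution over templates; rows sum to 1."""
        X = np.atleast_2d(X)
        _, logits = self._logits(X)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def fit(
        self,
        X: np.ndarray,
        template_labels: Sequence[str],
        epochs: int = 50,
        lr: float = 0.001,
        batch_size: int = 1024,
        seed: int = 0,
    ) -> list[float]:
        """Cross-entropy training; returns the per-epoch mean loss history."""
        index = {t: i for i, t in enumerate(self.template_ids)}
        y = np.array([index[t] for t in template_labels])
        X = np.asarray(X, dtype=float)
        n = len(y)
        opt = _nn.Adam(self.params, lr=lr)
        rng = np.random.default_rng(seed)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                Xb, yb = X[idx], y[idx]
                Z, logits = self._logits(Xb)
                logits = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(logits)
                P = e / e.sum(axis=1, keepdims=True)
                losses.append(
                    float(-np.log(P[np.arange(len(yb)), yb] + 1e-12).mean())
                )
                G = P.copy()
                G[np.arange(len(yb)), yb] -= 1.0
                G /= len(yb)
                H = _nn.relu(Z)
                gW2 = H.T @ G
                gb2 = G.sum(axis=0)
                GH = (G @ self.W2.T) * _nn.drelu(Z)
                gW1 = Xb.T @ GH
                gb1 = GH.sum(axis=0)
                opt.step([gW1, gb1, gW2, gb2])
            history.append(float(np.mean(losses)))
        return history


#: Template applier signature: (template_id, molecule) -> reactant tuples.
#: Returning no reactant sets means the template does not apply.
TemplateApplier = Callable[[str, Molecule], Sequence[tuple[Molecule, ...]]]


class ClassifierPolicy:
    """Expansion policy backed by a featurizer + template classifier.

    ``featurizer`` maps a molecule to a fixed-length vector (Morgan
    fingerprint for real chemistry, hashed token features for synthetic
    worlds); ``classifier`` scores templates; ``applier`` instantiates a
    template on the molecule, yielding zero or more reactant sets.
    Proposals whose template does not apply are discarded *before* top-k
    truncation, so the caller always sees up to k applicable reactions.
    """

    def __init__(
        self,
        featurizer: Callable[[Molecule], np.ndarray],
        classifier: TemplateClassifier,
        applier: TemplateApplier,
        feasibility_fn: Optional[Callable[[Reaction], float]] = None,
    ):
        self.featurizer = featurizer
        self.classifier = classifier
        self.applier = applier
        self.feasibility_fn = feasibility_fn

    def proposals(self, molecule: Molecule) -> list[PolicyProposal]:
        x = self.featurizer(molecule)
        probs = self.classifier.predict_proba(x)[0]
        order = sorted(
            range(len(probs)),
            key=lambda i: (-probs[i], self.classifier.template_ids[i]),
        )
        reactions = []
        for i in order:
            tid = self.classifier.template_ids[i]
            prior = float(probs[i])
            if prior <= 0.0:
                continue
            for reactants in self.applier(tid, molecule):
                reactants = tuple(sorted(set(reactants)))
                if not reactants or molecule in reactants:
                    continue
                r = Reaction(
                    product=molecule,
                    reactants=reactants,
                    template_id=tid,
                    prior=prior,
                    feasibility=prior,
                )
                if self.feasibility_fn is not None:
                    r = Reaction(
                        product=r.product,
                        reactants=r.reactants,
                        template_id=r.template_id,
                        prior=r.prior,
                        feasibility=self.feasibility_fn(r),
                    )
                reactions.append(r)
        return _rank_proposals(reactions)
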