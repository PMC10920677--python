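"""Markov decision process for retrosynthetic planning.

A *state* is the set of molecules still required to synthesize the target:
the search starts from ``{target}`` and applies retro-reactions backwards,
replacing a product molecule with its reactants, until every molecule in the
state is a purchasable building block (a *stock* member).

Molecules are opaque canonical identifier strings. Without a chemistry
backend the identifier text itself is canonical (synthetic worlds use tokens
like ``"M0007"``); with the optional RDKit backend identifiers are canonical
SMILES. This keeps the whole search stack runnable with zero chemistry
dependencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

__all__ = [
    "Molecule",
    "State",
    "Stock",
    "Reaction",
    "rdkit_canonicalizer",
    "canonicalize_state",
    "is_terminal",
    "first_open_molecule",
    "apply_reaction",
    "reaction_cost",
    "load_stock",
    "save_stock",
]

#: Molecules are canonical identifier strings.
Molecule = str

#: A state is a lexicographically sorted, duplicate-free tuple of molecules.
State = tuple[Molecule, ...]

#: Canonicalizer signature: raw identifier -> canonical identifier.
Canonicalizer = Callable[[str], str]


def rdkit_canonicalizer(raw: str) -> str:
    """Canonicalize a SMILES string through RDKit.

    Raises ``ValueError`` on unparsable input. RDKit is an optional
    dependency; import happens on first use.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise ValueError(f"invalid SMILES: {raw!r}")
    return Chem.MolToSmiles(mol)


def _canonical_one(raw: str, canonicalizer: Optional[Canonicalizer]) -> Molecule:
    if not isinstance(raw, str) or not raw:
        raise ValueError(f"invalid molecule identifier: {raw!r}")
    if canonicalizer is None:
        return raw
    return canonicalizer(raw)


def canonicalize_state(
    molecules: Iterable[str],
    canonicalizer: Optional[Canonicalizer] = None,
) -> State:
    """Build a canonical state: each molecule canonicalized, sorted, deduplicated.

    States are sorted lexicographically by canonical identifier, which also
    removes duplicates (set semantics). The empty state is allowed and is
    vacuously terminal.

    Raises ``ValueError`` naming the offending entry if any identifier is
    invalid or fails canonicalization.
    """
    canon = []
    for raw in molecules:
        try:
            canon.append(_canonical_one(raw, canonicalizer))
        except ValueError:
            raise
        except Exception as exc:  # backend-specific failure
            raise ValueError(f"cannot canonicalize molecule {raw!r}: {exc}") from exc
    return tuple(sorted(set(canon)))


@dataclass(frozen=True)
class Stock:
    """A building-block stock: the set of purchasable molecules."""

    members: frozenset[Molecule]

    @classmethod
    def from_iterable(cls, molecules: Iterable[Molecule]) -> "Stock":
        return cls(frozenset(molecules))

    def __contains__(self, molecule: Molecule) -> bool:
        return molecule in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Reaction:
    """A retro-reaction decomposing ``product`` into ``reactants``.

    ``prior`` is the single-step policy probability pi(a|m) used for ranking
    proposals; ``feasibility`` is the reaction-feasibility probability
    p_r(a|m) that defines the edge cost -ln p_r. The two are trained
    separately in general and may differ.
    """

    product: Molecule
    reactants: State
    template_id: str
    prior: float = 1.0
    feasibility: float = 1.0

    def __post_init__(self) -> None:
        if not self.reactants:
            raise ValueError("reaction must have at least one reactant")
        if tuple(sorted(set(self.reactants))) != tuple(self.reactants):
            object.__setattr__(
                self, "reactants", tuple(sorted(set(self.reactants)))
            )
        if self.product in self.reactants:
            raise ValueError(
                f"product {self.product!r} cannot appear among its reactants"
            )
        if not (0.0 < self.prior <= 1.0):
            raise ValueError(f"prior must be in (0, 1], got {self.prior}")
        if not (0.0 < self.feasibility <= 1.0):
            raise ValueError(
                f"feasibility must be in (0, 1], got {self.feasibility}"
            )

    @property
    def cost(self) -> float:
        """Edge cost -ln(feasibility)."""
        return reaction_cost(self.feasibility)

    def to_dict(self) -> dict:
        return {
            "product": self.product,
            "reactants": list(self.reactants),
            "template_id": self.template_id,
            "prior": self.prior,
            "feasibility": self.feasibility,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Reaction":
        return cls(
            product=d["product"],
            reactants=tuple(d["reactants"]),
            template_id=d["template_id"],
            prior=float(d.get("prior", 1.0)),
            feasibility=float(d.get("feasibility", 1.0)),
        )


def is_terminal(state: State, stock: Stock) -> bool:
    """True iff every molecule in ``state`` is a stock member.

    The empty state is terminal (vacuous subset)."""
    return all(m in stock for m in state)


def first_open_molecule(state: State, stock: Stock) -> Molecule:
    """The lexicographically first molecule of ``state`` not in stock.

    This is the expansion convention: actions always apply to the first
    non-building-block molecule. Raises ``ValueError`` on terminal states."""
    for m in state:
        if m not in stock:
            return m
    raise ValueError("terminal state has no open molecule to expand")


def apply_reaction(state: State, reaction: Reaction) -> State:
    """Transition: replace ``reaction.product`` in ``state`` by its reactants.

    The result is re-canonicalized (sorted, duplicates collapsed). Raises
    ``ValueError`` if the product is absent from the state."""
    if reaction.product not in state:
        raise ValueError(
            f"product {reaction.product!r} not present in state {state!r}"
        )
    rest = [m for m in state if m != reaction.product]
    rest.extend(reaction.reactants)
    return tuple(sorted(set(rest)))


def reaction_cost(feasibility: float) -> float:
    """Reaction cost -ln(p_r); non-negative for p_r in (0, 1]."""
    if not (0.0 < feasibility <= 1.0):
        raise ValueError(f"feasibility must be in (0, 1], got {feasibility}")
    return -math.log(feasibility)


def load_stock(path, canonicalizer: Optional[Canonicalizer] = None) -> Stock:
    """Read a stock file: one identifier per line, '#' comments ignored."""
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                members.append(_canonical_one(line, canonicalizer))
    return Stock.from_iterable(members)


def save_stock(stock: Stock, path) -> None:
    with open(path, "w") as fh:
        for m in sorted(stock.members):
            fh.write(m + "\n")
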