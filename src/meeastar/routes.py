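"""Synthetic routes: root-to-terminal sequences of (state, reaction) pairs.

A route records the full trajectory of the planning MDP: step ``t`` holds
the state *before* applying its reaction, and ``final_state`` holds the
terminal state whose molecules are all building blocks (the route's
*leaves*). Routes serialize to JSON (one object, or JSON-lines for
corpora).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .mdp import Molecule, Reaction, State, Stock, apply_reaction, is_terminal

__all__ = ["RouteStep", "Route", "save_routes_jsonl", "load_routes_jsonl"]


@dataclass(frozen=True)
class RouteStep:
    """One planning step: ``reaction`` applied to ``state``.

    ``g`` is the accumulated cost *before* this step; ``h`` an optional
    heuristic estimate of the state recorded at search time (0 when the
    route was not produced by a guided search)."""

    state: State
    reaction: Reaction
    g: float = 0.0
    h: float = 0.0

    @property
    def f(self) -> float:
        return self.g + self.h


@dataclass(frozen=True)
class Route:
    """A complete synthetic route for ``target``.

    May be empty (target already in stock): then ``final_state`` is just
    ``(target,)`` and cost and length are 0."""

    target: Molecule
    steps: tuple[RouteStep, ...]
    final_state: State

    @property
    def cost(self) -> float:
        """Total route cost: sum of -ln(feasibility) over reactions."""
        return sum(s.reaction.cost for s in self.steps)

    @property
    def length(self) -> int:
        """Number of reactions."""
        return len(self.steps)

    @property
    def leaves(self) -> frozenset[Molecule]:
        """Building blocks consumed by the route (molecules of the terminal
        state)."""
        return frozenset(self.final_state)

    def signature(self) -> tuple:
        """Hashable identity: the ordered (product, template) sequence."""
        return tuple((s.reaction.product, s.reaction.template_id) for s in self.steps)

    def validate(self, stock: Optional[Stock] = None) -> None:
        """Check internal consistency; raises ``ValueError`` on defects.

        Verifies the transition chain (each step's reaction applied to its
        state yields the next state), the g accumulation, and — when a
        stock is given — that the final state is terminal."""
        state: State = (self.target,)
        g = 0.0
        for i, step in enumerate(self.steps):
            if step.state != state:
                raise ValueError(
                    f"step {i}: recorded state {step.state!r} != expected {state!r}"
                )
            if abs(step.g - g) > 1e-9:
                raise ValueError(f"step {i}: recorded g {step.g} != expected {g}")
            state = apply_reaction(state, step.reaction)
            g += step.reaction.cost
        if state != self.final_state:
            raise ValueError(
                f"final state {self.final_state!r} != reached state {state!r}"
            )
        if stock is not None and not is_terminal(state, stock):
            raise ValueError("route does not end in a terminal state")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "steps": [
                {
                    "state": list(s.state),
                    "reaction": s.reaction.to_dict(),
                    "g": s.g,
                    "h": s.h,
                    "f": s.f,
                }
                for s in self.steps
            ],
            "final_state": list(self.final_state),
            "cost": self.cost,
            "length": self.length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Route":
        steps = tuple(
            RouteStep(
                state=tuple(s["state"]),
                reaction=Reaction.from_dict(s["reaction"]),
                g=float(s.get("g", 0.0)),
                h=float(s.get("h", 0.0)),
            )
            for s in d["steps"]
        )
        return cls(
            target=d["target"],
            steps=steps,
            final_state=tuple(d["final_state"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Route":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def save_routes_jsonl(routes: Iterable[Route], path) -> None:
    """Write a route corpus, one JSON object per line."""
    with open(path, "w") as fh:
        for r in routes:
            fh.write(json.dumps(r.to_dict()) + "\n")


def load_routes_jsonl(path) -> list[Route]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(Route.from_dict(json.loads(line)))
    return out
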