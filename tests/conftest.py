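"""Shared fixtures: tiny hand-checkable worlds and their policies."""

import math

import pytest

from meeastar.mdp import Reaction, Stock
from meeastar.policy import policy_from_world
from meeastar.worlds import ReactionWorld


@pytest.fixture
def chain_world():
    """Single linear route: M3 -> M2 -> M1 -> {B1, B2}; costs known."""
    reactions = (
        Reaction(product="M1", reactants=("B1", "B2"), template_id="T1",
                 prior=1.0, feasibility=0.5),
        Reaction(product="M2", reactants=("M1",), template_id="T2",
                 prior=1.0, feasibility=0.8),
        Reaction(product="M3", reactants=("M2",), template_id="T3",
                 prior=1.0, feasibility=0.25),
    )
    return ReactionWorld(
        stock=Stock.from_iterable(["B1", "B2"]),
        reactions=reactions,
        targets=("M3",),
    )


@pytest.fixture
def diamond_world():
    """Two routes for M1: via M2 (cost 0.9) or via M3 (cost 1.4).

    Edge costs are engineered through feasibilities exp(-c); the cheap
    branch goes M1 -> M2 -> {B1} with costs 0.4 + 0.5, the expensive one
    M1 -> M3 -> {B2} with costs 0.6 + 0.8."""
    e = math.exp
    reactions = (
        Reaction(product="M1", reactants=("M2",), template_id="Tcheap",
                 prior=0.6, feasibility=e(-0.4)),
        Reaction(product="M1", reactants=("M3",), template_id="Tdear",
                 prior=0.4, feasibility=e(-0.6)),
        Reaction(product="M2", reactants=("B1",), template_id="T2",
                 prior=1.0, feasibility=e(-0.5)),
        Reaction(product="M3", reactants=("B2",), template_id="T3",
                 prior=1.0, feasibility=e(-0.8)),
    )
    return ReactionWorld(
        stock=Stock.from_iterable(["B1", "B2"]),
        reactions=reactions,
        targets=("M1",),
    )


@pytest.fixture
def chain_policy(chain_world):
    return policy_from_world(chain_world)


@pytest.fixture
def diamond_policy(diamond_world):
    return policy_from_world(diamond_world)
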