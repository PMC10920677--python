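"""Independent textbook implementations of A* and MCTS for equivalence tests.

Deliberately coded from scratch against the plain algorithm statements —
own node containers, own loops — sharing only the problem conventions
(successor generation through the policy, first-open-molecule expansion,
ancestor-state cycle pruning, larger-g-then-earlier-creation tie-breaks,
success on generation of a terminal child). They return the sequence of
expanded states so the package's search trace can be compared
node-for-node.
"""

import heapq
import math

from meeastar.mdp import is_terminal
from meeastar.policy import successors


def astar_reference(target, stock, policy, estimator, k=50, max_calls=500):
    """Plain open-list A*: pop min-f, expand, push children.

    Returns (expanded_states, success, goal_cost)."""
    counter = 0

    def hval(state):
        if is_terminal(state, stock):
            return 0.0
        return max(0.0, estimator(state))

    root = (target,)
    if is_terminal(root, stock):
        return [], True, 0.0
    heap = []
    h0 = hval(root)
    heapq.heappush(heap, (0.0 + h0, -0.0, counter, root, 0.0, frozenset()))
    expanded = []
    calls = 0
    while heap and calls < max_calls:
        f, ng, idx, state, g, ancestors = heapq.heappop(heap)
        expanded.append(state)
        calls += 1
        anc = ancestors | {state}
        for reaction, nstate, cost in successors(policy, state, stock, k):
            if nstate in anc:
                continue
            cg = g + cost
            if is_terminal(nstate, stock):
                return expanded, True, cg
            counter += 1
            heapq.heappush(heap, (cg + hval(nstate), -cg, counter,
                                  nstate, cg, anc))
    return expanded, False, math.inf


class _MctsNode:
    def __init__(self, state, parent, g, h, order):
        self.state = state
        self.parent = parent
        self.g = g
        self.h = h
        self.f = g + h
        self.children = []
        self.N = 0          # edge visit count (edge from parent)
        self.Q = self.f     # edge mean value, initialized to own f
        self.expanded = False
        self.dead = False
        self.order = order


def mcts_reference(target, stock, policy, estimator, c_puct=4.0, k=50,
                   max_calls=500):
    """Textbook MCTS: pUCT selection to a leaf, evaluate, backup, expand.

    Uniform-prior pUCT: argmax over live children of
    -Q + c_puct * (1/|A|) * sqrt(sum N) / (1 + N).
    Returns (expanded_states, success, goal_cost)."""

    def hval(state):
        if is_terminal(state, stock):
            return 0.0
        return max(0.0, estimator(state))

    order = 0
    root = _MctsNode((target,), None, 0.0, hval((target,)), order)
    if is_terminal(root.state, stock):
        return [], True, 0.0
    expanded = []
    calls = 0

    def live_children(node):
        return [c for c in node.children if not c.dead]

    while calls < max_calls and not root.dead:
        # selection
        node = root
        path = [root]
        while node.expanded:
            kids = live_children(node)
            tot = sum(c.N for c in kids)
            s = math.sqrt(tot)
            node = max(kids, key=lambda c: (
                -c.Q + c_puct * (1.0 / len(kids)) * s / (1 + c.N),
                c.g, -c.order))
            path.append(node)
        # evaluation + backup of the leaf's f
        for n in path[1:]:
            n.Q = (n.N * n.Q + node.f) / (n.N + 1)
            n.N += 1
        # expansion
        expanded.append(node.state)
        calls += 1
        ancestors = {n.state for n in path}
        goal_costs = []
        for reaction, nstate, cost in successors(policy, node.state, stock, k):
            if nstate in ancestors:
                continue
            if is_terminal(nstate, stock):
                goal_costs.append(node.g + cost)
                continue
            order += 1
            node.children.append(
                _MctsNode(nstate, node, node.g + cost, hval(nstate), order))
        if goal_costs:
            return expanded, True, min(goal_costs)
        if node.children:
            node.expanded = True
        else:
            node.dead = True
            p = node.parent
            while p is not None and not live_children(p):
                p.dead = True
                p = p.parent
    return expanded, False, math.inf
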