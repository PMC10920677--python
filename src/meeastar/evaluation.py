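"""Route quality and diversity metrics, plus benchmark summarization.

Routes are compared as ordered labeled trees: molecule nodes alternate
with reaction nodes, and children are sorted by molecule identifier so the
metric does not depend on serialization order. Similarity is the exact
ordered tree edit distance (Zhang–Shasha dynamic program, unit
insert/delete/relabel costs by default); diversity is the number of
complete-linkage clusters of the pairwise TED matrix under a distance
threshold; leaves overlap measures how many of a reference route's
building blocks a generated route reuses.
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .mdp import Molecule
from .routes import Route

__all__ = [
    "RouteTree",
    "build_route_tree",
    "tree_edit_distance",
    "leaves_overlap",
    "cluster_routes",
    "TargetResult",
    "BenchmarkSummary",
    "summarize_benchmark",
    "write_benchmark_csv",
]


@dataclass(frozen=True)
class RouteTree:
    """Ordered labeled tree node (molecule or reaction level)."""

    label: str
    children: tuple["RouteTree", ...] = ()

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)


def build_route_tree(route: Route) -> RouteTree:
    """Lossless tree form of a route.

    Molecule nodes are labeled ``mol:<id>``; below each decomposed
    molecule sits one reaction node ``rxn:<template>`` whose children are
    the reactant subtrees, sorted by identifier. Leaves are the route's
    building blocks. An empty route is the single target node."""
    class _Node:
        __slots__ = ("label", "children")

        def __init__(self, label):
            self.label = label
            self.children = []

        def freeze(self) -> RouteTree:
            return RouteTree(label=self.label,
                             children=tuple(c.freeze() for c in self.children))

    # Replay the route: a state holds one merged copy per molecule, so a
    # reaction on molecule m resolves *all* currently open tree copies of
    # m (duplicated subtrees, as usual for route trees). A molecule can
    # reappear — and be decomposed again — after set-collapse removed it.
    root = _Node(f"mol:{route.target}")
    open_copies: dict[Molecule, list[_Node]] = {route.target: [root]}
    for step in route.steps:
        r = step.reaction
        nodes = open_copies.pop(r.product, None)
        if not nodes:
            raise ValueError(
                f"reaction on {r.product!r} but no pending copy in the tree"
            )
        for node in nodes:
            rxn = _Node(f"rxn:{r.template_id}")
            node.children.append(rxn)
            for m in sorted(r.reactants):
                child = _Node(f"mol:{m}")
                rxn.children.append(child)
                open_copies.setdefault(m, []).append(child)
    return root.freeze()


# ---------------------------------------------------------------------------
# Zhang–Shasha ordered tree edit distance
# ---------------------------------------------------------------------------


def _postorder(tree: RouteTree):
    """Postorder node labels, leftmost-leaf indices, and LR keyroots."""
    labels: list[str] = []
    lml: list[int] = []

    def walk(node: RouteTree) -> int:
        first = None
        for c in node.children:
            idx = walk(c)
            if first is None:
                first = lml[idx]
        my = len(labels)
        labels.append(node.label)
        lml.append(my if first is None else first)
        return my

    walk(tree)
    n = len(labels)
    # Keyroots: highest node for each distinct leftmost leaf (no proper
    # ancestor shares it); in postorder that is the last index per lml.
    seen: dict[int, int] = {}
    for i in range(n):
        seen[lml[i]] = i
    keyroots = sorted(seen.values())
    return labels, lml, keyroots


def tree_edit_distance(a: RouteTree, b: RouteTree,
                       indel_cost: float = 1.0,
                       relabel_cost: float = 1.0) -> float:
    """Exact edit distance between two ordered labeled trees.

    Unit-cost insert/delete/relabel by default (relabel is free between
    equal labels). Symmetric; zero iff the trees are identical."""
    la, l1, kr1 = _postorder(a)
    lb, l2, kr2 = _postorder(b)
    n, m = len(la), len(lb)
    td = np.zeros((n, m))

    def cost(i: int, j: int) -> float:
        return 0.0 if la[i] == lb[j] else relabel_cost

    for i in kr1:
        for j in kr2:
            # forest distance over suffix forests rooted at keyroots i, j
            ioff, joff = l1[i], l2[j]
            ni, nj = i - ioff + 2, j - joff + 2
            fd = np.zeros((ni, nj))
            fd[1:, 0] = np.arange(1, ni) * indel_cost
            fd[0, 1:] = np.arange(1, nj) * indel_cost
            for di in range(1, ni):
                x = ioff + di - 1
                for dj in range(1, nj):
                    y = joff + dj - 1
                    if l1[x] == ioff and l2[y] == joff:
                        fd[di, dj] = min(
                            fd[di - 1, dj] + indel_cost,
                            fd[di, dj - 1] + indel_cost,
                            fd[di - 1, dj - 1] + cost(x, y),
                        )
                        td[x, y] = fd[di, dj]
                    else:
                        fd[di, dj] = min(
                            fd[di - 1, dj] + indel_cost,
                            fd[di, dj - 1] + indel_cost,
                            fd[l1[x] - ioff, l2[y] - joff] + td[x, y],
                        )
    return float(td[n - 1, m - 1])


def leaves_overlap(generated: Route, reference: Route) -> float:
    """Fraction of the reference route's building blocks reused by the
    generated route: |leaves(gen) & leaves(ref)| / |leaves(ref)|."""
    ref_leaves = reference.leaves
    if not ref_leaves:
        raise ValueError("reference route has no leaves")
    return len(generated.leaves & ref_leaves) / len(ref_leaves)


def cluster_routes(routes: Sequence[Route],
                   threshold: float = 2.0) -> tuple[int, list[int]]:
    """Complete-linkage clustering of routes under pairwise TED.

    Returns (number of clusters, 1-based cluster labels in input order).
    The default threshold (routes within 2 edits merge) is a convention,
    not a literature value; tune per application. Deterministic given
    input order."""
    if not routes:
        raise ValueError("cluster_routes requires at least one route")
    n = len(routes)
    if n == 1:
        return 1, [1]
    from scipy.cluster.hierarchy import fcluster, linkage

    trees = [build_route_tree(r) for r in routes]
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(tree_edit_distance(trees[i], trees[j]))
    Z = linkage(np.array(condensed), method="complete")
    labels = fcluster(Z, t=threshold, criterion="distance")
    return int(labels.max()), [int(x) for x in labels]


# ---------------------------------------------------------------------------
# Benchmark summarization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetResult:
    """Per-target planning outcome."""

    target: Molecule
    success: bool
    length: Optional[int] = None
    cost: Optional[float] = None
    model_calls: int = 0
    wall_time: float = 0.0
    first_solution_time: Optional[float] = None


@dataclass(frozen=True)
class BenchmarkSummary:
    """Aggregates over a target set.

    ``avg_length``/``avg_cost`` charge failures the configured penalty
    (penalized averages); ``min_avg_length``/``min_avg_cost`` instead set
    *successes* to zero while failures keep the penalty — a lower bound on
    any achievable average under the same failure set."""

    n_targets: int
    n_success: int
    success_rate: float
    avg_length: float
    avg_cost: float
    min_avg_length: float
    min_avg_cost: float
    avg_model_calls: float
    mean_first_solution_time: Optional[float]
    penalty_length: float
    penalty_cost: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize_benchmark(results: Sequence[TargetResult],
                        penalty_length: float = 32.0,
                        penalty_cost: float = 64.0) -> BenchmarkSummary:
    """Success rate and penalized/zero-filled averages over targets.

    Failure penalties are configurable conventions (no canonical value
    exists); both the penalized and the zero-filled ("minimum") averages
    are reported so the choice is visible."""
    if not results:
        raise ValueError("summarize_benchmark requires at least one result")
    n = len(results)
    succ = [r for r in results if r.success]
    lengths = [r.length if r.success else penalty_length for r in results]
    costs = [r.cost if r.success else penalty_cost for r in results]
    min_lengths = [0.0 if r.success else penalty_length for r in results]
    min_costs = [0.0 if r.success else penalty_cost for r in results]
    fst = [r.first_solution_time for r in succ
           if r.first_solution_time is not None]
    return BenchmarkSummary(
        n_targets=n,
        n_success=len(succ),
        success_rate=len(succ) / n,
        avg_length=float(statistics.fmean(lengths)),
        avg_cost=float(statistics.fmean(costs)),
        min_avg_length=float(statistics.fmean(min_lengths)),
        min_avg_cost=float(statistics.fmean(min_costs)),
        avg_model_calls=float(statistics.fmean(r.model_calls for r in results)),
        mean_first_solution_time=(float(statistics.fmean(fst)) if fst else None),
        penalty_length=penalty_length,
        penalty_cost=penalty_cost,
    )


def write_benchmark_csv(results: Sequence[TargetResult], path) -> None:
    """Per-target rows as CSV (aggregates are recomputable from these)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["target", "success", "length", "cost", "model_calls",
                    "wall_time", "first_solution_time"])
        for r in results:
            w.writerow([r.target, int(r.success),
                        "" if r.length is None else r.length,
                        "" if r.cost is None else f"{r.cost:.6f}",
                        r.model_calls, f"{r.wall_time:.4f}",
                        "" if r.first_solution_time is None
                        else f"{r.first_solution_time:.4f}"])
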