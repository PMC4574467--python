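"""The penalized softwired network criterion.

For a network N with display trees tau(N) and characters C = (C_1..C_k):

* softwired score  S(N,C) = sum_i min_{T in tau(N)} cost_i(T) — each
  character follows its cheapest display tree;
* tree cost        min_{T} sum_i cost_i(T), attained by tau_min with
  cluster (edge) set E_min;
* penalty          P(N,C) = sum_i c_i * |E_i \\ E_min| / (2 * (2n - 2))
  when every network edge is "used", and infinity otherwise, where E_i is
  the edge set of a display tree attaining character i's minimum c_i and n
  is the leaf count.  The 1/2 factor is the metric lower bound on the
  gain an extra edge can legitimately deliver (substitution must cost no
  more than deletion plus reinsertion); T_cost/(2n-2) is the expected
  per-edge cost on a binary tree.  A network edge is *unused* when no
  minimal-cost display tree of any character keeps it; superfluous edges
  make the penalty infinite, otherwise the trivial winner would be the
  network displaying every tree.
* network cost     S(N,C) + P(N,C), comparable with the plain tree cost:
  the verdict is "network" iff the network cost is strictly smaller,
  "tree" iff strictly larger, "tie" on exact equality.

For a tree (no network edges) the penalty is 0 and softwired, tree, and
network costs coincide, so trees and networks compete on one scale.

Edge identity across display trees is by leaf cluster: contraction destroys
vertex correspondence, and the cluster below an edge's head is the only
label-free currency in which edge sets of different trees can be compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix, CostMatrix, FormatError
from .network import (
    DEFAULT_RETICULATION_CAP,
    DisplayTree,
    Network,
    enumerate_display_trees,
    validate,
)
from .parsimony import hardwired_score, tree_score_vector

__all__ = [
    "ScoreReport",
    "softwired_score",
    "best_display_tree",
    "edge_difference",
    "network_penalty",
    "network_cost",
]


@dataclass(frozen=True)
class CharacterRow:
    index: int
    cost: float
    minimal_trees: tuple[int, ...]  # display-tree ids attaining the minimum


@dataclass(frozen=True)
class ScoreReport:
    """Everything the diagnosis computes, ready for serialization."""

    n_leaves: int
    n_reticulations: int
    n_characters: int
    tree_cost: float
    softwired: float
    penalty: float
    network: float
    verdict: str
    tau_min_id: int
    characters: tuple[CharacterRow, ...]
    display_trees: tuple[str, ...]  # newick per display-tree id
    edge_usage: dict[str, bool] = field(default_factory=dict)
    hardwired: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_leaves": self.n_leaves,
            "n_reticulations": self.n_reticulations,
            "n_characters": self.n_characters,
            "tree": self.tree_cost,
            "softwired": self.softwired,
            "penalty": self.penalty,
            "network": self.network,
            "hardwired": self.hardwired,
            "verdict": self.verdict,
            "tau_min": self.tau_min_id,
            "characters": [
                {
                    "index": r.index,
                    "cost": r.cost,
                    "minimal_trees": list(r.minimal_trees),
                }
                for r in self.characters
            ],
            "display_trees": list(self.display_trees),
            "edge_usage": dict(self.edge_usage),
        }


def _score_all(net, matrix, costs, cap):
    trees = enumerate_display_trees(net, dedupe=True, cap=cap)
    scores = np.vstack([tree_score_vector(t, matrix, costs) for t in trees])
    return trees, scores  # scores[t, i]


def softwired_score(
    net: Network,
    matrix: CharacterMatrix,
    costs: CostMatrix | None = None,
    cap: int = DEFAULT_RETICULATION_CAP,
):
    """Per-character minima over the display trees and their sum S(N,C).

    Returns ``(rows, S)`` where each row records the character's minimum
    cost and every display tree attaining it.
    """
    costs = costs if costs is not None else CostMatrix.unit()
    trees, scores = _score_all(net, matrix, costs, cap)
    rows = _character_rows(scores)
    return rows, float(scores.min(axis=0).sum())


def _character_rows(scores: np.ndarray) -> tuple[CharacterRow, ...]:
    mins = scores.min(axis=0)
    return tuple(
        CharacterRow(
            index=i,
            cost=float(mins[i]),
            minimal_trees=tuple(int(t) for t in np.flatnonzero(scores[:, i] == mins[i])),
        )
        for i in range(scores.shape[1])
    )


def edge_difference(tree_i: DisplayTree, tau_min: DisplayTree) -> int:
    """|E_i \\ E_min|: clusters of ``tree_i`` absent from ``tau_min``.

    Bounded by n - 2 since all n singleton clusters are always shared.
    """
    leaves_i = frozenset.union(*tree_i.clusters) if tree_i.clusters else frozenset()
    leaves_m = frozenset.union(*tau_min.clusters) if tau_min.clusters else frozenset()
    if leaves_i != leaves_m:
        raise FormatError("display trees have different leaf sets")
    return len(tree_i.clusters - tau_min.clusters)


def _penalty_for(
    tau_min_idx: int,
    trees: list[DisplayTree],
    rows: tuple[CharacterRow, ...],
    n_leaves: int,
    all_used: bool,
) -> float:
    if not all_used:
        return math.inf
    emin = trees[tau_min_idx].clusters
    numerator = 0.0
    for row in rows:
        if tau_min_idx in row.minimal_trees:
            continue  # character is minimal on tau_min itself: no extra edges
        d = min(len(trees[t].clusters - emin) for t in row.minimal_trees)
        numerator += row.cost * d
    return numerator / (2.0 * (2 * n_leaves - 2))


def _edge_usage(net: Network, trees, rows) -> dict[tuple[int, int], bool]:
    """A network edge is used iff some display tree that keeps it (under any
    of its resolutions) attains some character's minimum; ties count."""
    used: set[tuple[int, int]] = set()
    minimal_tree_ids = {t for row in rows for t in row.minimal_trees}
    for t in minimal_tree_ids:
        used |= trees[t].chosen_network_edges()
    return {e: (e in used) for e in net.network_edges()}


def _edge_label(net: Network, edge: tuple[int, int]) -> str:
    u, v = edge
    return "{%s}->{%s}" % (
        ",".join(sorted(net.cluster_below(u))),
        ",".join(sorted(net.cluster_below(v))),
    )


def best_display_tree(
    net: Network,
    matrix: CharacterMatrix,
    costs: CostMatrix | None = None,
    cap: int = DEFAULT_RETICULATION_CAP,
):
    """The overall most parsimonious display tree tau_min.

    Among trees tied for the minimum total, the one yielding the smallest
    penalty is chosen (the criterion presupposes *a* best tree; resolving
    ties adversarially would punish networks for ties trees never face).
    Returns ``(tau_min, tree_cost, tau_min_id)``.
    """
    costs = costs if costs is not None else CostMatrix.unit()
    trees, scores = _score_all(net, matrix, costs, cap)
    idx, _, _ = _choose_tau_min(net, trees, scores)
    return trees[idx], float(scores.sum(axis=1).min()), idx


def _choose_tau_min(net, trees, scores):
    rows = _character_rows(scores)
    totals = scores.sum(axis=1)
    tree_cost = totals.min()
    candidates = [int(t) for t in np.flatnonzero(totals == tree_cost)]
    usage = _edge_usage(net, trees, rows)
    all_used = all(usage.values())
    best_idx, best_pen = None, None
    for cand in candidates:
        pen = _penalty_for(cand, trees, rows, net.n_leaves, all_used)
        if best_pen is None or pen < best_pen:
            best_idx, best_pen = cand, pen
    return best_idx, best_pen, (rows, usage, float(tree_cost))


def network_penalty(
    net: Network,
    matrix: CharacterMatrix,
    costs: CostMatrix | None = None,
    cap: int = DEFAULT_RETICULATION_CAP,
) -> float:
    """P(N,C): the per-character extra-edge surcharge, or infinity if any
    network edge is unused.  Always 0 for a tree."""
    costs = costs if costs is not None else CostMatrix.unit()
    trees, scores = _score_all(net, matrix, costs, cap)
    _, pen, _ = _choose_tau_min(net, trees, scores)
    return pen


def network_cost(
    net: Network,
    matrix: CharacterMatrix,
    costs: CostMatrix | None = None,
    cap: int = DEFAULT_RETICULATION_CAP,
    compute_hardwired: bool = False,
    hardwired_cap: int | None = None,
    check: bool = True,
) -> ScoreReport:
    """Full diagnosis: S(N,C) + P(N,C) against the best display tree cost.

    ``verdict`` is "network" iff the penalized network cost is strictly
    below the tree cost, "tree" iff strictly above (including the infinite
    penalty case), "tie" on exact equality; a reticulation-free input is a
    tree by definition.
    """
    costs = costs if costs is not None else CostMatrix.unit()
    if check:
        validate(net).raise_if_invalid()
    trees, scores = _score_all(net, matrix, costs, cap)
    idx, penalty, (rows, usage, tree_cost) = _choose_tau_min(net, trees, scores)
    softwired = float(scores.min(axis=0).sum())
    r = net.n_reticulations
    if r == 0:
        penalty = 0.0
    net_cost = softwired + penalty
    if r == 0:
        verdict = "tree"
    elif net_cost < tree_cost:
        verdict = "network"
    elif net_cost > tree_cost:
        verdict = "tree"
    else:
        verdict = "tie"
    hw = None
    if compute_hardwired:
        hw = hardwired_score(
            net, matrix, costs, **({"cap": hardwired_cap} if hardwired_cap else {})
        ).total
    return ScoreReport(
        n_leaves=net.n_leaves,
        n_reticulations=r,
        n_characters=matrix.n_characters,
        tree_cost=tree_cost,
        softwired=softwired,
        penalty=penalty,
        network=net_cost,
        verdict=verdict,
        tau_min_id=idx,
        characters=rows,
        display_trees=tuple(t.to_newick() for t in trees),
        edge_usage={_edge_label(net, e): u for e, u in usage.items()},
        hardwired=hw,
    )
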