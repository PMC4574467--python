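"""Parsimony kernels on rooted binary trees and networks.

Four routes to a character's minimum number of changes:

* :func:`fitch_score` — the classic two-pass set method for unordered
  characters under unit costs;
* :func:`sankoff_score` — dynamic programming under an arbitrary symmetric
  metric step-cost matrix (equals Fitch exactly when costs are unit);
* :func:`exhaustive_tree_score` — brute force over every internal-vertex
  state assignment; the ground-truth oracle for the two above;
* :func:`hardwired_score` — the exact hardwired network score: every edge
  of the network (both incoming edges of each reticulation included) is
  charged, minimized over full vertex-state assignments.  This problem is
  NP-hard in general, so only an exact, capped solver is offered — no
  heuristic fallback.

Missing observations (``?``, and ``-`` under the default gap policy) are
scored as the full state set and contribute no forced cost; IUPAC codes are
state subsets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .matrix import CharacterMatrix, CostMatrix, FormatError
from .network import CapacityError, DisplayTree, Network

__all__ = [
    "CharacterScore",
    "fitch_score",
    "sankoff_score",
    "exhaustive_tree_score",
    "hardwired_score",
    "tree_score_vector",
]

DEFAULT_ENUMERATION_CAP = 2_000_000


@dataclass(frozen=True)
class CharacterScore:
    """Minimum cost of one character on one tree (or network)."""

    index: int
    cost: float
    root_states: frozenset[str] | None = None


def _state_space(matrix: CharacterMatrix, costs: CostMatrix | None):
    """Ordered state list and dense SxS cost array for the instance."""
    observed = set(matrix.alphabet)
    for sub in matrix.ambiguity.values():
        observed |= set(sub)
    if costs is None or costs.is_unit:
        states = sorted(observed)
        arr = np.ones((len(states), len(states)))
        np.fill_diagonal(arr, 0.0)
        return states, arr
    states = list(costs.states)
    extra = observed - set(states)
    if extra:
        raise FormatError(f"observed states {sorted(extra)} missing from cost matrix")
    arr = np.array([[costs.cost(a, b) for b in states] for a in states])
    return states, arr


def _leaf_sets(tree: DisplayTree, column: int, matrix: CharacterMatrix):
    labels = tree.leaf_labels
    missing = set(labels.values()) - set(matrix.taxa)
    if missing:
        raise FormatError(f"no data row for leaves {sorted(missing)}")
    return {v: matrix.state_set(column, lab) for v, lab in labels.items()}


def fitch_score(tree: DisplayTree, column: int, matrix: CharacterMatrix) -> CharacterScore:
    """Two-pass Fitch count (unit costs) on a rooted binary display tree.

    Postorder: a vertex's preliminary set is the intersection of its
    children's sets if nonempty, else their union at +1 change.  The root
    is treated like any internal vertex.
    """
    g = tree.graph
    leaf_sets = _leaf_sets(tree, column, matrix)
    cost = 0
    sets: dict[int, frozenset[str]] = {}
    for v in nx.dfs_postorder_nodes(g, tree.root):
        if g.out_degree(v) == 0:
            sets[v] = leaf_sets[v]
        else:
            a, b = (sets[c] for c in g.successors(v))
            inter = a & b
            if inter:
                sets[v] = inter
            else:
                sets[v] = a | b
                cost += 1
    return CharacterScore(column, float(cost), sets[tree.root])


def sankoff_score(
    tree: DisplayTree,
    column: int,
    matrix: CharacterMatrix,
    costs: CostMatrix,
) -> CharacterScore:
    """Sankoff dynamic program under a metric step-cost matrix.

    With unit costs this equals :func:`fitch_score` exactly.
    """
    g = tree.graph
    states, C = _state_space(matrix, costs)
    index = {s: i for i, s in enumerate(states)}
    leaf_sets = _leaf_sets(tree, column, matrix)
    vec: dict[int, np.ndarray] = {}
    for v in nx.dfs_postorder_nodes(g, tree.root):
        if g.out_degree(v) == 0:
            w = np.full(len(states), np.inf)
            for s in leaf_sets[v]:
                w[index[s]] = 0.0
            vec[v] = w
        else:
            w = np.zeros(len(states))
            for c in g.successors(v):
                w = w + np.min(C + vec[c][None, :], axis=1)
            vec[v] = w
    root_vec = vec[tree.root]
    best = float(root_vec.min())
    root_states = frozenset(states[i] for i in np.flatnonzero(root_vec == best))
    return CharacterScore(column, best, root_states)


def tree_score_vector(
    tree: DisplayTree,
    matrix: CharacterMatrix,
    costs: CostMatrix,
) -> np.ndarray:
    """Per-character minimum costs of all k characters on one tree."""
    if costs.is_unit:
        return np.array(
            [fitch_score(tree, j, matrix).cost for j in range(matrix.n_characters)]
        )
    return np.array(
        [sankoff_score(tree, j, matrix, costs).cost for j in range(matrix.n_characters)]
    )


def _brute_force_min(
    edges: list[tuple[int, int]],
    free_vertices: list[int],
    fixed_sets: dict[int, frozenset[str]],
    states: list[str],
    C: np.ndarray,
    cap: int,
) -> float:
    """Minimum summed edge cost over all state assignments of free_vertices;
    vertices with a fixed (possibly ambiguous) observation contribute the
    cheapest compatible state given their single parent."""
    S = len(states)
    m = len(free_vertices)
    if S**m > cap:
        raise CapacityError(
            f"{S}**{m} = {S**m} assignments exceed the enumeration cap {cap}"
        )
    index = {s: i for i, s in enumerate(states)}
    pos = {v: i for i, v in enumerate(free_vertices)}
    # columns of assignment matrix: one row per assignment
    grids = np.meshgrid(*([np.arange(S)] * m), indexing="ij") if m else []
    assign = (
        np.stack([gr.ravel() for gr in grids], axis=1)
        if m
        else np.zeros((1, 0), dtype=int)
    )
    total = np.zeros(assign.shape[0])
    for u, v in edges:
        if v in fixed_sets:
            allowed = [index[s] for s in fixed_sets[v]]
            leaf_cost = C[:, allowed].min(axis=1)  # cheapest compatible state
            total += leaf_cost[assign[:, pos[u]]]
        else:
            total += C[assign[:, pos[u]], assign[:, pos[v]]]
    return float(total.min())


def exhaustive_tree_score(
    tree: DisplayTree,
    column: int,
    matrix: CharacterMatrix,
    costs: CostMatrix,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> CharacterScore:
    """Brute-force minimum over all internal-vertex state assignments.

    Independent ground truth for :func:`fitch_score` / :func:`sankoff_score`;
    exponential in the internal vertex count, hence capped.
    """
    g = tree.graph
    states, C = _state_space(matrix, costs)
    internal = [v for v in g if g.out_degree(v) > 0]
    fixed = _leaf_sets(tree, column, matrix)
    best = _brute_force_min(list(g.edges), internal, fixed, states, C, cap)
    return CharacterScore(column, best)


@dataclass(frozen=True)
class HardwiredResult:
    total: float
    per_character: tuple[float, ...]


def hardwired_score(
    net: Network,
    matrix: CharacterMatrix,
    costs: CostMatrix | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> HardwiredResult:
    """Exact hardwired network score.

    Every edge of the network is charged the step cost between the states
    at its endpoints — both incoming edges of each reticulate vertex count
    independently — and the assignment of internal-vertex states is
    minimized per character.  The minimized totals can never fall below the
    best display tree's cost.

    Raises
    ------
    CapacityError
        When |states| ** (#internal vertices) exceeds ``cap``; the problem
        is NP-hard and only the exact solver is provided.
    """
    costs = costs if costs is not None else CostMatrix.unit()
    g = net.graph
    states, C = _state_space(matrix, costs)
    internal = [v for v in g if g.out_degree(v) > 0]
    labels = net.leaf_labels
    per_char = []
    for j in range(matrix.n_characters):
        fixed = {v: matrix.state_set(j, lab) for v, lab in labels.items()}
        per_char.append(
            _brute_force_min(list(g.edges), internal, fixed, states, C, cap)
        )
    return HardwiredResult(float(sum(per_char)), tuple(per_char))
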