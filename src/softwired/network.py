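"""Rooted phylogenetic networks and their display trees.

A network is a rooted DAG over taxa in which *network* (reticulate) vertices
have indegree 2 and outdegree 1, modelling hybridization or horizontal
transfer, while all other internal vertices are ordinary bifurcating tree
vertices.  The structural conventions enforced here are the usual ones for
explicit rooted networks:

* exactly one root (indegree 0, outdegree 2);
* leaves have indegree 1, outdegree 0; tree vertices indegree 1, outdegree 2;
  network vertices indegree 2, outdegree 1;
* no edge may join two network vertices;
* the two parents of a network vertex must be potentially contemporaneous:
  neither may be an ancestor of the other (time-consistency).

An edge is a *network edge* iff its head is a network vertex; all other
edges are *tree edges*.  Resolving every network vertex to a single parent
and contracting the resulting degree-2 vertices yields a *display tree*; a
network with ``r`` network vertices has at most ``2**r`` distinct ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Network",
    "DisplayTree",
    "ValidationResult",
    "Violation",
    "CapacityError",
    "validate",
    "enumerate_display_trees",
    "clusters_of",
    "is_ancestor",
]

DEFAULT_RETICULATION_CAP = 12


class CapacityError(RuntimeError):
    """An exact computation would exceed its configured size cap."""


class StructureError(ValueError):
    """Graph violates the structural constraints for rooted networks."""


class Network:
    """Rooted phylogenetic network backed by a :class:`networkx.DiGraph`.

    Vertices are opaque integer ids; leaves carry a ``label`` attribute.
    Branch lengths (``length`` edge attribute) and internal labels are
    retained when parsed but never used in parsimony scoring.
    """

    def __init__(self, graph: nx.DiGraph, root: int):
        self.graph = graph
        self.root = root

    # -- basic structure ---------------------------------------------------
    @property
    def leaves(self) -> list[int]:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    @property
    def leaf_labels(self) -> dict[int, str]:
        return {v: self.graph.nodes[v]["label"] for v in self.leaves}

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def network_nodes(self) -> list[int]:
        """Reticulate vertices (indegree >= 2), in a stable order."""
        return sorted(v for v in self.graph if self.graph.in_degree(v) >= 2)

    @property
    def n_reticulations(self) -> int:
        return len(self.network_nodes)

    def network_edges(self) -> list[tuple[int, int]]:
        """Edges whose head is a network vertex."""
        return [(u, v) for u, v in self.graph.edges if self.graph.in_degree(v) >= 2]

    def vertex_class(self, v: int) -> str:
        ind, outd = self.graph.in_degree(v), self.graph.out_degree(v)
        if ind == 0:
            return "root"
        if outd == 0:
            return "leaf"
        if ind >= 2:
            return "network"
        return "tree"

    def is_tree(self) -> bool:
        return self.n_reticulations == 0

    def copy(self) -> "Network":
        return Network(self.graph.copy(), self.root)

    def cluster_below(self, v: int) -> frozenset[str]:
        """Leaf labels reachable from ``v`` (the cluster of the edge into v)."""
        labels = self.leaf_labels
        return frozenset(
            labels[d] for d in nx.descendants(self.graph, v) | {v} if d in labels
        )


@dataclass(frozen=True)
class Violation:
    code: str  # degree | root | adjacency | time_consistency | cycle | label
    message: str


@dataclass(frozen=True)
class ValidationResult:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise StructureError(
                "; ".join(f"[{v.code}] {v.message}" for v in self.violations)
            )


def is_ancestor(net: Network, u: int, v: int) -> bool:
    """True iff a directed path of one or more edges runs from u to v."""
    if u == v:
        return False
    return nx.has_path(net.graph, u, v)


def validate(net: Network, time_consistency: str = "error") -> ValidationResult:
    """Check all structural constraints; violations are data, not exceptions.

    ``time_consistency`` may be ``"error"`` (default), ``"warn"`` (violations
    reported with code ``time_consistency_warning`` and do not fail
    validation), or ``"ignore"``.
    """
    g = net.graph
    out: list[Violation] = []

    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        out.append(Violation("cycle", f"graph contains a directed cycle through {cyc[0][0]}"))
        return ValidationResult(tuple(out))

    roots = [v for v in g if g.in_degree(v) == 0]
    if len(roots) != 1:
        out.append(Violation("root", f"expected exactly one root, found {len(roots)}: {sorted(roots)}"))
    elif roots[0] != net.root:
        out.append(Violation("root", f"designated root {net.root} has nonzero indegree"))

    labels = [g.nodes[v].get("label") for v in g if g.out_degree(v) == 0]
    if any(l is None for l in labels):
        out.append(Violation("label", "unlabelled leaf vertex"))
    elif len(labels) != len(set(labels)):
        out.append(Violation("label", "duplicate leaf labels"))

    for v in g:
        ind, outd = g.in_degree(v), g.out_degree(v)
        cls = net.vertex_class(v)
        expected = {
            "root": (0, 2),
            "leaf": (ind, 0),  # indegree checked below
            "tree": (1, 2),
            "network": (2, 1),
        }[cls]
        if cls == "leaf":
            if ind != 1:
                out.append(Violation("degree", f"leaf {v} has indegree {ind} (expected 1)"))
        elif (ind, outd) != expected:
            out.append(
                Violation(
                    "degree",
                    f"{cls} vertex {v} has (indegree, outdegree) = ({ind}, {outd}), "
                    f"expected {expected}",
                )
            )

    for u, v in g.edges:
        if g.in_degree(u) >= 2 and g.in_degree(v) >= 2:
            out.append(Violation("adjacency", f"edge ({u}, {v}) joins two network vertices"))

    if time_consistency != "ignore":
        code = "time_consistency" if time_consistency == "error" else "time_consistency_warning"
        for h in net.network_nodes:
            parents = list(g.predecessors(h))
            for a, b in itertools.permutations(parents, 2):
                if is_ancestor(net, a, b):
                    out.append(
                        Violation(
                            code,
                            f"parents {a} and {b} of network vertex {h} are "
                            f"ancestor and descendant",
                        )
                    )
                    break

    if time_consistency == "warn":
        out = [v for v in out if v.code != "time_consistency_warning"] + [
            v for v in out if v.code == "time_consistency_warning"
        ]
        hard = tuple(v for v in out if v.code != "time_consistency_warning")
        return ValidationResult(hard)
    return ValidationResult(tuple(out))


@dataclass(frozen=True)
class DisplayTree:
    """A rooted binary tree displayed by a network.

    ``resolutions`` records every combination of incoming-edge choices (one
    chosen parent per network vertex of the source network) that yields this
    topology; distinct resolutions can collapse to the same tree.
    ``clusters`` identifies each edge by the leaf set below its head — the
    only edge identity that survives contraction and is comparable across
    trees.
    """

    graph: nx.DiGraph = field(hash=False, compare=False)
    root: int = field(compare=False)
    clusters: frozenset[frozenset[str]] = field()
    resolutions: tuple[dict, ...] = field(hash=False, compare=False)

    @property
    def leaf_labels(self) -> dict[int, str]:
        return {
            v: self.graph.nodes[v]["label"]
            for v in self.graph
            if self.graph.out_degree(v) == 0
        }

    @property
    def n_leaves(self) -> int:
        return sum(1 for v in self.graph if self.graph.out_degree(v) == 0)

    def chosen_network_edges(self) -> set[tuple[int, int]]:
        """Network edges of the parent network kept by any of this tree's
        resolutions (edge = (chosen parent, network vertex))."""
        return {(p, h) for res in self.resolutions for h, p in res.items()}

    def to_newick(self) -> str:
        return _tree_newick(self.graph, self.root) + ";"


def _tree_newick(g: nx.DiGraph, v: int) -> str:
    if g.out_degree(v) == 0:
        return g.nodes[v]["label"]
    parts = sorted(_tree_newick(g, c) for c in g.successors(v))
    return "(" + ",".join(parts) + ")"


def clusters_of(graph: nx.DiGraph, root: int) -> frozenset[frozenset[str]]:
    """One cluster per edge of a rooted tree: the leaf set below the edge's
    head.  The root's full-leaf cluster is excluded; for a binary tree on n
    leaves this yields exactly 2n - 2 clusters."""
    memo: dict[int, frozenset[str]] = {}

    def below(v: int) -> frozenset[str]:
        if v not in memo:
            if graph.out_degree(v) == 0:
                memo[v] = frozenset({graph.nodes[v]["label"]})
            else:
                acc: frozenset[str] = frozenset()
                for c in graph.successors(v):
                    acc |= below(c)
                memo[v] = acc
        return memo[v]

    below(root)
    return frozenset(memo[v] for v in memo if v != root)


def _resolve(net: Network, choice: dict[int, int]) -> tuple[nx.DiGraph, int]:
    """Apply one incoming-edge choice per network vertex, drop vertices no
    longer reachable from the root, contract degree-2 vertices, and promote
    the root past any outdegree-1 chain."""
    g = net.graph.copy()
    for h, keep_parent in choice.items():
        for p in list(g.predecessors(h)):
            if p != keep_parent:
                g.remove_edge(p, h)
    reachable = nx.descendants(g, net.root) | {net.root}
    g.remove_nodes_from([v for v in list(g) if v not in reachable])

    # prune dead-end internal vertices (possible when both children of a
    # tree vertex are network vertices resolved toward their other parents)
    while True:
        dead = [
            v for v in g if g.out_degree(v) == 0 and "label" not in g.nodes[v]
        ]
        if not dead:
            break
        g.remove_nodes_from(dead)

    # splice out indegree-1/outdegree-1 vertices
    for v in list(g):
        if g.in_degree(v) == 1 and g.out_degree(v) == 1:
            (p,) = g.predecessors(v)
            (c,) = g.successors(v)
            g.add_edge(p, c)
            g.remove_node(v)

    root = net.root
    while g.out_degree(root) == 1:
        (c,) = g.successors(root)
        g.remove_node(root)
        root = c
    return g, root


def enumerate_display_trees(
    net: Network,
    dedupe: bool = True,
    cap: int = DEFAULT_RETICULATION_CAP,
) -> list[DisplayTree]:
    """All binary trees displayed by ``net``.

    Iterates the ``2**r`` resolutions (one incoming edge kept per network
    vertex).  With ``dedupe`` (default) trees with identical cluster sets are
    merged and carry all resolutions that produced them, so the result has
    at most ``2**r`` entries and often fewer.

    Raises
    ------
    CapacityError
        If ``r`` exceeds ``cap``: enumeration is exponential in the number
        of network vertices.
    """
    hybrids = net.network_nodes
    r = len(hybrids)
    if r > cap:
        raise CapacityError(
            f"network has {r} reticulations; enumerating 2**{r} display trees "
            f"exceeds the cap of {cap} (cost is exponential in the number of "
            f"network vertices)"
        )
    parent_lists = [sorted(net.graph.predecessors(h)) for h in hybrids]
    resolved: list[tuple[dict, nx.DiGraph, int, frozenset[frozenset[str]]]] = []
    for combo in itertools.product(*parent_lists):
        choice = dict(zip(hybrids, combo))
        g, root = _resolve(net, choice)
        resolved.append((choice, g, root, clusters_of(g, root)))
    if not dedupe:
        return [
            DisplayTree(graph=g, root=root, clusters=cl, resolutions=(choice,))
            for choice, g, root, cl in resolved
        ]
    grouped: dict[frozenset[frozenset[str]], list] = {}
    order: list[frozenset[frozenset[str]]] = []
    for choice, g, root, cl in resolved:
        if cl not in grouped:
            grouped[cl] = [g, root, []]
            order.append(cl)
        grouped[cl][2].append(choice)
    return [
        DisplayTree(
            graph=grouped[cl][0],
            root=grouped[cl][1],
            clusters=cl,
            resolutions=tuple(grouped[cl][2]),
        )
        for cl in order
    ]
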