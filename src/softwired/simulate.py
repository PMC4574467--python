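"""Synthetic sequence data: GTR+Gamma+I evolution on trees, multi-locus
scenarios, and network construction for end-to-end experiments.

The generator emulates a locus-level simulation design with three
scenarios:

* ``COM`` — every locus evolves on the same tree with the same branch
  lengths (one history, tree-like);
* ``SEP`` — one shared topology but locus-specific branch lengths (still
  tree-like);
* ``IND`` — each locus has its own topology and branch lengths
  (network-like: loci genuinely disagree).

Sequences evolve under a general time-reversible substitution model with
discrete-gamma rate variation and a proportion of invariant sites.  Branch
lengths are expected substitutions per *variable* site.  No indels are
simulated: columns stay homologous, which is what downstream scoring
consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .matrix import CharacterMatrix, FormatError
from .network import Network, StructureError, clusters_of, validate
from .io import parse_enewick

__all__ = [
    "SubstitutionModel",
    "GTR_GAMMA_I",
    "ScenarioSpec",
    "Locus",
    "build_rate_matrix",
    "discrete_gamma_rates",
    "simulate_locus",
    "simulate_scenario",
    "add_network_edge",
    "random_binary_tree",
    "random_network",
]

NUCLEOTIDES = ("A", "C", "G", "T")
_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")
MIN_BRANCH_LENGTH = 1e-12


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+Gamma+I parameters.

    ``exchangeabilities`` are the six symmetric rate multipliers for the
    unordered pairs AC, AG, AT, CG, CT, GT; ``base_freqs`` the stationary
    frequencies of A, C, G, T; ``gamma_shape`` the shape of the gamma rate
    distribution (discretized into ``n_rate_categories`` equal-probability
    categories by their means); ``invariant_prop`` the proportion of sites
    that never change.
    """

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_freqs: tuple[float, ...] = (0.25,) * 4
    gamma_shape: float = 1.0
    invariant_prop: float = 0.0
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or any(
            r <= 0 for r in self.exchangeabilities
        ):
            raise FormatError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if len(self.base_freqs) != 4 or abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise FormatError("base frequencies must be 4 values summing to 1")
        if self.gamma_shape <= 0:
            raise FormatError("gamma shape must be positive")
        if not 0.0 <= self.invariant_prop < 1.0:
            raise FormatError("invariant proportion must lie in [0, 1)")
        if self.n_rate_categories < 1:
            raise FormatError("need at least one rate category")


#: The GTR+Gamma+I parameter set used throughout the worked simulations.
GTR_GAMMA_I = SubstitutionModel(
    exchangeabilities=(1.5, 3.0, 0.9, 1.2, 2.5, 1.0),
    base_freqs=(0.20, 0.30, 0.30, 0.20),
    gamma_shape=1.0,
    invariant_prop=0.1,
)


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """4x4 GTR generator: Q_ij = s_ij * pi_j off-diagonal, rows sum to 0,
    scaled so the expected rate -sum_i pi_i Q_ii is one substitution per
    site per unit branch length (over variable sites)."""
    pi = np.asarray(model.base_freqs)
    s = np.zeros((4, 4))
    for (a, b), rate in zip(_PAIRS, model.exchangeabilities):
        i, j = NUCLEOTIDES.index(a), NUCLEOTIDES.index(b)
        s[i, j] = s[j, i] = rate
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean-one discrete gamma rates, one per equal-probability category,
    each the conditional mean of the gamma density over its quantile slab."""
    if n_categories == 1:
        return np.array([1.0])
    edges = np.linspace(0.0, 1.0, n_categories + 1)
    q = gamma_dist.ppf(edges, shape, scale=1.0 / shape)
    # E[X | a < X < b] for gamma(shape, 1/shape) via the shape+1 CDF
    upper_cdf = gamma_dist.cdf(q, shape + 1.0, scale=1.0 / shape)
    means = (upper_cdf[1:] - upper_cdf[:-1]) * n_categories
    return means / means.mean()


def _parse_sim_tree(tree: str | Network) -> Network:
    net = parse_enewick(tree) if isinstance(tree, str) else tree
    if net.n_reticulations:
        raise FormatError("simulation requires a tree, not a network")
    for u, v in net.graph.edges:
        ln = net.graph.edges[u, v].get("length")
        if ln is None:
            raise FormatError(f"missing branch length on edge into vertex {v}")
        if not np.isfinite(ln) or ln < 0:
            raise FormatError(f"invalid branch length {ln!r}")
    return net


def simulate_locus(
    tree: str | Network,
    model: SubstitutionModel,
    length: int,
    seed: int | np.random.Generator,
) -> CharacterMatrix:
    """Evolve one locus of aligned nucleotide columns down a tree.

    Root states are drawn from the stationary frequencies.  Each site is
    invariant with probability I, otherwise assigned a discrete-gamma rate
    category; states then evolve edge-wise under ``expm(Q * t * rate)``.
    Deterministic for a fixed seed.
    """
    if length < 1:
        raise FormatError("locus length must be >= 1")
    net = _parse_sim_tree(tree)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = build_rate_matrix(model)
    rates = discrete_gamma_rates(model.gamma_shape, model.n_rate_categories)
    pi = np.asarray(model.base_freqs)

    # per-site rate: 0 for invariant sites
    invariant = rng.random(length) < model.invariant_prop
    category = rng.integers(0, len(rates), size=length)
    site_rate = np.where(invariant, 0.0, rates[category])

    states: dict[int, np.ndarray] = {
        net.root: rng.choice(4, size=length, p=pi)
    }
    g = net.graph
    for v in nx.topological_sort(g):
        if v == net.root:
            continue
        (p,) = g.predecessors(v)
        t = max(g.edges[p, v]["length"], MIN_BRANCH_LENGTH)
        parent_states = states[p]
        child = parent_states.copy()
        for rate in np.unique(site_rate):
            if rate == 0.0:
                continue
            idx = np.flatnonzero(site_rate == rate)
            P = expm(q * t * rate)
            cum = P.cumsum(axis=1)
            u = rng.random(len(idx))
            child[idx] = (u[:, None] > cum[parent_states[idx], :]).sum(axis=1)
        states[v] = child

    letters = np.array(NUCLEOTIDES)
    seqs = {
        lab: "".join(letters[states[v]]) for v, lab in net.leaf_labels.items()
    }
    return CharacterMatrix.from_sequences(
        [(lab, seqs[lab]) for lab in sorted(seqs)]
    )


@dataclass(frozen=True)
class Locus:
    tree: str  # newick with branch lengths
    length: int


@dataclass(frozen=True)
class ScenarioSpec:
    """A multi-locus simulation design.

    Invariants by scenario: ``COM`` — all loci share one tree and one
    branch-length set; ``SEP`` — all loci share one topology but branch
    lengths differ between loci; ``IND`` — loci carry their own topologies.
    """

    scenario: str
    loci: tuple[Locus, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.scenario not in ("COM", "SEP", "IND"):
            raise FormatError(f"unknown scenario {self.scenario!r}")
        if not self.loci:
            raise FormatError("scenario needs at least one locus")
        nets = [_parse_sim_tree(l.tree) for l in self.loci]
        topologies = [frozenset(clusters_of(n.graph, n.root)) for n in nets]
        strings = [l.tree.strip() for l in self.loci]
        if self.scenario == "COM":
            if len(set(strings)) != 1:
                raise FormatError("COM requires one shared tree and branch-length set")
        elif self.scenario == "SEP":
            if len(set(topologies)) != 1:
                raise FormatError("SEP requires a single shared topology")
            if len(self.loci) > 1 and len(set(strings)) == 1:
                raise FormatError("SEP requires locus-specific branch lengths")
        else:  # IND
            if len(self.loci) > 1 and len(set(topologies)) == 1:
                raise FormatError("IND requires locus-specific topologies")

    @classmethod
    def com(cls, tree: str, n_loci: int, length: int, seed: int) -> "ScenarioSpec":
        return cls("COM", tuple(Locus(tree, length) for _ in range(n_loci)), seed)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as e:
            raise FormatError(f"bad scenario config: {e}") from None
        try:
            loci = tuple(Locus(l["tree"], int(l["length"])) for l in d["loci"])
            return cls(str(d["scenario"]).upper(), loci, int(d.get("seed", 0)))
        except (KeyError, TypeError) as e:
            raise FormatError(f"scenario config missing field: {e}") from None


def simulate_scenario(
    spec: ScenarioSpec, model: SubstitutionModel
) -> tuple[CharacterMatrix, list[tuple[int, int]]]:
    """Simulate all loci and concatenate their columns.

    Per-locus seeds are spawned deterministically from the spec seed, so
    loci are independent but the whole run is reproducible.  Returns the
    concatenated matrix and ``[start, stop)`` column bounds per locus.
    """
    children = np.random.SeedSequence(spec.seed).spawn(len(spec.loci))
    parts = [
        simulate_locus(l.tree, model, l.length, np.random.default_rng(ss))
        for l, ss in zip(spec.loci, children)
    ]
    taxa = parts[0].taxa
    for p in parts[1:]:
        if p.taxa != taxa:
            raise FormatError("loci have different taxon sets")
    seqs = {t: "".join(p.sequence(t) for p in parts) for t in taxa}
    bounds = []
    start = 0
    for l in spec.loci:
        bounds.append((start, start + l.length))
        start += l.length
    return CharacterMatrix.from_sequences([(t, seqs[t]) for t in taxa]), bounds


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def _find_edge(net: Network, cluster: frozenset[str]) -> tuple[int, int]:
    hits = [
        (u, v)
        for u, v in net.graph.edges
        if net.cluster_below(v) == frozenset(cluster)
    ]
    if not hits:
        raise FormatError(f"no edge with cluster {sorted(cluster)}")
    if len(hits) > 1:
        raise FormatError(f"cluster {sorted(cluster)} matches several edges")
    return hits[0]


def add_network_edge(
    tree: str | Network,
    source: frozenset[str] | set[str],
    target: frozenset[str] | set[str],
) -> Network:
    """Add one reticulation to a tree, yielding a network that displays it.

    ``source`` and ``target`` name tree edges by the leaf cluster below
    each edge's head.  The source edge is subdivided by a new tree vertex,
    the target edge by a new network vertex, and a network edge is run
    between them.  One resolution of the new network restores the input
    tree; the other regrafts the target clade onto the source edge.

    Raises
    ------
    StructureError
        If the result violates validation — in particular when the new
        edge would be time-inconsistent (one attachment ancestral to the
        other).
    """
    base = parse_enewick(tree) if isinstance(tree, str) else tree
    net = base.copy()
    g = net.graph
    if frozenset(source) == frozenset(target):
        raise FormatError("source and target edges must be distinct")
    su, sv = _find_edge(net, frozenset(source))
    tu, tv = _find_edge(net, frozenset(target))
    nid = max(g.nodes) + 1
    mid_s, mid_t = nid, nid + 1

    def subdivide(u, v, mid):
        length = g.edges[u, v].get("length")
        half = None if length is None else length / 2.0
        g.remove_edge(u, v)
        g.add_node(mid)
        g.add_edge(u, mid, length=half)
        g.add_edge(mid, v, length=half)

    subdivide(su, sv, mid_s)
    subdivide(tu, tv, mid_t)
    g.add_edge(mid_s, mid_t, length=0.0)
    result = validate(net)
    if not result.ok:
        raise StructureError(
            "adding edge {}->{} breaks network constraints: {}".format(
                sorted(source),
                sorted(target),
                "; ".join(f"[{v.code}] {v.message}" for v in result.violations),
            )
        )
    return net


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: Eight-taxon study trees: TREE_B is TREE_A with the (C,D) clade regrafted
#: next to (E,F).  Terminal branches 0.15, internal 0.08 expected
#: substitutions per variable site — typical interspecific nuclear-locus
#: depths.  BRIDGE_NETWORK displays exactly these two topologies.
TREE_A = (
    "((((A:0.15,B:0.15):0.08,(C:0.15,D:0.15):0.08):0.08,"
    "(E:0.15,F:0.15):0.08):0.08,(G:0.15,H:0.15):0.16);"
)
TREE_B = (
    "(((A:0.15,B:0.15):0.16,((C:0.15,D:0.15):0.08,"
    "(E:0.15,F:0.15):0.08):0.08):0.08,(G:0.15,H:0.15):0.16);"
)


def bridge_network() -> Network:
    """The 1-reticulation network displaying both study topologies: the
    (C,D) clade keeps its original parent and gains a second attachment on
    the edge above (E,F)."""
    return add_network_edge(TREE_A, frozenset("EF"), frozenset("CD"))


def scenario_spec(
    scenario: str, n_loci: int = 2, length: int = 500, seed: int = 0
) -> ScenarioSpec:
    """Ready-made COM / IND specs on the study trees (SEP: perturbed
    lengths on the shared topology)."""
    scenario = scenario.upper()
    if scenario == "COM":
        return ScenarioSpec.com(TREE_A, n_loci, length, seed)
    if scenario == "SEP":
        loci = []
        for i in range(n_loci):
            scale = 1.0 + 0.5 * (i % 2)  # alternate depth between loci
            tree = _rescale_lengths(TREE_A, scale)
            loci.append(Locus(tree, length))
        return ScenarioSpec("SEP", tuple(loci), seed)
    if scenario == "IND":
        trees = [TREE_A, TREE_B]
        loci = tuple(Locus(trees[i % 2], length) for i in range(n_loci))
        return ScenarioSpec("IND", loci, seed)
    raise FormatError(f"unknown scenario {scenario!r}")


def _rescale_lengths(newick: str, factor: float) -> str:
    net = parse_enewick(newick)
    for u, v in net.graph.edges:
        ln = net.graph.edges[u, v].get("length")
        if ln is not None:
            net.graph.edges[u, v]["length"] = ln * factor
    from .io import write_enewick

    return write_enewick(net)


# ---------------------------------------------------------------------------
# random fixtures
# ---------------------------------------------------------------------------


def random_binary_tree(
    labels: list[str],
    rng: np.random.Generator,
    branch_lengths: tuple[float, float] | None = None,
) -> Network:
    """Random rooted binary tree by sequential pair joining; optional
    uniform branch lengths from the given (low, high) range."""
    if len(labels) < 2:
        raise FormatError("need at least 2 leaves")
    g = nx.DiGraph()
    nodes = []
    for i, lab in enumerate(labels):
        g.add_node(i, label=lab)
        nodes.append(i)
    nid = len(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [x for x in nodes if x not in (a, b)]
        g.add_node(nid)
        g.add_edge(nid, a)
        g.add_edge(nid, b)
        nodes.append(nid)
        nid += 1
    net = Network(g, nodes[0])
    if branch_lengths is not None:
        lo, hi = branch_lengths
        for u, v in g.edges:
            g.edges[u, v]["length"] = float(rng.uniform(lo, hi))
    return net


def random_network(
    n_leaves: int,
    n_reticulations: int,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> Network:
    """Random valid network: a random tree plus random reticulations,
    rejection-sampled against the structural constraints."""
    labels = [f"t{i}" for i in range(n_leaves)]
    for _ in range(max_tries):
        net = random_binary_tree(labels, rng)
        ok = True
        for _ in range(n_reticulations):
            clusters = [net.cluster_below(v) for _, v in net.graph.edges]
            # exclude ambiguous duplicates (possible below reticulations)
            uniq = [c for c in clusters if clusters.count(c) == 1]
            added = False
            for _ in range(40):
                if len(uniq) < 2:
                    break
                i, j = rng.choice(len(uniq), size=2, replace=False)
                try:
                    net = add_network_edge(net, uniq[i], uniq[j])
                    added = True
                    break
                except (StructureError, FormatError):
                    continue
            if not added:
                ok = False
                break
        if ok and validate(net).ok:
            return net
    raise RuntimeError(
        f"could not build a valid network with {n_leaves} leaves and "
        f"{n_reticulations} reticulations"
    )
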