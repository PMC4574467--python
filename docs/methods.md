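# Methods

## The problem and the criterion

Rooted phylogenetic networks extend trees with *network* (reticulate)
vertices of indegree 2 and outdegree 1, each representing a lineage with
two ancestors (hybridization, horizontal transfer, reassortment). Under
the *softwired* reading, the two incoming edges of a network vertex are
alternatives: keeping exactly one per network vertex and contracting the
resulting degree-2 vertices yields a binary *display tree*, and a network
with `r` network vertices displays at most `2^r` of them.

Two parsimony scores bracket any network:

- the **softwired score** `S(N,C) = Σ_i min_{T∈τ(N)} cost_i(T)` lets each
  character follow its cheapest display tree, so it can only fall as edges
  are added — raw softwired parsimony is trivially optimized by ever more
  reticulate networks;
- the **hardwired score** `H(N,C) = Σ_i Σ_{e∈N} w_i(e)` charges every
  edge, including both incoming edges of each network vertex, so it can
  only exceed the best displayed tree.

Hence `S(N,C) ≤ min_T Σ_i cost_i(T) ≤ H(N,C)`, and neither endpoint
supports hypothesis testing between a tree and a network. The criterion
implemented here prices the softwired advantage:

```
network cost = S(N,C) + P(N,C)

P(N,C) = Σ_{i=1..k} c_i · |E_i \ E_min| / (2 · (2n − 2))   if all network edges are used
       = ∞                                                  otherwise
```

with `τ_min`/`E_min` the overall most parsimonious display tree and its
edge set, `τ_i`/`E_i`/`c_i` character *i*'s cheapest display tree, its
edge set and its cost, and `n` the number of leaves. The denominator is
the expected cost per edge of a binary tree (`2n − 2` edges) and the ½ is
the metric lower bound on the saving an extra edge may deliver: metricity
(triangle inequality) requires a substitution to cost no more than a
deletion plus a reinsertion, so at best an extra edge halves a
character's cost of appearing independently. A network edge kept by no
character's minimal display tree is *unused*; any unused edge makes
`P = ∞`, since otherwise the network displaying all trees would always
win. For a tree, `P = 0` and the network cost equals the plain tree cost,
so the two hypothesis classes are directly comparable. The verdict is
`network` iff `S + P <` tree cost, `tree` iff `>`, and reported as `tie`
on exact equality rather than silently resolved.

## Edge identity, tie-breaking, and the "used" rule

Contraction destroys vertex correspondence between display trees, so edge
sets of different trees are compared **by leaf cluster** (the set of
leaves below an edge's head); a binary rooted tree on `n` leaves has
exactly `2n − 2` such clusters (root cluster excluded). Three choices in
the formula are underdetermined and are resolved as follows:

- **`τ_min` ties**: among display trees tied for the minimum total, the
  one minimizing the resulting penalty is chosen. The criterion
  presupposes *a* best display tree; breaking ties adversarially would
  punish networks for ties that trees never face.
- **`τ_i` ties**: among trees attaining `c_i`, the one minimizing
  `|E_i \ E_min|` is used (0 whenever `τ_min` itself is minimal for
  character *i*), so the penalty charges only for edges a character
  actually needs.
- **"Used"** is evaluated for network edges only: network edge `e` is
  used iff some display tree whose resolution keeps `e` attains `c_i` for
  at least one character, ties counting as use. Every tree edge trivially
  survives as a cluster in some display tree; the infinite penalty is
  aimed at superfluous *reticulations*.

`n` in the denominator is the leaf count (the `2n − 2` of a binary tree's
edge count), not the network-vertex count.

## Algorithms and numerical choices

- **Structural validation** enforces: single root (indegree 0,
  outdegree 2), leaves 1/0, tree vertices 1/2, network vertices 2/1, no
  edge joining two network vertices, acyclicity, and time-consistency (no
  network vertex whose parents are ancestor and descendant). Violations
  are returned as data, each naming the offending vertex or edge;
  time-consistency can be downgraded to a warning because real eNewick
  files sometimes violate it. Polytomies are rejected, not auto-resolved.
- **Display-tree enumeration** iterates all `2^r` resolutions, deletes
  vertices unreachable from the root, prunes dead-end internal vertices
  (possible when both children of a tree vertex are reticulations
  resolved away), splices degree-2 vertices, and promotes an
  outdegree-1 root. Trees with identical cluster sets are merged, keeping
  every resolution that produced them (needed for the "used" rule). The
  default cap is `r ≤ 12` (4096 resolutions): enumeration is exponential
  in `r`, and diagnosis should stay interactive.
- **Character scoring**: two-pass Fitch for unit costs (the default);
  Sankoff dynamic programming for arbitrary symmetric metric step
  matrices (validated for symmetry, zero diagonal, triangle inequality on
  load). Missing symbols (`?`, and `-` under the default gap policy)
  score as the full observed alphabet; IUPAC codes as state subsets when
  the data are nucleotide-like. With unit costs the two kernels agree
  exactly; both are checked against a vectorized brute-force enumeration
  of all internal-vertex assignments.
- **Hardwired score**: exact minimization over full vertex-state
  assignments only (the problem is NP-hard for >2 states); instances
  beyond the enumeration cap raise a capacity error rather than fall back
  to a heuristic that would silently change semantics.
- **Gap policy**: columns are fixed aligned characters. `-` is missing by
  default; `gap_policy="state"` makes it an ordinary symbol,
  approximating a one-step-indel cost regime without modelling indels.
- Branch lengths and internal labels are parsed and retained but never
  used in scoring — all scores are step counts.
- Scores are floats (real-valued cost matrices are allowed); unit-cost
  scores are exact small integers, and verdict comparisons are exact.

## The synthetic-data generator

`simulate_locus` evolves aligned nucleotide columns down a tree under
GTR+Γ+I: root states from the stationary frequencies, per-site rates
either 0 (invariant, probability `I`) or one of 4 equal-probability
discrete-gamma categories (mean-of-quantile-slab discretization,
normalized to mean 1), and edge-wise evolution by `expm(Q·t·rate)`. The
generator matrix is scaled so branch lengths are expected substitutions
per **variable** site. Defaults are the parameter set used in all worked
experiments: exchangeabilities AC 1.5, AG 3.0, AT 0.9, CG 1.2, CT 2.5,
GT 1.0; base frequencies A 0.20, C 0.30, G 0.30, T 0.20; Γ shape 1;
invariant proportion 0.1.

Scenarios: **COM** (all loci on one tree with one branch-length set),
**SEP** (shared topology, per-locus lengths), **IND** (per-locus
topologies) — tree-like, tree-like, and network-like histories
respectively. Per-locus RNG streams are spawned deterministically from
the scenario seed.

The study fixture is a pair of 8-taxon trees differing by one
subtree-prune-regraft move (the (C,D) clade moves next to (E,F)), with
terminal branches 0.15 and internal branches 0.08 expected substitutions
per variable site — depths typical of interspecific nuclear loci — and
the 1-reticulation network bridging them, built by `add_network_edge`
(subdivide the source edge with a tree vertex, the target edge with a
network vertex, connect them; refuses edges that would violate
validation). Experiments use 2 loci × 500 sites and 10 replicates per
scenario; the acceptance script's other problem sizes (1,000 random
oracle instances at ≤ 6 leaves, 300 sandwich instances at ≤ 5 leaves
within the exact-hardwired cap, 50,000/20,000-site calibrations) are
chosen so the whole run completes in well under a minute of CPU.

What the generator does **not** emulate: indels (columns stay homologous
by construction — scoring consumes aligned columns, so an indel process
would only add a gap-handling confound), ambiguity codes, sequencing
error, codon structure, heterotachy, or within-locus recombination.
Passing the scenario tests therefore shows that the criterion responds to
genuine topological conflict between clean loci, not that it is robust to
alignment error or missing data in real matrices.

## Behaviour at column granularity (known limitation)

With every aligned column an independent character, the penalty is weak
and the infinite rule is hard to trigger on realistic data:

- any constant column attains its minimum (0) on *every* display tree, so
  under ties-count-as-use no network edge is ever unused once the data
  contain a constant column;
- a column strictly cheaper on a non-`τ_min` display tree saves at least
  1 step but contributes at most `c_i·|E_i\E_min| / (2(2n−2))` — for a
  single reticulation whose display trees differ by 2 clusters this is at
  most ≈ 0.5 step.

Consequently a 1-reticulation network diagnosed on column characters is
never beaten by the tree (the verdict is `network` or, with zero
conflicting columns, `tie`): homoplasy alone suffices to "pay for" the
edge. The criterion separates tree-like from network-like histories as
intended when characters are few and expensive (loci, gene partitions,
multi-state word characters) so that `c_i` is commensurate with whole-tree
costs. The acceptance suite documents this: loci simulated on conflicting
topologies are correctly diagnosed as `network`, while the
common-history scenario — expected to favor the tree at locus granularity
— still returns `network` at column granularity, and the corresponding
test records the gap rather than hiding it.

## Interfaces

Library: `NetworkParsimonyModel(characters, network, costs).fit()` returns
a `NetworkParsimonyResults` with component costs, per-character detail,
edge-usage table, `summary()`, and JSON/TSV export; the underlying
functions (`softwired_score`, `network_penalty`, `network_cost`,
`hardwired_score`, `enumerate_display_trees`, …) are public. CLI:
`softwired score|displays|validate|simulate` (exit codes: 2 input or
validation error, 3 capacity). Formats: aligned FASTA; plain Newick and
hybrid-tag eNewick (`#Hk`, `#LGTk`, `#k`; one tagged occurrence carries
the child subtree); step-cost TSV (header row/column of states); report
JSON/TSV with `∞` serialized as the string `"inf"`; scenario specs as
JSON (`{"scenario": "COM|SEP|IND", "seed": int, "loci": [{"tree":
newick, "length": int}, …]}`).
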