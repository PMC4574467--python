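# softwired

**Penalized softwired parsimony: compete rooted phylogenetic networks and
trees on one optimality scale.**

Incongruence between loci is the classic signal of reticulate evolution —
hybridization, horizontal gene transfer, viral reassortment — but it is
also exactly what plain homoplasy produces. Softwired networks cannot
settle the question on raw parsimony: because each character is free to
follow its cheapest *display tree*, a network's softwired score can only
go down as edges are added, so the most reticulate hypothesis always
"wins". `softwired` implements a cost adjustment that makes the comparison
fair, for systematists who want to ask: *does this candidate reticulation
actually pay for itself?*

## The criterion

For a rooted network `N` (network vertices of indegree 2/outdegree 1,
no two adjacent, parents potentially contemporaneous) with display trees
`τ(N)` and unordered characters `C = (C_1, …, C_k)`:

- **Softwired score** `S(N,C) = Σ_i min_{T ∈ τ(N)} cost_i(T)`
- **Tree cost** `min_{T ∈ τ(N)} Σ_i cost_i(T)`, attained by `τ_min` with
  edge (cluster) set `E_min`
- **Penalty**

  ```
  P(N,C) = Σ_i c_i · |E_i \ E_min| / (2 · (2n − 2))   if every network edge is "used"
         = ∞                                           otherwise
  ```

  where `c_i` and `E_i` are character *i*'s minimum cost and the edge set
  of a display tree attaining it, and `n` is the leaf count. `T/(2n−2)` is
  the expected per-edge cost on a binary tree, and the factor ½ is the
  metric lower bound on what an extra edge may legitimately save
  (substitution can cost at most deletion + reinsertion). An edge *used by
  no character's* minimal display tree makes the penalty infinite —
  otherwise the network displaying every tree would be unbeatable.
- **Network cost** `S(N,C) + P(N,C)`; the verdict is **network** iff this
  is strictly below the tree cost.

Trees have penalty 0 and `S = tree cost`, so trees and networks compete
directly. Character costs come from Fitch (unit) or Sankoff (arbitrary
symmetric metric step matrix) optimization on each display tree; an exact
(capped) hardwired score `H(N,C)` — every network edge charged — is also
available, with the guaranteed ordering `S(N,C) ≤ tree cost ≤ H(N,C)`.

## Worked example

The 4-taxon network `((A,(B)#H1),((#H1,C),D));` (eNewick hybrid-tag
dialect) displays `((A,B),(C,D))` and `(A,((B,C),D))`. Score it against
three binary characters, two splitting AB|CD and one splitting AD|BC:

```python
from softwired import NetworkParsimonyModel

fasta = ">A\n000\n>B\n001\n>C\n111\n>D\n110\n"
res = NetworkParsimonyModel.from_strings(fasta, "((A,(B)#H1),((#H1,C),D));").fit()
print(res.summary())
```

```
            Penalized Softwired Parsimony Results
==============================================================
Leaves:             4           Characters:         3
Reticulations:      1           Display trees:      2
--------------------------------------------------------------
Tree cost:          4           Softwired S(N,C):   3
Penalty P(N,C):     0.166667    Network cost:       3.16667
Verdict:            network
--------------------------------------------------------------
Best display tree: ((A,B),(C,D));
==============================================================
```

The best single tree explains the data in 4 steps; letting the conflicting
character follow the alternative display tree saves one step (softwired 3)
at a penalty of `1·2 / (2·(2·4−2)) = 1/6`, so the network wins,
`3.167 < 4`. Drop the conflicting character and the second reticulation
edge is used by nothing: the penalty becomes `∞` and the verdict flips to
`tree`.

The same workflow is available from the shell:

```bash
softwired score --fasta toy.fas --graph toy.enewick --format json
softwired displays --graph toy.enewick
softwired validate --graph toy.enewick
softwired simulate --scenario com --tree tree.nwk --loci 2 --length 500 --seed 42
```

`simulate` evolves aligned loci under GTR+Γ+I (defaults: exchangeabilities
1.5/3.0/0.9/1.2/2.5/1.0 for AC/AG/AT/CG/CT/GT, base frequencies
0.20/0.30/0.30/0.20, Γ shape 1, 10 % invariant sites) under COM (one shared
history), SEP (shared topology, per-locus branch lengths) or IND
(per-locus topologies) designs.

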