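"""Readers and writers: FASTA character matrices, (extended) Newick
networks, step-cost TSVs, and machine-readable score reports.

The eNewick dialect accepted is the hybrid-tag one: a network vertex is
written as several ``#Hk``-tagged occurrences (``#LGTk`` and bare ``#k``
are also accepted), exactly one of which carries the vertex's child
subtree.  ``parse_enewick`` merges the occurrences into a single network
vertex; plain Newick parses to a network with zero network vertices.
"""

from __future__ import annotations

import io as _io
import json
import math
from typing import Mapping

import networkx as nx
from Bio import SeqIO

from .matrix import (
    DEFAULT_MISSING,
    IUPAC_AMBIGUITY,
    CharacterMatrix,
    CostMatrix,
    FormatError,
)
from .network import Network

__all__ = [
    "parse_fasta",
    "write_fasta",
    "parse_enewick",
    "write_enewick",
    "read_cost_matrix",
    "write_report",
    "FormatError",
]

_NUCLEOTIDES = frozenset("ACGTU")


def parse_fasta(
    text: str,
    gap_policy: str = "missing",
    iupac: str | bool = "auto",
) -> CharacterMatrix:
    """Read an aligned FASTA into a CharacterMatrix, one character per column.

    Parameters
    ----------
    gap_policy
        ``"missing"`` (default): ``-`` joins ``?`` as a missing symbol,
        scored as the full state set.  ``"state"``: ``-`` is an ordinary
        alphabet symbol, approximating a regime where indels cost one step
        like substitutions.
    iupac
        ``"auto"`` applies IUPAC ambiguity codes as state subsets when the
        data are nucleotide-like; ``True``/``False`` force the choice.
    """
    if gap_policy not in ("missing", "state"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
    if not records:
        raise FormatError("empty or non-FASTA input")
    seen: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate taxon label {rec.id!r}")
        seen.add(rec.id)
        pairs.append((rec.id, str(rec.seq).upper()))
    missing = DEFAULT_MISSING if gap_policy == "missing" else frozenset({"?"})
    symbols = {s for _, seq in pairs for s in seq} - missing
    if iupac == "auto":
        use_iupac = bool(symbols & _NUCLEOTIDES) and symbols <= (
            _NUCLEOTIDES | set(IUPAC_AMBIGUITY)
        )
    else:
        use_iupac = bool(iupac)
    ambiguity = IUPAC_AMBIGUITY if use_iupac else {}
    return CharacterMatrix.from_sequences(pairs, missing, ambiguity)


def write_fasta(matrix: CharacterMatrix, width: int = 70) -> str:
    lines = []
    for t in matrix.taxa:
        lines.append(f">{t}")
        seq = matrix.sequence(t)
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# eNewick
# ---------------------------------------------------------------------------

_LABEL_END = set(",();")


def _parse_label(s: str, i: int) -> tuple[str | None, str | None, float | None, int]:
    j = i
    while j < len(s) and s[j] not in _LABEL_END and s[j] != ":":
        j += 1
    raw = s[i:j].strip()
    length = None
    if j < len(s) and s[j] == ":":
        j += 1
        k = j
        while k < len(s) and s[k] not in _LABEL_END and s[k] != ":":
            k += 1
        try:
            length = float(s[j:k])
        except ValueError:
            raise FormatError(f"bad branch length {s[j:k]!r} at position {j}") from None
        j = k
    name = tag = None
    if "#" in raw:
        name_part, _, tag_part = raw.partition("#")
        name = name_part or None
        tag = tag_part
        if not tag:
            raise FormatError(f"empty hybrid tag in label {raw!r}")
    elif raw:
        name = raw
    return name, tag, length, j


def parse_enewick(text: str) -> Network:
    """Parse one rooted (e)Newick statement into a :class:`Network`.

    Branch lengths and internal labels are stored on the graph but ignored
    by all scoring.  Structural constraint checking is deferred to
    :func:`softwired.network.validate`; this raises only on syntax errors
    (unbalanced parentheses, missing ``;``, a hybrid tag appearing once, or
    a tag carrying a subtree at more than one occurrence).
    """
    s = text.strip()
    if not s:
        raise FormatError("empty Newick input")
    if not s.endswith(";"):
        raise FormatError("Newick statement must end with ';'")
    s = s[:-1]
    if ";" in s:
        raise FormatError("expected a single Newick statement")

    g = nx.DiGraph()
    counter = [0]

    def new_node() -> int:
        counter[0] += 1
        return counter[0]

    def subtree(i: int) -> tuple[int, int]:
        if i >= len(s):
            raise FormatError("unexpected end of input (unbalanced parentheses?)")
        if s[i] == "(":
            children = []
            i += 1
            while True:
                i, c = subtree(i)
                children.append(c)
                if i >= len(s):
                    raise FormatError("unbalanced parentheses: missing ')'")
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                raise FormatError(f"unexpected character {s[i]!r} at position {i}")
            name, tag, length, i = _parse_label(s, i)
            v = new_node()
            g.add_node(v, name=name, tag=tag)
            for c in children:
                g.add_edge(v, c, length=g.nodes[c].pop("_length", None))
            g.nodes[v]["_length"] = length
            return i, v
        name, tag, length, i = _parse_label(s, i)
        if name is None and tag is None:
            raise FormatError(f"empty node label at position {i}")
        v = new_node()
        g.add_node(v, name=name, tag=tag, _length=length)
        return i, v

    i, root = subtree(0)
    if i != len(s):
        raise FormatError(
            f"trailing characters after Newick statement at position {i}: {s[i:]!r}"
        )
    g.nodes[root].pop("_length", None)

    # merge hybrid-tagged occurrences
    by_tag: dict[str, list[int]] = {}
    for v, data in g.nodes(data=True):
        if data.get("tag") is not None:
            by_tag.setdefault(data["tag"], []).append(v)
    for tag, occ in by_tag.items():
        if len(occ) < 2:
            raise FormatError(
                f"hybrid tag #{tag} appears only once; a network vertex needs "
                f"at least two attachment points"
            )
        with_child = [v for v in occ if g.out_degree(v) > 0]
        if len(with_child) > 1:
            raise FormatError(f"hybrid tag #{tag} carries a subtree at {len(with_child)} occurrences")
        if not with_child:
            raise FormatError(f"hybrid tag #{tag} has no occurrence with a child subtree")
        keep = with_child[0]
        for v in occ:
            if v == keep:
                continue
            for p in list(g.predecessors(v)):
                g.add_edge(p, keep, length=g.edges[p, v].get("length"))
            g.remove_node(v)

    # finalize node attributes: leaves get 'label'
    for v in list(g):
        data = g.nodes[v]
        name = data.pop("name", None)
        data.pop("tag", None)
        data.pop("_length", None)
        if g.out_degree(v) == 0:
            if name is None:
                raise FormatError("unlabelled leaf in Newick input")
            data["label"] = name
        elif name is not None:
            data["internal_label"] = name
    return Network(g, root)


def write_enewick(net: Network) -> str:
    """Serialize a network to eNewick; a tree yields plain Newick.

    Round-trip contract: re-parsing the output gives a network isomorphic
    to the input (same leaf labels, same display-tree cluster sets, same
    hybrid attachments)."""
    g = net.graph
    tags = {h: f"H{i + 1}" for i, h in enumerate(net.network_nodes)}
    sort_key: dict[int, str] = {
        v: ",".join(sorted(net.cluster_below(v))) for v in g
    }
    written: set[int] = set()

    def rec(v: int, length) -> str:
        suffix = "" if length is None else f":{length:g}"
        if v in tags:
            if v in written:
                return f"#{tags[v]}{suffix}"
            written.add(v)
            (child,) = g.successors(v)
            inner = rec(child, g.edges[v, child].get("length"))
            return f"({inner})#{tags[v]}{suffix}"
        if g.out_degree(v) == 0:
            return g.nodes[v]["label"] + suffix
        parts = [
            rec(c, g.edges[v, c].get("length"))
            for c in sorted(g.successors(v), key=lambda c: sort_key[c])
        ]
        return "(" + ",".join(parts) + ")" + suffix

    return rec(net.root, None) + ";"


# ---------------------------------------------------------------------------
# cost matrix TSV
# ---------------------------------------------------------------------------


def read_cost_matrix(text: str) -> CostMatrix:
    """Read a symmetric step-cost matrix from TSV.

    Layout: a header row of state symbols (first cell empty or a caption),
    then one row per state with its label in the first column."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError("cost matrix needs a header row and one row per state")
    header = lines[0].split("\t")
    states = [c.strip() for c in header[1:] if c.strip()]
    if not states:
        raise FormatError("cost matrix header lists no states")
    costs: dict[tuple[str, str], float] = {}
    rows_seen = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        row_state = cells[0].strip()
        rows_seen.append(row_state)
        vals = [c.strip() for c in cells[1:]]
        if len(vals) != len(states):
            raise FormatError(
                f"cost row {row_state!r} has {len(vals)} cells, expected {len(states)}"
            )
        for col_state, cell in zip(states, vals):
            try:
                costs[(row_state, col_state)] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric cost {cell!r} at ({row_state}, {col_state})"
                ) from None
    if sorted(rows_seen) != sorted(states):
        raise FormatError("cost matrix row labels do not match header states")
    return CostMatrix(states, costs)


def write_cost_matrix(costs: CostMatrix) -> str:
    states = costs.states
    lines = ["\t" + "\t".join(states)]
    for a in states:
        lines.append(a + "\t" + "\t".join(f"{costs.cost(a, b):g}" for b in states))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# score reports
# ---------------------------------------------------------------------------


def _jsonable(x):
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    if isinstance(x, Mapping):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_report(report, fmt: str = "json") -> str:
    """Serialize a ScoreReport; infinity is written as the string ``"inf"``."""
    d = _jsonable(report.to_dict())
    if fmt == "json":
        return json.dumps(d, indent=2) + "\n"
    if fmt == "tsv":
        lines = []
        for key in ("tree", "softwired", "hardwired", "penalty", "network", "verdict"):
            if key in d and d[key] is not None:
                lines.append(f"{key}\t{d[key]}")
        for row in d.get("characters", []):
            lines.append(
                "character\t{index}\t{cost}\t{minimal_trees}".format(
                    index=row["index"],
                    cost=row["cost"],
                    minimal_trees=",".join(str(t) for t in row["minimal_trees"]),
                )
            )
        for edge, used in d.get("edge_usage", {}).items():
            lines.append(f"network_edge\t{edge}\t{'used' if used else 'unused'}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")
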