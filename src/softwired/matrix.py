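"""Character and step-cost containers.

A :class:`CharacterMatrix` holds ``n`` taxa scored for ``k`` unordered
(non-additive) characters over a finite symbol alphabet; columns are treated
as independent characters, the usual static-homology view of an alignment.
A :class:`CostMatrix` holds symmetric metric step costs between states; the
default is the unit (Fitch) cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = ["CharacterMatrix", "CostMatrix", "DEFAULT_MISSING"]

DEFAULT_MISSING = frozenset({"?", "-"})

# IUPAC nucleotide ambiguity codes, read as state subsets.
IUPAC_AMBIGUITY = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class FormatError(ValueError):
    """Malformed input data (FASTA, Newick, cost matrix, config)."""


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters state matrix.

    Parameters
    ----------
    taxa
        Ordered, unique taxon labels (n >= 2).
    columns
        ``k`` columns; each maps every taxon to a one-symbol state.
    missing_symbols
        Symbols read as "state unknown" (the full state set in parsimony).
    """

    taxa: tuple[str, ...]
    columns: tuple[Mapping[str, str], ...]
    missing_symbols: frozenset[str] = DEFAULT_MISSING
    ambiguity: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            raise FormatError("duplicate taxon labels")
        if len(self.taxa) < 2:
            raise FormatError("need at least 2 taxa")
        if not self.columns:
            raise FormatError("need at least 1 character")
        for j, col in enumerate(self.columns):
            missing_taxa = set(self.taxa) - set(col)
            if missing_taxa:
                raise FormatError(
                    f"character {j}: no state for taxa {sorted(missing_taxa)}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.columns)

    @property
    def alphabet(self) -> frozenset[str]:
        """Observed state symbols, excluding missing and ambiguity codes."""
        cached = self.__dict__.get("_alphabet")
        if cached is None:
            out: set[str] = set()
            for col in self.columns:
                for s in col.values():
                    if s not in self.missing_symbols and s not in self.ambiguity:
                        out.add(s)
            cached = frozenset(out)
            object.__setattr__(self, "_alphabet", cached)
        return cached

    def state_set(self, column: int, taxon: str) -> frozenset[str]:
        """States compatible with the observation, for parsimony kernels.

        Missing symbols expand to the full observed alphabet; ambiguity
        codes expand to their subset.
        """
        s = self.columns[column][taxon]
        if s in self.missing_symbols:
            return self.alphabet
        if s in self.ambiguity:
            return self.ambiguity[s] & self.alphabet or self.ambiguity[s]
        return frozenset({s})

    def sequence(self, taxon: str) -> str:
        return "".join(col[taxon] for col in self.columns)

    def subset_columns(self, indices: Iterable[int]) -> "CharacterMatrix":
        cols = tuple(self.columns[i] for i in indices)
        return CharacterMatrix(self.taxa, cols, self.missing_symbols, self.ambiguity)

    @classmethod
    def from_sequences(
        cls,
        sequences: Mapping[str, str] | Sequence[tuple[str, str]],
        missing_symbols: Iterable[str] = DEFAULT_MISSING,
        ambiguity: Mapping[str, frozenset[str]] | None = None,
    ) -> "CharacterMatrix":
        """Build from equal-length aligned sequences, one column per site."""
        items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
        if not items:
            raise FormatError("empty alignment")
        taxa = tuple(t for t, _ in items)
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            ref = len(items[0][1])
            bad = next(t for t, s in items if len(s) != ref)
            raise FormatError(
                f"unequal sequence lengths: taxon {bad!r} differs from {items[0][0]!r}"
            )
        k = lengths.pop()
        if k == 0:
            raise FormatError("zero-length alignment")
        columns = tuple({t: s[j] for t, s in items} for j in range(k))
        return cls(taxa, columns, frozenset(missing_symbols), ambiguity or {})


class CostMatrix:
    """Symmetric metric step-cost matrix between character states.

    ``cost(a, a) == 0``, ``cost(a, b) == cost(b, a)``, and the triangle
    inequality are validated at construction. States absent from the matrix
    fall back to unit cost only when the matrix was built as ``unit()``.
    """

    def __init__(self, states: Sequence[str], costs: Mapping[tuple[str, str], float]):
        self.states = tuple(states)
        self._cost = dict(costs)
        self._validate()

    @classmethod
    def unit(cls, states: Iterable[str] = ()) -> "CostMatrix":
        m = cls.__new__(cls)
        m.states = tuple(states)
        m._cost = None  # sentinel: unit cost for every pair
        return m

    @property
    def is_unit(self) -> bool:
        return self._cost is None

    def cost(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        if self._cost is None:
            return 1.0
        try:
            return self._cost[(a, b)]
        except KeyError:
            raise FormatError(f"no step cost defined for states {a!r}, {b!r}") from None

    def restricted_to(self, states: Iterable[str]) -> "CostMatrix":
        if self.is_unit:
            return CostMatrix.unit(states)
        missing = set(states) - set(self.states)
        if missing:
            raise FormatError(f"states {sorted(missing)} not in cost matrix")
        return self

    def _validate(self) -> None:
        for a in self.states:
            if self._cost.get((a, a), 0.0) != 0.0:
                raise FormatError(f"cost({a},{a}) must be 0")
            self._cost[(a, a)] = 0.0
        for a in self.states:
            for b in self.states:
                if a == b:
                    continue
                ab = self._cost.get((a, b))
                ba = self._cost.get((b, a))
                if ab is None or ba is None:
                    raise FormatError(f"missing cost entry for ({a},{b})")
                if ab != ba:
                    raise FormatError(f"asymmetric costs for ({a},{b}): {ab} != {ba}")
                if ab < 0:
                    raise FormatError(f"negative cost for ({a},{b})")
                if ab == 0:
                    raise FormatError(f"zero cost between distinct states ({a},{b})")
        for a in self.states:
            for b in self.states:
                for c in self.states:
                    if self.cost(a, c) > self.cost(a, b) + self.cost(b, c) + 1e-12:
                        raise FormatError(
                            f"triangle inequality violated: "
                            f"cost({a},{c}) > cost({a},{b}) + cost({b},{c})"
                        )
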