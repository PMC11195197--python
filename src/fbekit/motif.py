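"""Degenerate FBE consensus patterns and exact matching over RNA sequences.

FBF (a *C. elegans* PUF protein) recognizes short single-stranded RNA
elements.  Four element classes are modeled, written in a degenerate
alphabet where R = A/G (purine), Y = C/U (pyrimidine) and n = any base:

========  ============  ======  =========================================
name      consensus     length  description
========  ============  ======  =========================================
FBE9      UGURnnAUn     9       canonical 9-nt FBF binding element
CFBE8     UGURnAUn      8       compact 8-nt variant (cFBE)
ASTAR9    UGUYRnAUn     9       FBEa*-like element, 9-nt form
ASTAR10   UGUnRnnAUn    10      FBEa*-like element, 10-nt form
========  ============  ======  =========================================

Matching is exact (no mismatch tolerance, no PWM scoring), single strand,
in the given 5'->3' orientation.  Coordinates are 0-based half-open
internally; user-facing writers convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

RNA_BASES = "ACGU"

#: Allowed base set for each degenerate consensus symbol.
SYMBOL_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "n": frozenset("ACGU"),
}

_INPUT_ALPHABET = set("ACGTUacgtuNn")


@dataclass(frozen=True)
class ConsensusPattern:
    """A degenerate RNA consensus over the symbols {A,C,G,U,R,Y,n}."""

    name: str
    symbols: str
    is_canonical: bool = False

    def __post_init__(self) -> None:
        bad = [s for s in self.symbols if s not in SYMBOL_SETS]
        if bad:
            raise ValueError(
                f"pattern {self.name!r}: invalid symbol(s) {bad!r}; "
                f"allowed: {sorted(SYMBOL_SETS)}"
            )
        if not self.symbols.startswith("UGU"):
            raise ValueError(
                f"pattern {self.name!r} must start with the UGU anchor, "
                f"got {self.symbols!r}"
            )

    @property
    def length(self) -> int:
        return len(self.symbols)


#: The four FBE element classes searched for under CLIP peaks.
FBE_PATTERNS: dict[str, ConsensusPattern] = {
    "FBE9": ConsensusPattern("FBE9", "UGURnnAUn", is_canonical=True),
    "CFBE8": ConsensusPattern("CFBE8", "UGURnAUn"),
    "ASTAR9": ConsensusPattern("ASTAR9", "UGUYRnAUn"),
    "ASTAR10": ConsensusPattern("ASTAR10", "UGUnRnnAUn"),
}


@dataclass(frozen=True)
class ElementMatch:
    """One occurrence of a consensus pattern in a sequence.

    ``start`` is a 0-based offset; the match occupies
    ``[start, start + length)``.
    """

    sequence_id: str
    pattern_name: str
    start: int
    length: int
    matched_text: str

    def __post_init__(self) -> None:
        if len(self.matched_text) != self.length:
            raise ValueError(
                f"matched_text length {len(self.matched_text)} != {self.length}"
            )

    @property
    def end(self) -> int:
        """0-based exclusive end offset."""
        return self.start + self.length


def normalize_sequence(raw: str) -> str:
    """Normalize a nucleotide string to the uppercase RNA alphabet.

    T is mapped to U so DNA-alphabet peak FASTA works unchanged; N is
    retained as an ambiguous base.  Any other character is rejected with
    its (1-based) position named.
    """
    for i, ch in enumerate(raw):
        if ch not in _INPUT_ALPHABET:
            raise ValueError(
                f"invalid nucleotide {ch!r} at position {i + 1}"
            )
    return raw.upper().replace("T", "U")


def symbol_matches(symbol: str, base: str, *, n_matches_ambiguous: bool = False) -> bool:
    """Whether a degenerate consensus symbol matches a concrete base.

    Literal symbols match only themselves, R matches A/G, Y matches C/U
    and n matches any of the four bases.  The ambiguous input base N never
    satisfies a literal or R/Y symbol; it satisfies n only when
    ``n_matches_ambiguous`` is set (off by default: the search is for
    exact matches, so ambiguity earns no credit).
    """
    try:
        allowed = SYMBOL_SETS[symbol]
    except KeyError:
        raise ValueError(f"invalid consensus symbol {symbol!r}") from None
    if base == "N":
        return n_matches_ambiguous and symbol == "n"
    return base in allowed


def match_positions(
    seq: str,
    pattern: ConsensusPattern,
    sequence_id: str = "",
    *,
    n_matches_ambiguous: bool = False,
) -> list[ElementMatch]:
    """All exact occurrences of ``pattern`` in ``seq``, ordered by start.

    ``seq`` must already be normalized (see :func:`normalize_sequence`).
    Overlapping occurrences are all reported; matches must be fully
    contained in the sequence.
    """
    m = pattern.length
    out: list[ElementMatch] = []
    for start in range(len(seq) - m + 1):
        window = seq[start : start + m]
        if all(
            symbol_matches(sym, base, n_matches_ambiguous=n_matches_ambiguous)
            for sym, base in zip(pattern.symbols, window)
        ):
            out.append(
                ElementMatch(sequence_id, pattern.name, start, m, window)
            )
    return out


def scan_all(
    seq: str,
    patterns: Iterable[ConsensusPattern] | None = None,
    sequence_id: str = "",
    *,
    n_matches_ambiguous: bool = False,
) -> list[ElementMatch]:
    """Union of :func:`match_positions` over all element classes.

    Matches at the same start with different pattern names are distinct
    records.  Output is ordered by (start, pattern name).
    """
    if patterns is None:
        patterns = FBE_PATTERNS.values()
    matches: list[ElementMatch] = []
    for pattern in patterns:
        matches.extend(
            match_positions(
                seq, pattern, sequence_id, n_matches_ambiguous=n_matches_ambiguous
            )
        )
    matches.sort(key=lambda m: (m.start, m.pattern_name))
    return matches
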