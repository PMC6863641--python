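"""IUPAC nucleotide-code algebra.

Degenerate DNA patterns and SNP-masked genome sequence both use the
IUPAC ambiguity alphabet: each one-letter code denotes a set of
concrete bases (R = A or G, Y = C or T, ..., N = any of the four).
This module is the small algebra everything else is built on:
expansion of a code to its base set, Watson-Crick complementation of
codes, reverse complementation of whole patterns, and the match
predicate between a genome symbol and a motif symbol.

Matching uses intersection semantics: a genome symbol matches a motif
symbol when their expansions share at least one concrete base.  The
one deliberate exception is the *genome* symbol ``N``: in SNP-masked
FASTA, ``N`` marks unsequenced assembly gaps, not a known
tetra-allelic SNP, so it matches nothing -- including the motif
wildcard ``n``.  Without this rule every gap region would light up
with spurious motif hits.

All comparisons are case-insensitive; sequences are uppercased on
read (UCSC FASTA uses lowercase for repeat masking, which is
irrelevant here).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import FormatError

__all__ = [
    "EXPANSION",
    "COMPLEMENT",
    "SNP_CODES",
    "MotifPattern",
    "expand",
    "complement",
    "reverse_complement",
    "matches",
    "is_snp_code",
]

#: Expansion of every legal IUPAC nucleotide code to its base set.
EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
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

#: Watson-Crick complement of every code (complement of the expansion
#: set, re-encoded as a single code).
COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

#: Codes that mark a SNP position in masked FASTA: every ambiguity
#: code except N (which marks an assembly gap) and the concrete bases.
SNP_CODES: frozenset[str] = frozenset("RYSWKMBDHV")

_LEGAL = frozenset(EXPANSION)


def _validate(symbol: str) -> str:
    """Uppercase and validate a single IUPAC symbol."""
    if not isinstance(symbol, str) or len(symbol) != 1:
        raise FormatError(f"expected a single IUPAC character, got {symbol!r}")
    up = symbol.upper()
    if up not in _LEGAL:
        raise FormatError(f"illegal IUPAC character {symbol!r}")
    return up


def expand(symbol: str) -> frozenset[str]:
    """Return the set of concrete bases a code stands for.

    >>> sorted(expand("R"))
    ['A', 'G']
    """
    return EXPANSION[_validate(symbol)]


def complement(symbol: str) -> str:
    """Watson-Crick complement of a (possibly degenerate) code.

    Satisfies expand(complement(x)) == {complement of b for b in expand(x)}.
    """
    return COMPLEMENT[_validate(symbol)]


def matches(genome_symbol: str, motif_symbol: str) -> bool:
    """Does a genome symbol satisfy a motif symbol at one position?

    True iff the expansions intersect, except that the genome symbol
    ``N`` (assembly gap) matches nothing.  Symmetric for non-N symbols.
    """
    g = _validate(genome_symbol)
    m = _validate(motif_symbol)
    if g == "N":
        return False
    return bool(EXPANSION[g] & EXPANSION[m])


def is_snp_code(symbol: str) -> bool:
    """True for the ten ambiguity codes that mark a SNP position
    (everything but A, C, G, T and N)."""
    return _validate(symbol) in SNP_CODES


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate DNA pattern written in IUPAC code.

    Parameters
    ----------
    sequence:
        The pattern, e.g. ``"RGNACA"`` for the GR half-site.  Stored
        uppercased; every symbol must be a legal IUPAC code.
    label:
        Free-text name carried through to reports.
    """

    sequence: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("motif pattern must have length >= 1")
        object.__setattr__(self, "sequence", "".join(_validate(c) for c in self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self):
        return iter(self.sequence)

    def concrete_strings(self):
        """Yield every concrete ACGT string the pattern denotes."""
        for combo in itertools.product(*(sorted(EXPANSION[c]) for c in self.sequence)):
            yield "".join(combo)


def reverse_complement(pattern):
    """Reverse complement of a pattern or plain string.

    Symbol ``i`` of the output is the complement of symbol ``L-1-i``
    of the input; an involution that preserves length.
    """
    if isinstance(pattern, MotifPattern):
        rc = "".join(COMPLEMENT[_validate(c)] for c in reversed(pattern.sequence))
        return MotifPattern(rc, label=pattern.label)
    return "".join(COMPLEMENT[_validate(c)] for c in reversed(pattern))
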