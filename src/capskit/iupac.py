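"""IUPAC nucleotide codes, reverse complement, and degenerate-motif scanning.

Restriction-enzyme recognition sequences use the 15-symbol IUPAC alphabet
(e.g. W = A/T in AvaII's GGWCC).  Scanning translates a motif into a regular
expression of character classes; a zero-width lookahead is used so that
overlapping occurrences are all reported.  An ``N`` in the *sequence* never
matches any motif symbol, including motif ``N``.
"""

from __future__ import annotations

import re

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_COMP_TABLE = str.maketrans(
    "".join(_COMPLEMENT) + "".join(_COMPLEMENT).lower(),
    "".join(_COMPLEMENT.values()) + "".join(_COMPLEMENT.values()).lower(),
)


def expand(code: str) -> str:
    """Concrete bases matched by a single IUPAC symbol."""
    try:
        return IUPAC_CODES[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def is_palindromic(pattern: str) -> bool:
    """True if the motif equals its own reverse complement (symbol-wise)."""
    return pattern.upper() == reverse_complement(pattern.upper())


def _motif_regex(pattern: str) -> re.Pattern[str]:
    parts = []
    for sym in pattern.upper():
        bases = expand(sym)
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead: report overlapping matches
    return re.compile("(?=" + "".join(parts) + ")")


def find_matches(seq: str, pattern: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) motif occurrences
    on the given strand."""
    if not pattern:
        raise ValueError("empty motif")
    return [m.start() for m in _motif_regex(pattern).finditer(seq.upper())]
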