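"""IUPAC nucleotide alphabet: expansion and minimal-code lookup.

The degenerate single-letter codes (R = A/G, Y = C/T, ...) are the standard
IUPAC nucleotide ambiguity codes.  ``iupac_expand`` and ``iupac_code`` are
mutually inverse: ``iupac_code(iupac_expand(c)) == c`` for every code, and
``iupac_code`` always returns the unique minimal code covering a base set.
"""

from __future__ import annotations

from .errors import AlphabetError

#: Expansion of every IUPAC nucleotide code into its plain-base set.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
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

_CODE_FOR: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPANSION.items()}

#: Characters allowed in an aligned input sequence (gap included).
GAP = "-"
ALLOWED_RESIDUES = frozenset(IUPAC_EXPANSION) | {GAP}

#: Marker for an alignment column dropped from the consensus (too gappy).
DROPPED = "."

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def iupac_expand(code: str) -> frozenset[str]:
    """Return the set of plain bases an IUPAC code stands for.

    >>> sorted(iupac_expand('R'))
    ['A', 'G']
    """
    try:
        return IUPAC_EXPANSION[code.upper()]
    except (KeyError, AttributeError):
        raise AlphabetError(f"unknown IUPAC code: {code!r}") from None


def iupac_code(bases) -> str:
    """Return the unique minimal IUPAC code covering ``bases``.

    >>> iupac_code({'A', 'C', 'G', 'T'})
    'N'
    """
    key = frozenset(str(b).upper() for b in bases)
    if not key:
        raise AlphabetError("cannot encode an empty base set")
    try:
        return _CODE_FOR[key]
    except KeyError:
        bad = key - frozenset("ACGT")
        raise AlphabetError(f"not a plain base set: {sorted(bad)}") from None


def is_degenerate(residue: str) -> bool:
    """True for any residue outside the plain {A, C, G, T} alphabet."""
    return residue not in ("A", "C", "G", "T")


def count_degenerate(seq: str) -> int:
    """Number of residues outside {A, C, G, T} (the probe degeneracy count)."""
    return sum(1 for r in seq if is_degenerate(r))


def reverse_complement(seq: str) -> str:
    """Reverse complement, degenerate codes mapped to their complements."""
    return seq.translate(_COMPLEMENT)[::-1]


def expansions(seq: str, limit: int | None = None) -> list[str]:
    """Enumerate plain-base expansions of a degenerate sequence.

    Expansions follow a canonical order (each degenerate position cycles
    through its bases alphabetically, rightmost fastest).  When the total
    exceeds ``limit`` a deterministic uniform-stride subsample of exactly
    ``limit`` expansions is returned, so repeated calls agree without any
    random state.
    """
    sets = [sorted(iupac_expand(r)) for r in seq]
    total = 1
    for s in sets:
        total *= len(s)
    if limit is None or total <= limit:
        picks = range(total)
    else:
        picks = [(i * total) // limit for i in range(limit)]
    out = []
    for idx in picks:
        chars = []
        rem = idx
        for s in reversed(sets):
            rem, j = divmod(rem, len(s))
            chars.append(s[j])
        out.append("".join(reversed(chars)))
    return out


def intersects(a: str, b: str) -> bool:
    """True if the IUPAC expansions of two residues share at least one base."""
    return bool(iupac_expand(a) & iupac_expand(b))
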