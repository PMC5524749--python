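"""Group-specific IUPAC consensus extraction from 16S alignments.

The base-calling rule: at each alignment column, the consensus reports the
plain nucleotide present in at least a ``cutoff`` fraction (default 3/4) of
the positive-set sequences; when no base reaches the cutoff, the minimal
IUPAC ambiguity code covering every base above a small ``minor_floor``
(default 1%) is emitted instead, so that rare variants widen the code while
singleton sequencing errors do not degenerate it.

Gap handling: base fractions are computed over non-gap residues only, and
columns gappier than ``max_gap`` are marked ``'.'`` and excluded from probe
placement downstream.  Degenerate residues in the *input* contribute
fractionally to the column counts (1/k per expanded base), treating
ambiguous database entries without bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import DROPPED, GAP, iupac_code, iupac_expand
from .errors import ParameterError
from .sequences import AlignedSet


@dataclass(frozen=True)
class ColumnProfile:
    """Per-base frequencies of one alignment column (gaps excluded)."""

    column_index: int
    base_fractions: dict[str, float]
    gap_fraction: float

    def __post_init__(self) -> None:
        if self.gap_fraction < 1.0 and self.base_fractions:
            total = sum(self.base_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"base fractions sum to {total}, not 1")


@dataclass(frozen=True)
class ConsensusSequence:
    """IUPAC consensus over an alignment; '.' marks dropped (gappy) columns."""

    residues: str
    cutoff: float = 0.75
    minor_floor: float = 0.01
    source_target: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def column_profile(aln: AlignedSet, col: int) -> ColumnProfile:
    """Base and gap fractions at alignment column ``col`` (0-based).

    Degenerate input residues are spread fractionally over their expansions.
    """
    if not 0 <= col < aln.length:
        raise IndexError(f"column {col} out of range [0, {aln.length})")
    counts = {"A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}
    gaps = 0
    for seq in aln:
        res = seq.residues[col]
        if res == GAP:
            gaps += 1
            continue
        bases = iupac_expand(res)
        w = 1.0 / len(bases)
        for b in bases:
            counts[b] += w
    n = len(aln)
    non_gap = n - gaps
    if non_gap:
        fractions = {b: c / non_gap for b, c in counts.items() if c > 0}
    else:
        fractions = {}
    return ColumnProfile(col, fractions, gaps / n)


def extract_consensus(
    aln: AlignedSet,
    cutoff: float = 0.75,
    minor_floor: float = 0.01,
    max_gap: float = 0.5,
) -> ConsensusSequence:
    """Extract the group consensus with the fractional-cutoff calling rule.

    Per column: if the gap fraction exceeds ``max_gap`` emit ``'.'``; else if
    a single base reaches ``cutoff`` emit it; else emit the minimal IUPAC
    code covering every base at frequency >= ``minor_floor``.
    """
    if not 0.5 < cutoff <= 1.0:
        raise ParameterError(f"cutoff must be in (0.5, 1], got {cutoff}")
    if minor_floor >= cutoff:
        raise ParameterError(
            f"minor_floor ({minor_floor}) must be below cutoff ({cutoff})"
        )
    out = []
    for col in range(aln.length):
        prof = column_profile(aln, col)
        if prof.gap_fraction > max_gap or not prof.base_fractions:
            out.append(DROPPED)
            continue
        top_base, top_frac = max(
            prof.base_fractions.items(), key=lambda kv: (kv[1], kv[0])
        )
        if top_frac >= cutoff:
            out.append(top_base)
            continue
        covered = {b for b, f in prof.base_fractions.items() if f >= minor_floor}
        if not covered:  # every base rarer than the floor: fall back to the top one
            covered = {top_base}
        out.append(iupac_code(covered))
    return ConsensusSequence(
        "".join(out), cutoff=cutoff, minor_floor=minor_floor,
        source_target=aln.target_name,
    )


def write_consensus_fasta(cons: ConsensusSequence, path) -> None:
    """Write the consensus as a single-record FASTA.

    The header carries the target name; the description records the calling
    parameters so a consensus file is self-describing.
    """
    name = cons.source_target or "consensus"
    with open(path, "w") as fh:
        fh.write(
            f">{name} cutoff={cons.cutoff} minor_floor={cons.minor_floor}\n"
        )
        for i in range(0, len(cons.residues), 70):
            fh.write(cons.residues[i : i + 70] + "\n")
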