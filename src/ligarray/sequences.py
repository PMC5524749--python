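"""Aligned 16S sequence sets: containers and FASTA I/O.

An :class:`AlignedSet` is the unit the consensus extractor and the probe
specificity screens operate on: a gap-aligned collection of 16S rRNA gene
sequences, labelled either *positive* (what a probe set must detect) or
*negative* (what it must not).  Alignment itself is out of scope — inputs
must be pre-aligned (e.g. with ClustalW/MAFFT) and readers refuse records
of unequal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import ALLOWED_RESIDUES
from .errors import AlignmentError, AlphabetError, FormatError

Role = Literal["positive", "negative"]


def normalize_residues(residues: str, record_id: str = "<sequence>") -> str:
    """Uppercase, map U->T, and validate against the IUPAC+gap alphabet."""
    out = residues.upper().replace("U", "T")
    for pos, ch in enumerate(out):
        if ch not in ALLOWED_RESIDUES:
            raise AlphabetError(
                f"illegal residue {ch!r} in record {record_id!r} at position {pos}"
            )
    return out


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence over the IUPAC alphabet (gaps allowed)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"record {self.id!r} is empty")
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> str:
        """Residues with alignment gaps removed (the physical molecule)."""
        return self.residues.replace("-", "")


@dataclass
class AlignedSet:
    """An equal-length set of aligned sequences for one target group."""

    sequences: list[NucleotideSequence]
    role: Role
    target_name: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"aligned set {self.target_name!r} is empty")
        if self.role not in ("positive", "negative"):
            raise ValueError(f"role must be positive|negative, got {self.role!r}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"aligned set {self.target_name!r} has unequal sequence "
                f"lengths {sorted(lengths)}; inputs must be pre-aligned"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


def read_aligned_fasta(path, role: Role = "positive", target_name: str = "") -> AlignedSet:
    """Read a pre-aligned multi-FASTA file into an :class:`AlignedSet`.

    Record order and ids are preserved; residues are stored uppercase with
    U normalized to T.  Unequal record lengths raise
    :class:`~ligarray.errors.AlignmentError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seqs = [NucleotideSequence(rec.id, str(rec.seq)) for rec in records]
    name = target_name or path.stem
    return AlignedSet(seqs, role=role, target_name=name)


def write_aligned_fasta(aln: AlignedSet, path) -> None:
    """Write an aligned set back to multi-FASTA (round-trips losslessly)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in aln.sequences
    ]
    SeqIO.write(records, str(path), "fasta")
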