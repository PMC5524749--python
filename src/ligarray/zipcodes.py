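"""Zip-code libraries: the artificial 25-mer address sequences of the array.

The universal array is printed with Zip Codes rather than target-specific
probes; each ligation product finds its spot through the complementary cZip
tail on its CP.  Two zips are reserved: 63 (ligation control — a fixed
synthetic template added to every reaction, the normalization anchor) and
66 (hybridization control — a directly Cy3-labelled oligo for locating the
grid).  The published Zip 66 sequence is shipped; the remaining library is
generated deterministically as 25-mers with pairwise Hamming distance >= 8
so cross-hybridization between addresses is negligible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import FormatError, ParameterError

ZipRole = Literal["probe", "ligation_control", "hybridization_control"]

#: Published hybridization-control capture sequence (Zip Code 66).
ZIP66_SEQUENCE = "GTTACCGCTGGTGCTGCCGCCGGTA"

#: Published synthetic ligation-control template recognized by the Zip-63 probes.
ZIP63_TEMPLATE = "AGCCGCGAACACCACGATCGACCGGCGCGCGCAGCTGCAGCTTGCTCATG"

ZIP_LENGTH = 25
MIN_PAIRWISE_HAMMING = 8

# Fixed generation seed: the default library is a stable artifact, not a
# per-run random draw.
_LIBRARY_SEED = 20170724


@dataclass(frozen=True)
class ZipCode:
    zip_id: str
    residues: str
    role: ZipRole = "probe"

    def __post_init__(self) -> None:
        if not set(self.residues) <= set("ACGT"):
            raise ParameterError(
                f"zip {self.zip_id!r}: residues must be plain ACGT"
            )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_zip_sequences(
    n: int,
    length: int = ZIP_LENGTH,
    min_distance: int = MIN_PAIRWISE_HAMMING,
    seed: int = _LIBRARY_SEED,
    anchor: Sequence[str] = (),
) -> list[str]:
    """Rejection-sample ``n`` sequences pairwise >= ``min_distance`` apart.

    ``anchor`` sequences (e.g. the published Zip 66) are respected as
    exclusion neighbours but not returned.
    """
    if min_distance > length:
        raise ParameterError("min_distance cannot exceed the zip length")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    all_known = list(anchor)
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 100000:
            raise ParameterError(
                "zip generation failed: constraints too tight"
            )
        cand = "".join(rng.choice(list("ACGT"), size=length))
        if all(_hamming(cand, known) >= min_distance for known in all_known):
            accepted.append(cand)
            all_known.append(cand)
    return accepted


def default_zip_library(n_probe: int = 47) -> list[ZipCode]:
    """The stock library: ``n_probe`` probe zips plus controls 63 and 66.

    Deterministic — repeated calls return identical sequences.
    """
    if n_probe < 1:
        raise ParameterError("n_probe must be >= 1")
    seqs = generate_zip_sequences(n_probe + 1, anchor=[ZIP66_SEQUENCE])
    lib = [
        ZipCode(str(i + 1), seq, "probe") for i, seq in enumerate(seqs[:n_probe])
    ]
    lib.append(ZipCode("63", seqs[n_probe], "ligation_control"))
    lib.append(ZipCode("66", ZIP66_SEQUENCE, "hybridization_control"))
    return lib


def write_zip_library(library: Sequence[ZipCode], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["zip_id", "sequence", "role"])
        for z in library:
            writer.writerow([z.zip_id, z.residues, z.role])


def read_zip_library(path) -> list[ZipCode]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"zip_id", "sequence", "role"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise FormatError(f"zip library missing columns: {sorted(missing)}")
        lib = [
            ZipCode(row["zip_id"], row["sequence"], row["role"])  # type: ignore[arg-type]
            for row in reader
        ]
    ids = [z.zip_id for z in lib]
    if len(ids) != len(set(ids)):
        raise FormatError("duplicate zip_id in library")
    seqs = [z.residues for z in lib]
    if len(seqs) != len(set(seqs)):
        raise FormatError("duplicate zip sequence in library")
    return lib
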