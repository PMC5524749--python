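"""Synthetic 16S-like sequence sets with controlled divergence.

Real probe design starts from curated positive/negative sets of 16S rRNA
sequences.  This module fabricates the same structure, emulating the
conserved/variable architecture of the 16S gene that makes ligation-probe
design possible in the first place:

- the alignment alternates *variable* blocks (where sequences within a set
  diverge at rate ``divergence`` per column, like the V regions) with
  *conserved* blocks (near-identical within and across sets, like the
  flanks probes anneal to);
- each sufficiently long conserved block carries one *discriminating
  column* at its centre: every positive shares the ancestral base there and
  every negative a different one, the diagnostic position a DP 3' terminus
  can interrogate;
- conserved blocks also carry rare *shared polymorphisms*
  (``polymorphism_rate`` per column): a second base present in a third of
  the set, which the consensus absorbs as an IUPAC code — the origin of
  degenerate probe bases;
- optional partial-gap columns are injected into variable blocks.

Not emulated: the actual V1-V9 coordinates, indel patterns beyond uniform
gap columns, chimeras, and inter-target homology — targets are independent
random sequences, so cross-hybridization between synthetic targets is
vanishingly unlikely by construction.  Tests passing on these sets show the
machinery is correct under the stated model, not that any real probe panel
is specific.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .sequences import AlignedSet, NucleotideSequence

_BASES = np.array(list("ACGT"))

VARIABLE_BLOCK = 40
CONSERVED_BLOCK = 140
#: A conserved block must be at least this long to host a discriminating
#: column at its centre (room for a minimal probe half on each side).
_MIN_HOST_BLOCK = 56


def _block_structure(length: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Alternating variable/conserved blocks; returns (is_variable mask,
    list of conserved (start, stop) spans)."""
    is_variable = np.zeros(length, dtype=bool)
    conserved_spans = []
    pos = 0
    variable = True
    while pos < length:
        size = VARIABLE_BLOCK if variable else CONSERVED_BLOCK
        stop = min(pos + size, length)
        if variable:
            is_variable[pos:stop] = True
        else:
            conserved_spans.append((pos, stop))
        pos = stop
        variable = not variable
    return is_variable, conserved_spans


def synthetic_sequence_sets(
    n_targets: int,
    seqs_per_set: int = 6,
    length: int = 400,
    divergence: float = 0.1,
    seed: int | None = None,
    n_discriminating: int | None = None,
    gap_fraction: float = 0.0,
    polymorphism_rate: float = 0.01,
) -> list[tuple[AlignedSet, AlignedSet]]:
    """Generate (positive, negative) aligned set pairs for ``n_targets``.

    divergence: per-column substitution probability inside variable blocks.
    n_discriminating: number of discriminating columns (default: one per
    eligible conserved block); 0 makes positive and negative sets
    indistinguishable at every conserved column, so design must fail.
    Deterministic under ``seed``.
    """
    if not 0.0 <= divergence < 1.0:
        raise ParameterError(f"divergence must be in [0, 1), got {divergence}")
    if length < 120:
        raise ParameterError(f"length must be >= 120, got {length}")
    if seqs_per_set < 1:
        raise ParameterError("seqs_per_set must be >= 1")
    if not 0.0 <= gap_fraction < 0.5:
        raise ParameterError("gap_fraction must be in [0, 0.5)")
    if not 0.0 <= polymorphism_rate < 0.5:
        raise ParameterError("polymorphism_rate must be in [0, 0.5)")
    is_variable, conserved_spans = _block_structure(length)
    host_blocks = [(a, b) for a, b in conserved_spans if b - a >= _MIN_HOST_BLOCK]
    if n_discriminating is None:
        n_disc = len(host_blocks)
    else:
        if n_discriminating < 0:
            raise ParameterError("n_discriminating must be >= 0")
        if n_discriminating > len(host_blocks):
            raise ParameterError(
                f"cannot place {n_discriminating} discriminating columns: "
                f"only {len(host_blocks)} conserved blocks of >= "
                f"{_MIN_HOST_BLOCK} columns in a length-{length} alignment"
            )
        n_disc = n_discriminating
    if n_disc == 0 and n_discriminating is None:
        raise ParameterError(
            f"length {length} leaves no conserved block long enough for a "
            f"discriminating column"
        )
    rng = np.random.default_rng(seed)
    out = []
    for t in range(n_targets):
        ancestor = rng.integers(0, 4, size=length)
        disc_cols = np.array(
            [(a + b) // 2 for a, b in host_blocks[:n_disc]], dtype=int
        )
        special = np.zeros(length, dtype=bool)  # no further variation here
        special[disc_cols] = True

        # shared polymorphisms inside conserved blocks: a second base carried
        # by a third of each set, absorbed by the consensus as an IUPAC code
        poly_mask = (
            ~is_variable & ~special & (rng.random(length) < polymorphism_rate)
        )
        poly_cols = np.flatnonzero(poly_mask)
        poly_alt = (ancestor[poly_cols] + rng.integers(1, 4, size=poly_cols.size)) % 4
        n_carriers = max(1, -(-seqs_per_set // 3))  # ceil(n/3)
        if seqs_per_set >= 4 and n_carriers / seqs_per_set <= 0.25:
            n_carriers += 1  # keep the major fraction below the 75% cutoff

        neg_backbone = ancestor.copy()
        for col in disc_cols:
            neg_backbone[col] = (ancestor[col] + rng.integers(1, 4)) % 4

        def _make_set(backbone: np.ndarray) -> np.ndarray:
            mat = np.tile(backbone, (seqs_per_set, 1))
            for i in range(seqs_per_set):
                hit = (rng.random(length) < divergence) & is_variable
                shifts = rng.integers(1, 4, size=int(hit.sum()))
                mat[i, hit] = (mat[i, hit] + shifts) % 4
            for col, alt in zip(poly_cols, poly_alt):
                carriers = rng.choice(seqs_per_set, size=n_carriers, replace=False)
                mat[carriers, col] = alt
            return mat

        pos_mat = _make_set(ancestor)
        neg_mat = _make_set(neg_backbone)

        gap_cols = np.array([], dtype=int)
        if gap_fraction > 0:
            candidates = np.flatnonzero(is_variable)
            n_gap = min(int(round(gap_fraction * length)), candidates.size)
            gap_cols = rng.choice(candidates, size=n_gap, replace=False)

        def _to_set(mat: np.ndarray, role: str) -> AlignedSet:
            seqs = []
            for i, row in enumerate(mat):
                chars = _BASES[row].tolist()
                for col in gap_cols:
                    # gap a majority of rows so the column is dropped ('.')
                    if (i + col) % 3 != 0:
                        chars[col] = "-"
                seqs.append(
                    NucleotideSequence(f"{role[:3]}_{t}_{i}", "".join(chars))
                )
            return AlignedSet(seqs, role=role, target_name=f"target_{t:02d}")

        out.append((_to_set(pos_mat, "positive"), _to_set(neg_mat, "negative")))
    return out
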