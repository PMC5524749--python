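"""LDR probe-pair design on IUPAC consensus sequences.

Each probe set is a Discriminating Probe (DP, 5'-Cy3 labelled) and a Common
Probe (CP, carrying the complementary Zip Code at its 3' end) that anneal
head-to-tail on the target 16S sequence.  A thermostable ligase seals the
nick between them only on perfect base-pairing at the junction, so the DP's
3'-terminal base is the diagnostic position: the pair must perfectly match
every positive-set sequence and mismatch every negative-set sequence at
that terminal base.

Design scans every junction on the consensus, extends the DP upstream and
the CP downstream over contiguous usable columns, and keeps candidates
whose halves satisfy the length window (25-60 nt), the melting-temperature
window (68 +/- 1 degC) and the degeneracy cap (<= 4 ambiguous bases per
half).  Candidates are ranked by closeness of both halves to the target Tm,
then total degeneracy, then leftmost junction — a deterministic order, so
the same inputs always yield the same panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .alphabet import DROPPED, GAP, count_degenerate, intersects, iupac_expand
from .consensus import ConsensusSequence
from .errors import (
    CapacityError,
    CoordinateError,
    DesignInfeasibleError,
    ParameterError,
)
from .sequences import AlignedSet
from .thermo import DEFAULT_THERMO, ThermoParameters, melting_temp
from .zipcodes import ZipCode

#: Maximum probe sets a single universal array can carry.
MAX_PROBESETS_PER_ARRAY = 47


@dataclass(frozen=True)
class DesignConstraints:
    """Length, Tm and degeneracy windows applied to each probe half."""

    min_len: int = 25
    max_len: int = 60
    tm_target: float = 68.0
    tm_tol: float = 1.0
    max_degenerate: int = 4

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ParameterError("min_len must not exceed max_len")
        if self.tm_tol <= 0:
            raise ParameterError("tm_tol must be positive")
        if self.max_degenerate < 0:
            raise ParameterError("max_degenerate must be >= 0")


@dataclass(frozen=True)
class ProbeHalf:
    """One half of a probe set (DP or CP) with its design metrics."""

    kind: Literal["DP", "CP"]
    residues: str
    tm: float
    degenerate_count: int
    label: bool = False       # Cy3 at the 5' end; DP only
    czip: str | None = None   # cZip tail at the 3' end; CP only

    def __post_init__(self) -> None:
        if self.kind == "DP" and self.czip is not None:
            raise ParameterError("a DP never carries a cZip tail")
        if self.kind == "CP" and self.label:
            raise ParameterError("a CP never carries the fluorophore label")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProbePair:
    """A DP+CP probe set anchored at one consensus junction.

    ``junction`` is the 0-based consensus column of the DP 3'-terminal base;
    the CP starts at the next column, so dp.residues + cp.residues is a
    contiguous consensus substring.
    """

    target_name: str
    dp: ProbeHalf
    cp: ProbeHalf
    junction: int
    zip_id: str = ""

    @property
    def footprint(self) -> tuple[int, int]:
        """Half-open consensus column span [start, stop) of dp+cp."""
        start = self.junction - len(self.dp) + 1
        return start, self.junction + 1 + len(self.cp)

    @property
    def sequence(self) -> str:
        return self.dp.residues + self.cp.residues


@dataclass
class SpecificityReport:
    """In-silico specificity screen result for one candidate pair."""

    pair: ProbePair | None
    target_name: str
    positive_matches: dict[str, bool] = field(default_factory=dict)
    negative_discriminated: dict[str, bool] = field(default_factory=dict)
    failure_reason: str = ""

    @property
    def passed(self) -> bool:
        return (
            self.pair is not None
            and all(self.positive_matches.values())
            and all(self.negative_discriminated.values())
        )


@dataclass
class ProbePanel:
    """The designed probe sets plus the zip-code library they map onto."""

    pairs: list[ProbePair]
    zip_library: list[ZipCode]
    metadata: str = ""

    def __post_init__(self) -> None:
        ids = [p.zip_id for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ParameterError("duplicate zip_id assignments in panel")
        by_id = {z.zip_id: z for z in self.zip_library}
        for p in self.pairs:
            z = by_id.get(p.zip_id)
            if z is None:
                raise ParameterError(f"zip_id {p.zip_id!r} not in the library")
            if z.role != "probe":
                raise ParameterError(
                    f"control zip {p.zip_id!r} may not be assigned to a probe"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_for(self, target_name: str) -> ProbePair:
        for p in self.pairs:
            if p.target_name == target_name:
                return p
        raise KeyError(target_name)


def _usable_runs(residues: str) -> list[tuple[int, int]]:
    """Maximal half-open runs of non-'.' consensus columns."""
    runs = []
    start = None
    for i, ch in enumerate(residues):
        if ch == DROPPED:
            if start is not None:
                runs.append((start, i))
                start = None
        elif start is None:
            start = i
    if start is not None:
        runs.append((start, len(residues)))
    return runs


def _half_candidates(
    residues: str,
    lo: int,
    hi: int,
    anchored_at: int,
    direction: int,
    constraints: DesignConstraints,
    thermo: ThermoParameters,
) -> list[tuple[str, float, int]]:
    """Probe halves anchored at a junction, grown away from it.

    direction -1 grows the DP upstream (anchored at its 3' end); +1 grows
    the CP downstream (anchored at its 5' start).  Returns (residues, tm,
    degeneracy) triples passing every per-half constraint.
    """
    out = []
    for length in range(constraints.min_len, constraints.max_len + 1):
        if direction < 0:
            start, stop = anchored_at - length + 1, anchored_at + 1
        else:
            start, stop = anchored_at, anchored_at + length
        if start < lo or stop > hi:
            break
        seq = residues[start:stop]
        deg = count_degenerate(seq)
        if deg > constraints.max_degenerate:
            # Degeneracy only grows with length in this direction; no point
            # trying longer halves at this junction.
            break
        tm = melting_temp(seq, thermo)
        if abs(tm - constraints.tm_target) <= constraints.tm_tol:
            out.append((seq, tm, deg))
    return out


def enumerate_probe_pairs(
    consensus: ConsensusSequence,
    constraints: DesignConstraints = DesignConstraints(),
    thermo: ThermoParameters = DEFAULT_THERMO,
    junctions: Iterable[int] | None = None,
) -> list[ProbePair]:
    """Enumerate every DP+CP candidate satisfying the per-half constraints.

    Candidates are sorted by combined |Tm - target| over the two halves,
    then total degeneracy, then junction position.  An empty list means no
    window qualifies; a consensus without a single usable stretch of
    2 * min_len columns is design-infeasible.
    """
    residues = consensus.residues
    runs = _usable_runs(residues)
    if not runs or max(hi - lo for lo, hi in runs) < 2 * constraints.min_len:
        raise DesignInfeasibleError(
            f"consensus {consensus.source_target!r} has no usable stretch of "
            f"{2 * constraints.min_len} columns"
        )
    wanted = None if junctions is None else set(junctions)
    candidates = []
    for lo, hi in runs:
        for junction in range(lo + constraints.min_len - 1, hi - constraints.min_len):
            if wanted is not None and junction not in wanted:
                continue
            dps = _half_candidates(
                residues, lo, hi, junction, -1, constraints, thermo
            )
            if not dps:
                continue
            cps = _half_candidates(
                residues, lo, hi, junction + 1, +1, constraints, thermo
            )
            for dseq, dtm, ddeg in dps:
                for cseq, ctm, cdeg in cps:
                    pair = ProbePair(
                        target_name=consensus.source_target,
                        dp=ProbeHalf("DP", dseq, dtm, ddeg, label=True),
                        cp=ProbeHalf("CP", cseq, ctm, cdeg),
                        junction=junction,
                    )
                    candidates.append(pair)
    candidates.sort(
        key=lambda p: (
            abs(p.dp.tm - constraints.tm_target)
            + abs(p.cp.tm - constraints.tm_target),
            p.dp.degenerate_count + p.cp.degenerate_count,
            p.junction,
            len(p.dp),
            len(p.cp),
        )
    )
    return candidates


def matches_positive(pair: ProbePair, positives: AlignedSet) -> dict[str, bool]:
    """Perfect-match screen of the pair footprint against each positive.

    A sequence matches iff it has no gap inside the footprint and, at every
    footprint column, its residue's IUPAC expansion intersects the probe
    residue's expansion.
    """
    start, stop = pair.footprint
    if start < 0 or stop > positives.length:
        raise CoordinateError(
            f"footprint [{start}, {stop}) exceeds alignment length "
            f"{positives.length}"
        )
    probe_seq = pair.sequence
    result = {}
    for seq in positives:
        window = seq.residues[start:stop]
        ok = GAP not in window and all(
            intersects(p, s) for p, s in zip(probe_seq, window)
        )
        result[seq.id] = ok
    return result


def discriminates_negative(pair: ProbePair, negatives: AlignedSet) -> dict[str, bool]:
    """3'-terminal mismatch screen against each negative-set sequence.

    A negative is discriminated iff its residue at the junction column does
    NOT intersect the DP 3'-terminal residue's expansion (a gap there also
    counts as discriminated, since the ligase has nothing to seal).
    """
    if not 0 <= pair.junction < negatives.length:
        raise CoordinateError(
            f"junction {pair.junction} outside alignment of length "
            f"{negatives.length}"
        )
    terminal = pair.dp.residues[-1]
    result = {}
    for seq in negatives:
        res = seq.residues[pair.junction]
        result[seq.id] = res == GAP or not intersects(terminal, res)
    return result


def _discriminable_junctions(
    consensus: ConsensusSequence, positives: AlignedSet, negatives: AlignedSet
) -> list[int]:
    """Columns where every negative mismatches the consensus residue.

    Cheap pre-filter: the full screens are re-applied to each candidate, but
    only junctions passing this column test can possibly succeed.
    """
    cols = []
    for j, res in enumerate(consensus.residues):
        if res == DROPPED:
            continue
        if all(
            s.residues[j] == GAP or not intersects(res, s.residues[j])
            for s in negatives
        ):
            cols.append(j)
    return cols


def design_pair(
    positives: AlignedSet,
    negatives: AlignedSet,
    constraints: DesignConstraints = DesignConstraints(),
    thermo: ThermoParameters = DEFAULT_THERMO,
    cutoff: float = 0.75,
    minor_floor: float = 0.01,
) -> SpecificityReport:
    """Design the best specific probe pair for one target.

    Extracts the positive-set consensus, enumerates candidates restricted to
    junctions where discrimination is possible, and returns the first
    (best-ranked) candidate passing both specificity screens, or a failing
    report with the closest-failing reason.
    """
    from .consensus import extract_consensus

    cons = extract_consensus(positives, cutoff=cutoff, minor_floor=minor_floor)
    name = positives.target_name
    junctions = _discriminable_junctions(cons, positives, negatives)
    if not junctions:
        return SpecificityReport(
            None, name, failure_reason="no discriminable junction column"
        )
    try:
        candidates = enumerate_probe_pairs(cons, constraints, thermo, junctions)
    except DesignInfeasibleError as exc:
        return SpecificityReport(None, name, failure_reason=str(exc))
    if not candidates:
        return SpecificityReport(
            None,
            name,
            failure_reason="no candidate meets length/Tm/degeneracy "
            "constraints at a discriminable junction",
        )
    last_reason = ""
    for pair in candidates:
        pos = matches_positive(pair, positives)
        if not all(pos.values()):
            last_reason = "candidate fails perfect match on the positive set"
            continue
        neg = discriminates_negative(pair, negatives)
        if not all(neg.values()):
            last_reason = "candidate fails 3'-terminal discrimination"
            continue
        return SpecificityReport(pair, name, pos, neg)
    return SpecificityReport(None, name, failure_reason=last_reason)


def design_panel(
    targets: Sequence[tuple[AlignedSet, AlignedSet]],
    constraints: DesignConstraints = DesignConstraints(),
    zip_library: Sequence[ZipCode] | None = None,
    thermo: ThermoParameters = DEFAULT_THERMO,
    attach_czip: bool = True,
) -> tuple[ProbePanel, list[SpecificityReport]]:
    """Design one probe set per (positive, negative) target pair.

    Each passing target is assigned the next free probe-role zip code and,
    when ``attach_czip`` is set, its CP gets the reverse complement of that
    zip appended as the cZip tail.  Targets with no passing candidate are
    reported as failures; requesting more probe sets than the library (or
    the array, 47 sets) can hold raises :class:`CapacityError`.
    """
    from .alphabet import reverse_complement
    from .zipcodes import default_zip_library

    if not targets:
        raise ParameterError("at least one target is required")
    if zip_library is None:
        zip_library = default_zip_library()
    probe_zips = [z for z in zip_library if z.role == "probe"]
    if len(targets) > min(len(probe_zips), MAX_PROBESETS_PER_ARRAY):
        raise CapacityError(
            f"{len(targets)} targets exceed the available probe-role zip "
            f"codes ({len(probe_zips)}) or the {MAX_PROBESETS_PER_ARRAY}-"
            f"probeset-per-array limit"
        )
    pairs = []
    reports = []
    free = iter(probe_zips)
    for positives, negatives in targets:
        report = design_pair(positives, negatives, constraints, thermo)
        reports.append(report)
        if report.passed:
            zip_code = next(free)
            pair = replace(report.pair, zip_id=zip_code.zip_id)
            if attach_czip:
                pair = replace(
                    pair,
                    cp=replace(pair.cp, czip=reverse_complement(zip_code.residues)),
                )
            report.pair = pair
            pairs.append(pair)
    panel = ProbePanel(pairs, list(zip_library))
    return panel, reports


@dataclass(frozen=True)
class PanelStats:
    """Summary statistics over all probe halves of a panel."""

    n_halves: int
    mean_length: float
    sd_length: float
    mean_tm: float
    sd_tm: float
    degeneracy_histogram: dict[int, int]

    @property
    def n_degenerate_halves(self) -> int:
        return sum(n for k, n in self.degeneracy_histogram.items() if k > 0)


def panel_stats(panel: ProbePanel | Sequence[ProbeHalf]) -> PanelStats:
    """Length/Tm/degeneracy summary over DPs and CPs (cZip tails excluded)."""
    if isinstance(panel, ProbePanel):
        halves = [h for p in panel.pairs for h in (p.dp, p.cp)]
    else:
        halves = list(panel)
    if not halves:
        raise ParameterError("cannot summarize an empty panel")
    lengths = np.array([len(h) for h in halves], dtype=float)
    tms = np.array([h.tm for h in halves], dtype=float)
    hist: dict[int, int] = {}
    for h in halves:
        hist[h.degenerate_count] = hist.get(h.degenerate_count, 0) + 1
    ddof = 1 if len(halves) > 1 else 0
    return PanelStats(
        n_halves=len(halves),
        mean_length=float(lengths.mean()),
        sd_length=float(lengths.std(ddof=ddof)),
        mean_tm=float(tms.mean()),
        sd_tm=float(tms.std(ddof=ddof)),
        degeneracy_histogram=dict(sorted(hist.items())),
    )
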