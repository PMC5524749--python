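"""Probe enumeration, specificity screens, and the brute-force design oracle."""

import itertools

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from ligarray import (
    AlignedSet,
    ConsensusSequence,
    DesignConstraints,
    NucleotideSequence,
    ProbeHalf,
    ProbePair,
    discriminates_negative,
    enumerate_probe_pairs,
    extract_consensus,
    matches_positive,
    panel_stats,
)
from ligarray.alphabet import count_degenerate
from ligarray.errors import (
    CoordinateError,
    DesignInfeasibleError,
    ParameterError,
)
from ligarray.thermo import DEFAULT_THERMO


def _random_consensus(length, seed, degenerate_at=()):
    rng = np.random.default_rng(seed)
    chars = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    for col in degenerate_at:
        chars[col] = "R"
    return ConsensusSequence("".join(chars), source_target="t")


def _pair(dp_seq, cp_seq, junction, target="t"):
    return ProbePair(
        target,
        ProbeHalf("DP", dp_seq, 68.0, count_degenerate(dp_seq), label=True),
        ProbeHalf("CP", cp_seq, 68.0, count_degenerate(cp_seq)),
        junction,
    )


class TestEnumerate:
    def test_candidates_satisfy_all_half_constraints(self):
        cons = _random_consensus(120, seed=3)
        constraints = DesignConstraints()
        pairs = enumerate_probe_pairs(cons, constraints)
        assert pairs
        for p in pairs:
            for half in (p.dp, p.cp):
                assert constraints.min_len <= len(half) <= constraints.max_len
                assert abs(half.tm - 68.0) <= 1.0
                assert half.degenerate_count <= constraints.max_degenerate
            # junction adjacency: dp+cp is the contiguous consensus substring
            start, stop = p.footprint
            assert p.sequence == cons.residues[start:stop]

    def test_consensus_too_short_is_infeasible(self):
        with pytest.raises(DesignInfeasibleError):
            enumerate_probe_pairs(_random_consensus(30, seed=1))

    def test_degeneracy_cap_respected_near_degenerate_cluster(self):
        cluster = range(60, 65)  # 5 degenerate bases in one window
        cons = _random_consensus(160, seed=5, degenerate_at=cluster)
        pairs = enumerate_probe_pairs(cons, DesignConstraints())
        for p in pairs:
            start, stop = p.footprint
            n_inside = sum(1 for c in cluster if start <= c < stop)
            assert (
                p.dp.degenerate_count + p.cp.degenerate_count <= 8
            )  # <= 4 per half by construction
            if n_inside == 5:
                # a footprint swallowing the whole cluster would need >4 on
                # one half or a 4/1 split across the junction
                assert p.dp.degenerate_count <= 4 and p.cp.degenerate_count <= 4

    def test_sorted_by_tm_closeness_then_degeneracy_then_junction(self):
        cons = _random_consensus(140, seed=8)
        constraints = DesignConstraints()
        pairs = enumerate_probe_pairs(cons, constraints)
        keys = [
            (
                abs(p.dp.tm - 68) + abs(p.cp.tm - 68),
                p.dp.degenerate_count + p.cp.degenerate_count,
                p.junction,
            )
            for p in pairs
        ]
        assert keys == sorted(keys)


def brute_force_candidates(cons: ConsensusSequence, constraints: DesignConstraints):
    """Independent exhaustive scanner using Biopython's Tm implementation.

    Checks every (junction, dp-length, cp-length) triple directly against
    the constraint definitions; no sharing with the production code path
    beyond the residue string itself.
    """

    def half_ok(seq):
        if not (constraints.min_len <= len(seq) <= constraints.max_len):
            return False
        if "." in seq:
            return False
        if sum(1 for c in seq if c not in "ACGT") > constraints.max_degenerate:
            return False
        table = {
            "A": "A", "C": "C", "G": "G", "T": "T",
            "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT",
            "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
            "N": "ACGT",
        }
        variants = [
            "".join(combo)
            for combo in itertools.product(*(table[c] for c in seq))
        ]
        tms = [
            mt.Tm_NN(v, nn_table=mt.DNA_NN3, Na=DEFAULT_THERMO.na_mM,
                     dnac1=DEFAULT_THERMO.dnac1_nM, dnac2=DEFAULT_THERMO.dnac2_nM,
                     saltcorr=5)
            for v in variants
        ]
        return abs(sum(tms) / len(tms) - constraints.tm_target) <= constraints.tm_tol

    found = set()
    res = cons.residues
    for junction in range(len(res)):
        for l1 in range(constraints.min_len, constraints.max_len + 1):
            a = junction - l1 + 1
            if a < 0:
                continue
            dp = res[a : junction + 1]
            if not half_ok(dp):
                continue
            for l2 in range(constraints.min_len, constraints.max_len + 1):
                b = junction + 1 + l2
                if b > len(res):
                    continue
                cp = res[junction + 1 : b]
                if half_ok(cp):
                    found.add((junction, dp, cp))
    return found


def test_brute_force_oracle_reproduces_candidate_list_exactly():
    for seed in (2, 9):
        cons = _random_consensus(150, seed=seed, degenerate_at=(75, 90))
        constraints = DesignConstraints()
        mine = {
            (p.junction, p.dp.residues, p.cp.residues)
            for p in enumerate_probe_pairs(cons, constraints)
        }
        assert mine == brute_force_candidates(cons, constraints)


class TestSpecificityScreens:
    def _sets(self):
        base = "ACGTACGTGG" * 6
        target = AlignedSet(
            [NucleotideSequence("p1", base), NucleotideSequence("p2", base)],
            role="positive",
        )
        return base, target

    def test_identical_ungapped_region_matches(self):
        base, positives = self._sets()
        pair = _pair(base[:25], base[25:50], 24)
        assert all(matches_positive(pair, positives).values())

    def test_gap_in_footprint_fails_match(self):
        base, _ = self._sets()
        gapped = AlignedSet(
            [NucleotideSequence("g", base[:30] + "-" + base[31:])],
            role="positive",
        )
        pair = _pair(base[:25], base[25:50], 24)
        assert matches_positive(pair, gapped) == {"g": False}

    def test_degenerate_probe_residue_matches_covered_base(self):
        base, _ = self._sets()
        positives = AlignedSet(
            [NucleotideSequence("p", base)], role="positive"
        )
        dp = "R" + base[1:25]  # R covers the A at column 0
        pair = _pair(dp, base[25:50], 24)
        assert matches_positive(pair, positives) == {"p": True}

    def test_footprint_outside_alignment_is_coordinate_error(self):
        base, positives = self._sets()
        pair = _pair(base[:25], base[25:50], 20)  # dp start would be -4
        with pytest.raises(CoordinateError):
            matches_positive(pair, positives)

    @pytest.mark.parametrize(
        "terminal,negative_base,expected",
        [("A", "G", True), ("A", "A", False), ("R", "G", False), ("A", "-", True)],
    )
    def test_discrimination_is_decided_at_the_dp_terminus(
        self, terminal, negative_base, expected
    ):
        base, _ = self._sets()
        dp = base[:24] + terminal
        neg_seq = base[:24] + negative_base + base[25:]
        negatives = AlignedSet(
            [NucleotideSequence("n", neg_seq)], role="negative"
        )
        pair = _pair(dp, base[25:50], 24)
        assert discriminates_negative(pair, negatives) == {"n": expected}


class TestPanelStats:
    def test_mean_length_arithmetic(self):
        halves = [
            ProbeHalf("DP", "A" * n, 68.0, 0, label=True) for n in (30, 34)
        ] + [ProbeHalf("CP", "A" * n, 68.0, 0) for n in (38, 42)]
        st = panel_stats(halves)
        assert st.mean_length == pytest.approx(36.0)
        assert st.n_halves == 4

    def test_identical_probes_have_zero_sd(self):
        halves = [ProbeHalf("CP", "ACGT" * 8, 67.5, 0) for _ in range(4)]
        st = panel_stats(halves)
        assert st.sd_length == 0.0
        assert st.sd_tm == 0.0

    def test_degeneracy_histogram_counts_halves(self):
        halves = [
            ProbeHalf("CP", "ACGTACGT", 68.0, 0),
            ProbeHalf("CP", "ACGTACGR", 68.0, 1),
            ProbeHalf("CP", "ACGTACRR", 68.0, 2),
        ]
        st = panel_stats(halves)
        assert st.degeneracy_histogram == {0: 1, 1: 1, 2: 1}
        assert st.n_degenerate_halves == 2

    def test_empty_panel_rejected(self):
        with pytest.raises(ParameterError):
            panel_stats([])
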