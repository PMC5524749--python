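"""Nearest-neighbor melting temperatures for LDR probe candidates.

Duplex stability is scored with the unified Watson-Crick nearest-neighbor
parameters of Allawi & SantaLucia (1997): enthalpy/entropy increments per
dinucleotide stack plus terminal A·T / G·C initiation corrections, with the
entropic salt correction of SantaLucia (1998),
dS' = dS + 0.368 (N-1) ln[Na+], and

    Tm = 1000 * dH / (dS' + R ln k) - 273.15   (R = 1.987 cal/K/mol)

where k is the effective strand concentration, (c1 - c2/2) for
non-self-complementary duplexes.  Defaults (100 mM monovalent salt,
12.5 nM per strand — 250 fmol probe in a 20 uL ligation) put random
36-mers near 68 degC, the design target for LDR probe halves.

Degenerate probes are scored as the mean Tm over their plain-base
expansions (exhaustive up to 64, deterministic stride subsample beyond).
The implementation is an independent code path from Biopython's
``MeltingTemp.Tm_NN``; the two agree to <0.1 degC on the same parameter
set, which the test suite asserts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import count_degenerate, expansions, reverse_complement
from .errors import ParameterError

# Allawi & SantaLucia (1997) dH (kcal/mol) and dS (cal/K/mol) per stack.
_NN_DH_DS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Terminal base-pair initiation corrections.
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_SYM = (0.0, -1.4)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_TO_BASE = "ACGT"

# 4x4 stack tables indexed by (first base, second base).
_DH16 = np.zeros((4, 4))
_DS16 = np.zeros((4, 4))
for _pair, (_dh, _ds) in _NN_DH_DS.items():
    _DH16[_BASE_INDEX[_pair[0]], _BASE_INDEX[_pair[1]]] = _dh
    _DS16[_BASE_INDEX[_pair[0]], _BASE_INDEX[_pair[1]]] = _ds

_R = 1.987  # gas constant, cal / (K mol)


@dataclass(frozen=True)
class ThermoParameters:
    """Solution conditions and strand concentrations for Tm calculation.

    na_mM: monovalent cation concentration (mM).
    dnac1_nM / dnac2_nM: concentrations of the more/less abundant strand (nM).
    """

    na_mM: float = 100.0
    dnac1_nM: float = 12.5
    dnac2_nM: float = 12.5

    def effective_k(self, selfcomp: bool) -> float:
        if selfcomp:
            return self.dnac1_nM * 1e-9
        return (self.dnac1_nM - self.dnac2_nM / 2.0) * 1e-9


DEFAULT_THERMO = ThermoParameters()

MAX_EXPANSIONS = 64


def _tm_plain(seq: str, params: ThermoParameters) -> float:
    """Tm of a non-degenerate sequence (vectorized NN sum)."""
    idx = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    dh = _DH16[idx[:-1], idx[1:]].sum()
    ds = _DS16[idx[:-1], idx[1:]].sum()
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dh += _INIT_AT[0]
            ds += _INIT_AT[1]
        else:
            dh += _INIT_GC[0]
            ds += _INIT_GC[1]
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        dh += _SYM[0]
        ds += _SYM[1]
    ds += 0.368 * (len(seq) - 1) * math.log(params.na_mM * 1e-3)
    k = params.effective_k(selfcomp)
    return 1000.0 * dh / (ds + _R * math.log(k)) - 273.15


def melting_temp(
    seq: str,
    params: ThermoParameters = DEFAULT_THERMO,
    max_expansions: int = MAX_EXPANSIONS,
) -> float:
    """Melting temperature (degC) of a probe half.

    For degenerate sequences, the mean Tm over plain-base expansions
    (exhaustive when there are at most ``max_expansions``, else a
    deterministic stride subsample of that size).
    """
    if len(seq) < 8:
        raise ParameterError(
            f"sequence of length {len(seq)} too short for a meaningful Tm"
        )
    seq = seq.upper()
    if count_degenerate(seq) == 0:
        return _tm_plain(seq, params)
    variants = expansions(seq, limit=max_expansions)
    return float(np.mean([_tm_plain(v, params) for v in variants]))
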