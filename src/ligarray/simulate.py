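"""In-silico LDR-UA experiments: ligation events and spot fluorescence.

The simulator is the synthetic-data backbone for the analysis pipeline.  A
template mix (amplicon amounts in ng) is checked against every probe pair
for a ligation event; each matched probe spot then fluoresces with mean

    signal = efficiency * (sum of matched component amounts) + background

under multiplicative lognormal noise (configurable CV) plus additive
zero-truncated normal background.  Empty spots draw from the background
alone; buffer-only blank spots draw from the background plus a small
constant offset (unbound dye retained by the printing buffer), which makes
the one-tailed probe-vs-blank call conservative for unmatched probes, as
observed on the validated arrays; the Zip-63 ligation control fluoresces
at a fixed mean
independent of the mix (it is driven by the fixed synthetic template added
to every reaction), as does the Zip-66 hybridization control.  Human
carrier DNA is signal-inert.

Fluorescence tables are plain CSV; a minimal GenePix-GPR-like dialect
(Block / Row / Column / ID / F532 Median / B532 Median) can also be read.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import iupac_expand
from .errors import ComponentError, FormatError, ParameterError
from .layout import BLANK, EMPTY, ArrayLayout
from .probes import ProbePair, ProbePanel
from .sequences import NucleotideSequence

IFTABLE_COLUMNS = [
    "array_id", "row", "col", "zip_id", "role", "replicate", "IF", "background",
]


@dataclass(frozen=True)
class MixComponent:
    """One amplicon in a template mix: a panel target name or raw sequence."""

    name: str
    amount_ng: float
    sequence: str | None = None  # ungapped template; overrides name routing

    def __post_init__(self) -> None:
        if self.amount_ng < 0:
            raise ParameterError(f"component {self.name!r}: amount must be >= 0")


@dataclass
class TemplateMix:
    """A sample definition: amplicon components plus inert carrier DNA."""

    components: list[MixComponent]
    human_dna_ng: float = 0.0
    label: str = "mix"

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(names) != len(set(names)):
            raise ParameterError("component names must be unique")
        if self.human_dna_ng < 0:
            raise ParameterError("human_dna_ng must be >= 0")

    def to_json(self, path) -> None:
        payload = {
            "label": self.label,
            "human_dna_ng": self.human_dna_ng,
            "components": [
                {"name": c.name, "amount_ng": c.amount_ng,
                 **({"sequence": c.sequence} if c.sequence else {})}
                for c in self.components
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TemplateMix":
        with open(path) as fh:
            payload = json.load(fh)
        try:
            comps = [
                MixComponent(c["name"], c["amount_ng"], c.get("sequence"))
                for c in payload["components"]
            ]
            return cls(comps, payload.get("human_dna_ng", 0.0),
                       payload.get("label", "mix"))
        except KeyError as exc:
            raise FormatError(f"template mix missing field: {exc}") from None


#: ng of a ~1.5 kb 16S amplicon per fmol; reporting-only conversion.
FMOL_PER_NG = 0.7


@dataclass
class SimulationConfig:
    """Noise and response parameters of the virtual scanner/assay.

    efficiency: fluorescence units per ng of matched template, either one
    global value or a per-target mapping.  zip63/zip66 signal means are
    mix-independent control levels.
    """

    efficiency: float | Mapping[str, float] = 5000.0
    background_mean: float = 500.0
    background_sd: float = 50.0
    noise_cv: float = 0.1
    zip63_signal_mean: float = 40000.0
    zip66_signal_mean: float = 30000.0
    cross_hyb_rate: float = 0.0
    blank_offset_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        effs = (
            list(self.efficiency.values())
            if isinstance(self.efficiency, Mapping)
            else [self.efficiency]
        )
        if any(e <= 0 for e in effs):
            raise ParameterError("efficiencies must be positive")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.background_mean <= 0:
            raise ParameterError("background_mean must be positive")

    def efficiency_for(self, target_name: str) -> float:
        if isinstance(self.efficiency, Mapping):
            try:
                return float(self.efficiency[target_name])
            except KeyError:
                raise ComponentError(
                    f"no efficiency configured for target {target_name!r}"
                ) from None
        return float(self.efficiency)


def _footprint_regex(pair: ProbePair) -> re.Pattern:
    parts = []
    for res in pair.sequence:
        bases = sorted(iupac_expand(res))
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("".join(parts))


def ligation_match(pair: ProbePair, template: NucleotideSequence | str) -> bool:
    """Would the ligase seal this probe pair on this (ungapped) template?

    True iff the concatenated DP+CP footprint occurs in the template with
    every position compatible (IUPAC expansions intersecting) — which at
    the DP 3'-terminal junction position amounts to an exact base match,
    the single-mismatch discrimination the ligase enforces.
    """
    seq = template.degapped() if isinstance(template, NucleotideSequence) else template
    return _footprint_regex(pair).search(seq) is not None


def _matched_amounts(
    panel: ProbePanel, mix: TemplateMix
) -> dict[str, float]:
    """ng of template available to each probe pair of the panel."""
    known = {p.target_name for p in panel.pairs}
    amounts = {p.target_name: 0.0 for p in panel.pairs}
    for comp in mix.components:
        if comp.sequence is not None:
            for pair in panel.pairs:
                if ligation_match(pair, comp.sequence):
                    amounts[pair.target_name] += comp.amount_ng
        elif comp.name in known:
            amounts[comp.name] += comp.amount_ng
        else:
            raise ComponentError(
                f"mix component {comp.name!r} is not a panel target and "
                f"carries no raw sequence"
            )
    return amounts


def simulate_array(
    panel: ProbePanel,
    mix: TemplateMix,
    layout: ArrayLayout,
    config: SimulationConfig,
    array_id: str | None = None,
) -> pd.DataFrame:
    """Simulate one universal array; returns a 208-row fluorescence table.

    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    amounts = _matched_amounts(panel, mix)
    target_by_zip = {p.zip_id: p.target_name for p in panel.pairs}
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    else:
        sigma = 0.0

    def noise_factor() -> float:
        if sigma == 0.0:
            return 1.0
        # mean-one lognormal with the configured CV
        return float(rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma))

    def bg_draw() -> float:
        return float(max(rng.normal(config.background_mean, config.background_sd), 0.0))

    rows = []
    for spot in layout:
        if spot.role == "probe":
            target = target_by_zip.get(spot.zip_id)
            amount = amounts.get(target, 0.0) if target else 0.0
            if config.cross_hyb_rate > 0 and mix.human_dna_ng > 0:
                amount += config.cross_hyb_rate * mix.human_dna_ng
            mean_sig = config.efficiency_for(target) * amount if target else 0.0
            intensity = mean_sig * noise_factor() + bg_draw()
        elif spot.role == "ligation_control":
            intensity = config.zip63_signal_mean * noise_factor() + bg_draw()
        elif spot.role == "hybridization_control":
            intensity = config.zip66_signal_mean * noise_factor() + bg_draw()
        elif spot.role == "blank":
            # buffer-only spots retain slightly more unbound dye than bare
            # capture spots, so the one-tailed probe-vs-blank call is
            # conservative for unmatched probes (no off-target calls)
            intensity = bg_draw() + config.blank_offset_frac * config.background_mean
        else:  # empty: background only
            intensity = bg_draw()
        rows.append(
            {
                "array_id": array_id if array_id is not None else mix.label,
                "row": spot.row,
                "col": spot.col,
                "zip_id": spot.zip_id,
                "role": spot.role,
                "replicate": spot.replicate,
                "IF": intensity,
                "background": bg_draw(),
            }
        )
    return pd.DataFrame(rows, columns=IFTABLE_COLUMNS)


def validate_if_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in IFTABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"fluorescence table missing column(s): {missing}")
    if (table["IF"] < 0).any() or (table["background"] < 0).any():
        raise FormatError("fluorescence intensities must be >= 0")
    return table


def write_if_table(table: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    """Write a fluorescence table as CSV with optional '#' header lines."""
    validate_if_table(table)
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False)


def read_if_table(path) -> pd.DataFrame:
    """Read a fluorescence-table CSV ('#' lines are comments)."""
    table = pd.read_csv(path, comment="#")
    return validate_if_table(table)


_GPR_REQUIRED = ["Block", "Row", "Column", "ID", "F532 Median", "B532 Median"]


def read_gpr(path) -> pd.DataFrame:
    """Read a minimal GenePix-GPR-like tab-separated intensity file.

    Maps Block -> array_id, Row/Column -> row/col (0-based), ID -> zip_id,
    F532 Median -> IF and B532 Median -> background.  Roles are inferred
    from the ID (BLANK / EMPTY / 63 / 66, anything else a probe) and
    replicate indices are assigned in order of appearance per zip.
    """
    raw = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _GPR_REQUIRED if c not in raw.columns]
    if missing:
        raise FormatError(f"GPR file missing column(s): {missing}")
    role_map = {BLANK: "blank", EMPTY: "empty",
                "63": "ligation_control", "66": "hybridization_control"}
    counters: dict[tuple[str, str], int] = {}
    rows = []
    for _, rec in raw.iterrows():
        zid = str(rec["ID"])
        block = str(rec["Block"])
        key = (block, zid)
        counters[key] = counters.get(key, 0) + 1
        rows.append(
            {
                "array_id": block,
                "row": int(rec["Row"]) - 1,
                "col": int(rec["Column"]) - 1,
                "zip_id": zid,
                "role": role_map.get(zid, "probe"),
                "replicate": 0 if zid == EMPTY else counters[key],
                "IF": float(rec["F532 Median"]),
                "background": float(rec["B532 Median"]),
            }
        )
    return validate_if_table(pd.DataFrame(rows, columns=IFTABLE_COLUMNS))
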