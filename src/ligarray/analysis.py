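"""The fluorescence-analysis pipeline for LDR-UA arrays.

Order of operations per array:

1. **Normalization** — replicate intensities of the Zip-63 ligation control
   (added to every reaction in a fixed amount) are outlier-filtered with
   the 2.5-fold rule, then a correction factor rescales their mean to
   50 000 fluorescence units; the factor is applied to probe *and*
   background intensities, making arrays comparable.
2. **Spot calling** — for each probe zip, a one-tailed two-sample t-test
   (probe > blank; Welch by default) compares the outlier-filtered
   quadruplicate probe intensities with the six blank spots; P < 0.01
   calls the target present.  SNR = mean probe IF / mean blank IF.
3. **Summaries** — sSNR/nsSNR aggregation, per-probe efficiency from
   dilution series (mean sSNR per ng), binary detection matrices,
   prevalence, replicate agreement, and relative abundance as percent of
   total fluorescence.

All decisions are scale-invariant: multiplying every intensity by a common
constant changes neither p-values nor SNRs, so calls do not depend on the
normalization constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ControlMissingError,
    DegenerateReplicatesError,
    ParameterError,
    RegistryError,
    ShapeError,
)
from .simulate import validate_if_table

NORMALIZATION_TARGET = 50000.0
DEFAULT_FOLD = 2.5
DEFAULT_ALPHA = 0.01


def remove_outliers(values: Sequence[float], fold: float = DEFAULT_FOLD) -> list[float]:
    """Single-pass 2.5-fold outlier rule.

    The mean is computed once over the input; values more than ``fold``
    times above it or below mean/``fold`` are discarded.  Input order is
    preserved.  Discarding everything (possible when one huge value drags
    the mean above fold x the rest) raises
    :class:`~ligarray.errors.DegenerateReplicatesError` — by design, such
    replicate sets are unusable.
    """
    vals = list(values)
    if not vals:
        raise ParameterError("no replicate values supplied")
    if fold <= 1:
        raise ParameterError(f"fold must exceed 1, got {fold}")
    mean = sum(vals) / len(vals)
    kept = [v for v in vals if mean / fold <= v <= fold * mean]
    if not kept:
        raise DegenerateReplicatesError(
            f"all {len(vals)} replicate values discarded by the "
            f"{fold}-fold rule (mean {mean:.6g})"
        )
    return kept


@dataclass
class NormalizedIFTable:
    """A fluorescence table rescaled to the Zip-63 anchor, per array."""

    table: pd.DataFrame
    correction_factors: dict[str, float]
    target: float = NORMALIZATION_TARGET


def normalize_if(
    table: pd.DataFrame,
    target: float = NORMALIZATION_TARGET,
    fold: float = DEFAULT_FOLD,
) -> NormalizedIFTable:
    """Rescale each array so the retained Zip-63 mean equals ``target``.

    Idempotent: normalizing an already-normalized table yields correction
    factors of 1.
    """
    validate_if_table(table)
    table = table.copy()
    factors: dict[str, float] = {}
    for array_id, sub in table.groupby("array_id", sort=False):
        zip63 = sub.loc[sub["role"] == "ligation_control", "IF"]
        if zip63.empty:
            raise ControlMissingError(
                f"array {array_id!r}: no Zip-63 ligation-control spots"
            )
        retained = remove_outliers(zip63.tolist(), fold)
        factor = target / (sum(retained) / len(retained))
        mask = table["array_id"] == array_id
        table.loc[mask, "IF"] *= factor
        table.loc[mask, "background"] *= factor
        factors[str(array_id)] = factor
    return NormalizedIFTable(table, factors, target)


@dataclass(frozen=True)
class SpotCall:
    """Per-target normalized calling result on one array."""

    target: str
    mean_if: float
    p_value: float
    snr: float
    significant: bool
    n_retained: int


def _one_tailed_greater(
    probe: Sequence[float], blank: Sequence[float], equal_var: bool
) -> float:
    res = stats.ttest_ind(probe, blank, equal_var=equal_var, alternative="greater")
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance on both sides: decide on the means
        return 0.0 if np.mean(probe) > np.mean(blank) else 1.0
    return p


def call_spot(
    probe_ifs: Sequence[float],
    blank_ifs: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    fold: float = DEFAULT_FOLD,
    equal_var: bool = False,
    target: str = "",
) -> SpotCall:
    """Call one probe against the blank distribution of its array.

    Both sides are outlier-filtered first; at least two values must survive
    on each side.  The test is one-tailed (probe > blank), Welch by
    default.  SNR is the ratio of retained means.
    """
    probe = remove_outliers(probe_ifs, fold)
    blank = remove_outliers(blank_ifs, fold)
    if len(probe) < 2 or len(blank) < 2:
        raise DegenerateReplicatesError(
            f"target {target!r}: need >= 2 retained values per side "
            f"(probe {len(probe)}, blank {len(blank)})"
        )
    mean_probe = float(np.mean(probe))
    mean_blank = float(np.mean(blank))
    if mean_blank <= 0:
        raise ParameterError("blank mean must be positive for an SNR")
    p = _one_tailed_greater(probe, blank, equal_var)
    return SpotCall(
        target=target,
        mean_if=mean_probe,
        p_value=p,
        snr=mean_probe / mean_blank,
        significant=p < alpha,
        n_retained=len(probe),
    )


@dataclass
class ArrayCalls:
    """All spot calls of one array: probes and controls kept separate."""

    array_id: str
    probe_calls: list[SpotCall]
    control_calls: list[SpotCall]

    def significant_targets(self) -> list[str]:
        return [c.target for c in self.probe_calls if c.significant]


def call_array(
    norm: NormalizedIFTable | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fold: float = DEFAULT_FOLD,
    equal_var: bool = False,
) -> list[ArrayCalls]:
    """Call every probe zip of every array against its own blanks.

    Blanks are pooled per array only (never across arrays); EMPTY spots are
    ignored.  Controls are called with the same machinery but reported
    separately.
    """
    table = norm.table if isinstance(norm, NormalizedIFTable) else norm
    validate_if_table(table)
    out = []
    for array_id, sub in table.groupby("array_id", sort=False):
        blanks = sub.loc[sub["role"] == "blank", "IF"].tolist()
        if not blanks:
            raise ControlMissingError(f"array {array_id!r}: no blank spots")
        probe_calls = []
        control_calls = []
        for zip_id, spots in sub[sub["role"] != "empty"].groupby("zip_id", sort=False):
            role = spots["role"].iloc[0]
            if role == "blank":
                continue
            call = call_spot(
                spots["IF"].tolist(), blanks, alpha=alpha, fold=fold,
                equal_var=equal_var, target=str(zip_id),
            )
            if role == "probe":
                probe_calls.append(call)
            else:
                control_calls.append(call)
        out.append(ArrayCalls(str(array_id), probe_calls, control_calls))
    return out


@dataclass(frozen=True)
class SnrSummary:
    """Mean/min/max of significant (sSNR) and non-significant (nsSNR) ratios."""

    s_mean: float
    s_min: float
    s_max: float
    ns_mean: float
    ns_min: float
    ns_max: float
    n_significant: int
    n_nonsignificant: int


def summarize_snr(
    calls: Iterable[SpotCall] | Iterable[tuple[str, float, float]],
) -> SnrSummary:
    """Aggregate SNRs, reported to 2 decimals.

    Accepts either spot calls (split by their significance flag) or
    pre-tabulated (label, sSNR, nsSNR) rows such as a published validation
    table.
    """
    items = list(calls)
    if not items:
        raise ParameterError("no SNR rows to summarize")
    s_vals: list[float] = []
    ns_vals: list[float] = []
    for item in items:
        if isinstance(item, SpotCall):
            (s_vals if item.significant else ns_vals).append(item.snr)
        else:
            _, s, ns = item
            s_vals.append(float(s))
            ns_vals.append(float(ns))

    def _agg(vals: list[float]) -> tuple[float, float, float]:
        if not vals:
            return (float("nan"),) * 3
        return (
            round(float(np.mean(vals)), 2),
            round(float(np.min(vals)), 2),
            round(float(np.max(vals)), 2),
        )

    s_mean, s_min, s_max = _agg(s_vals)
    ns_mean, ns_min, ns_max = _agg(ns_vals)
    return SnrSummary(
        s_mean, s_min, s_max, ns_mean, ns_min, ns_max, len(s_vals), len(ns_vals)
    )


@dataclass(frozen=True)
class EfficiencyCoefficient:
    """Per-probe response: mean sSNR per ng, with the series correlation."""

    target: str
    efficiency: float
    pearson_r: float
    n_points: int


def estimate_efficiency(
    series: Sequence[tuple[float, SpotCall]], target: str = ""
) -> EfficiencyCoefficient:
    """Probe efficiency from a dilution series of (ng, call) points.

    Efficiency is the mean of sSNR/ng over the significant points; the
    Pearson correlation is computed between sSNR and ng across them.  At
    least two significant points at distinct amounts are required.
    """
    sig = [(ng, c.snr) for ng, c in series if c.significant and ng > 0]
    amounts = sorted({ng for ng, _ in sig})
    if len(amounts) < 2:
        raise ParameterError(
            f"target {target!r}: need significant calls at >= 2 distinct "
            f"amounts, got {len(amounts)}"
        )
    ngs = np.array([ng for ng, _ in sig])
    snrs = np.array([s for _, s in sig])
    eff = float(np.mean(snrs / ngs))
    r = float(stats.pearsonr(ngs, snrs).statistic)
    name = target or (series[0][1].target if series else "")
    return EfficiencyCoefficient(name, eff, r, len(sig))


def scale_by_efficiency(
    values: Mapping[str, float],
    efficiencies: Mapping[str, EfficiencyCoefficient | float],
) -> dict[str, float]:
    """Divide per-target values by their efficiency coefficient.

    Targets without a coefficient are passed through unscaled (flagged by
    keeping their raw value); zero/negative coefficients are rejected.
    """
    out = {}
    for target, value in values.items():
        coeff = efficiencies.get(target)
        if coeff is None:
            out[target] = value
            continue
        eff = coeff.efficiency if isinstance(coeff, EfficiencyCoefficient) else float(coeff)
        if eff <= 0:
            raise ParameterError(f"target {target!r}: non-positive efficiency")
        out[target] = value / eff
    return out


def detection_matrix(
    samples: Sequence[tuple[str, Sequence[SpotCall]]],
) -> pd.DataFrame:
    """Samples x targets binary matrix (1 = called significant)."""
    if not samples:
        raise ParameterError("no samples supplied")
    registry = [c.target for c in samples[0][1]]
    rows = {}
    for label, calls in samples:
        targets = [c.target for c in calls]
        if sorted(targets) != sorted(registry):
            raise RegistryError(
                f"sample {label!r} disagrees with the target registry"
            )
        rows[label] = {c.target: int(c.significant) for c in calls}
    return pd.DataFrame.from_dict(rows, orient="index", columns=registry).fillna(0).astype(int)


def prevalence(
    dm: pd.DataFrame, groups: Mapping[str, str] | None = None
) -> pd.Series | pd.DataFrame:
    """Percent of samples in which each target is detected (whole percent).

    With ``groups`` (sample label -> group), a per-group table is returned.
    """
    if groups is None:
        return (100.0 * dm.mean(axis=0)).round(0).astype(int)
    labels = pd.Series({s: groups[s] for s in dm.index})
    return (
        (100.0 * dm.groupby(labels).mean()).round(0).astype(int)
    )


def agreement(a, b) -> float:
    """Percent of entries identical between two binary profiles (1 decimal)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ShapeError(f"profile shapes differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ParameterError("empty profiles")
    return round(100.0 * float(np.mean(a == b)), 1)


def relative_abundance(
    mean_if: pd.DataFrame,
    significant: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
    efficiencies: Mapping[str, EfficiencyCoefficient | float] | None = None,
) -> pd.DataFrame:
    """Per-group percent-of-total-fluorescence profiles.

    ``mean_if`` and ``significant`` are samples x targets tables of mean
    probe intensity and significance.  Non-significant entries contribute
    zero; intensities are optionally divided by per-target efficiency
    coefficients first; then, per group, each target's mean intensity
    across the group's samples is expressed as a percentage of the group
    total.  A group with no detected target yields an all-zero row.
    """
    if mean_if.shape != significant.shape or list(mean_if.columns) != list(
        significant.columns
    ):
        raise ShapeError("mean_if and significant tables must align")
    values = mean_if.where(significant.astype(bool), 0.0)
    if efficiencies is not None:
        for target in values.columns:
            coeff = efficiencies.get(target)
            if coeff is not None:
                eff = (
                    coeff.efficiency
                    if isinstance(coeff, EfficiencyCoefficient)
                    else float(coeff)
                )
                if eff <= 0:
                    raise ParameterError(
                        f"target {target!r}: non-positive efficiency"
                    )
                values[target] = values[target] / eff
    if groups is None:
        grouped = values
    else:
        labels = pd.Series({s: groups[s] for s in values.index})
        grouped = values.groupby(labels).mean()
    totals = grouped.sum(axis=1)
    out = grouped.copy()
    nonzero = totals > 0
    out.loc[nonzero] = 100.0 * grouped.loc[nonzero].div(totals[nonzero], axis=0)
    out.loc[~nonzero] = 0.0
    return out
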