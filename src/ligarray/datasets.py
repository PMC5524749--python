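"""Bundled reference data for the 22-target oral probe panel.

Two small tables ship with the package: the target registry of the
published oral panel (probe set, taxonomic level, phylum, assigned zip
code) and the specificity-validation table of per-target p-values and
signal-to-noise ratios (sSNR on the significantly called spot, nsSNR
averaged over the remaining spots).  Both are inputs to the reporting
functions, e.g. feeding the validation SNRs to
:func:`ligarray.analysis.summarize_snr`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .zipcodes import ZIP63_TEMPLATE, ZIP66_SEQUENCE  # re-exported for convenience

__all__ = [
    "oral_target_registry",
    "specificity_snr_table",
    "ZIP63_TEMPLATE",
    "ZIP66_SEQUENCE",
]


def _data_path(name: str):
    return resources.files("ligarray.data").joinpath(name)


def oral_target_registry() -> pd.DataFrame:
    """The 22 oral bacterial targets with their array zip codes."""
    with resources.as_file(_data_path("oral_targets.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def specificity_snr_table() -> pd.DataFrame:
    """Published per-target validation results (p-value, sSNR, nsSNR)."""
    with resources.as_file(_data_path("specificity_snr.csv")) as p:
        return pd.read_csv(p)
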