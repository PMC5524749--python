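"""Shared fixtures: synthetic target sets and a designed 22-set panel.

Everything is generated programmatically with fixed seeds; the expensive
fixtures (the 22-target panel) are session-scoped so design runs once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ligarray import (
    build_layout,
    design_panel,
    synthetic_sequence_sets,
)


@pytest.fixture(scope="session")
def three_targets():
    return synthetic_sequence_sets(3, seed=42)


@pytest.fixture(scope="session")
def panel22_with_sets():
    sets = synthetic_sequence_sets(22, seed=11)
    panel, reports = design_panel(sets)
    assert all(r.passed for r in reports), "fixture panel must design cleanly"
    return sets, panel


@pytest.fixture(scope="session")
def panel22(panel22_with_sets):
    return panel22_with_sets[1]


@pytest.fixture(scope="session")
def layout22(panel22):
    return build_layout(panel22, seed=5)


def random_if_table(rng: np.random.Generator, array_id: str = "A1") -> pd.DataFrame:
    """A minimal random fluorescence table with controls, probes and blanks."""
    rows = []

    def add(zip_id, role, n, mean, sd):
        for rep in range(1, n + 1):
            rows.append(
                {
                    "array_id": array_id,
                    "row": len(rows) // 16,
                    "col": len(rows) % 16,
                    "zip_id": zip_id,
                    "role": role,
                    "replicate": rep,
                    "IF": max(float(rng.normal(mean, sd)), 0.0),
                    "background": max(float(rng.normal(300, 30)), 0.0),
                }
            )

    add("63", "ligation_control", 4, float(rng.uniform(10000, 80000)), 800)
    add("66", "hybridization_control", 4, 30000, 500)
    for i in range(int(rng.integers(3, 8))):
        add(f"p{i}", "probe", 4, float(rng.uniform(500, 60000)), 400)
    add("BLANK", "blank", 6, 400, 40)
    return pd.DataFrame(rows)
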