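"""The physical universal-array layout: a 13 x 16 grid of 208 spots.

Every assigned zip code is printed in quadruplicate; six buffer-only blank
spots provide the background distribution for spot calling; the ligation
control (Zip 63) and hybridization control (Zip 66) are printed like probe
zips.  Spot coordinates are not meaningful to the assay, so placement is
deterministic pseudo-random under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import CapacityError, ParameterError
from .probes import MAX_PROBESETS_PER_ARRAY, ProbePanel

N_ROWS = 13
N_COLS = 16
N_SPOTS = N_ROWS * N_COLS
REPLICATES_PER_ZIP = 4
N_BLANKS = 6

BLANK = "BLANK"
EMPTY = "EMPTY"

ROLE_BY_ZIP_SPECIALS = {BLANK: "blank", EMPTY: "empty"}


@dataclass(frozen=True)
class SpotAssignment:
    row: int
    col: int
    zip_id: str          # a zip id, or BLANK / EMPTY
    role: str            # probe | ligation_control | hybridization_control | blank | empty
    replicate: int       # 1-based within a zip; 0 for EMPTY


@dataclass
class ArrayLayout:
    """Assignment of each of the 208 spots of one universal array."""

    spots: list[SpotAssignment]
    n_rows: int = N_ROWS
    n_cols: int = N_COLS
    replicates_per_zip: int = REPLICATES_PER_ZIP
    n_blanks: int = N_BLANKS

    def __post_init__(self) -> None:
        if len(self.spots) != self.n_rows * self.n_cols:
            raise ParameterError(
                f"layout must assign all {self.n_rows * self.n_cols} spots"
            )
        counts: dict[str, int] = {}
        for s in self.spots:
            counts[s.zip_id] = counts.get(s.zip_id, 0) + 1
        if counts.get(BLANK, 0) != self.n_blanks:
            raise ParameterError(
                f"expected {self.n_blanks} blanks, found {counts.get(BLANK, 0)}"
            )
        for zid, n in counts.items():
            if zid in (BLANK, EMPTY):
                continue
            if n != self.replicates_per_zip:
                raise ParameterError(
                    f"zip {zid!r} printed {n} times, expected "
                    f"{self.replicates_per_zip}"
                )

    def __iter__(self) -> Iterator[SpotAssignment]:
        return iter(self.spots)

    @property
    def assigned(self) -> int:
        return sum(1 for s in self.spots if s.zip_id != EMPTY)

    def zip_ids(self, role: str | None = None) -> list[str]:
        seen = []
        for s in self.spots:
            if s.zip_id in (BLANK, EMPTY):
                continue
            if role is not None and s.role != role:
                continue
            if s.zip_id not in seen:
                seen.append(s.zip_id)
        return seen


def build_layout(panel: ProbePanel, seed: int = 0) -> ArrayLayout:
    """Place a panel on the grid: quadruplicate zips, controls, 6 blanks.

    Deterministic under ``seed``; remaining spots are EMPTY.  A panel of 22
    probe sets occupies 22*4 + 4 + 4 + 6 = 102 spots, leaving 106 empty.
    """
    if len(panel) > MAX_PROBESETS_PER_ARRAY:
        raise CapacityError(
            f"{len(panel)} probe sets exceed the "
            f"{MAX_PROBESETS_PER_ARRAY}-per-array capacity"
        )
    role_by_zip = {z.zip_id: z.role for z in panel.zip_library}
    items: list[tuple[str, str, int]] = []
    for pair in panel.pairs:
        for rep in range(1, REPLICATES_PER_ZIP + 1):
            items.append((pair.zip_id, "probe", rep))
    for control_id in ("63", "66"):
        role = role_by_zip.get(control_id, "ligation_control" if control_id == "63" else "hybridization_control")
        for rep in range(1, REPLICATES_PER_ZIP + 1):
            items.append((control_id, role, rep))
    for rep in range(1, N_BLANKS + 1):
        items.append((BLANK, "blank", rep))
    if len(items) > N_SPOTS:
        raise CapacityError("panel plus controls exceed the 208-spot grid")
    rng = np.random.default_rng(seed)
    positions = [(r, c) for r in range(N_ROWS) for c in range(N_COLS)]
    order = rng.permutation(len(positions))
    spots = []
    for k, (zid, role, rep) in enumerate(items):
        r, c = positions[order[k]]
        spots.append(SpotAssignment(r, c, zid, role, rep))
    for k in range(len(items), N_SPOTS):
        r, c = positions[order[k]]
        spots.append(SpotAssignment(r, c, EMPTY, "empty", 0))
    spots.sort(key=lambda s: (s.row, s.col))
    return ArrayLayout(spots)
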