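"""Reading and writing probe-panel files (TSV / JSON / FASTA export)."""

from __future__ import annotations

import csv
import json
from typing import Sequence

from .alphabet import count_degenerate
from .errors import FormatError
from .probes import ProbeHalf, ProbePair, ProbePanel
from .zipcodes import ZipCode, read_zip_library, write_zip_library

PANEL_COLUMNS = [
    "target_name", "zip_id", "dp_sequence", "cp_sequence",
    "junction", "tm_dp", "tm_cp",
]


def write_panel_tsv(panel: ProbePanel, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(PANEL_COLUMNS)
        for p in panel.pairs:
            writer.writerow(
                [p.target_name, p.zip_id, p.dp.residues, p.cp.residues,
                 p.junction, f"{p.dp.tm:.3f}", f"{p.cp.tm:.3f}"]
            )


def read_panel_tsv(path, zip_library: list[ZipCode]) -> ProbePanel:
    pairs = []
    with open(path, newline="") as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    if reader.fieldnames is None or not set(PANEL_COLUMNS) <= set(reader.fieldnames):
        missing = set(PANEL_COLUMNS) - set(reader.fieldnames or [])
        raise FormatError(f"panel file missing columns: {sorted(missing)}")
    for row in reader:
        dp = ProbeHalf(
            "DP", row["dp_sequence"], float(row["tm_dp"]),
            count_degenerate(row["dp_sequence"]), label=True,
        )
        cp = ProbeHalf(
            "CP", row["cp_sequence"], float(row["tm_cp"]),
            count_degenerate(row["cp_sequence"]),
        )
        pairs.append(
            ProbePair(row["target_name"], dp, cp, int(row["junction"]),
                      row["zip_id"])
        )
    return ProbePanel(pairs, zip_library)


def write_panel_json(panel: ProbePanel, path) -> None:
    payload = {
        "metadata": panel.metadata,
        "pairs": [
            {
                "target_name": p.target_name,
                "zip_id": p.zip_id,
                "dp_sequence": p.dp.residues,
                "cp_sequence": p.cp.residues,
                "junction": p.junction,
                "tm_dp": p.dp.tm,
                "tm_cp": p.cp.tm,
            }
            for p in panel.pairs
        ],
        "zip_library": [
            {"zip_id": z.zip_id, "sequence": z.residues, "role": z.role}
            for z in panel.zip_library
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_panel_json(path) -> ProbePanel:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        library = [
            ZipCode(z["zip_id"], z["sequence"], z["role"])
            for z in payload["zip_library"]
        ]
        pairs = []
        for p in payload["pairs"]:
            dp = ProbeHalf("DP", p["dp_sequence"], p["tm_dp"],
                           count_degenerate(p["dp_sequence"]), label=True)
            cp = ProbeHalf("CP", p["cp_sequence"], p["tm_cp"],
                           count_degenerate(p["cp_sequence"]))
            pairs.append(
                ProbePair(p["target_name"], dp, cp, p["junction"], p["zip_id"])
            )
    except KeyError as exc:
        raise FormatError(f"panel JSON missing field: {exc}") from None
    return ProbePanel(pairs, library, payload.get("metadata", ""))


def write_panel_fasta(panel: ProbePanel, path) -> None:
    """Export probe sequences (DP and CP per target) as FASTA."""
    with open(path, "w") as fh:
        for p in panel.pairs:
            fh.write(f">{p.target_name}|DP|zip{p.zip_id}\n{p.dp.residues}\n")
            fh.write(f">{p.target_name}|CP|zip{p.zip_id}\n{p.cp.residues}\n")
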